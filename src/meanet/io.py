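"""Plain-text readers and writers for rasters, layouts, graphs and tables.

All formats are line-oriented, tab-separated and diff-able.  Spike times
are serialised in seconds with 0.1 ms precision, the resolution ceiling
of a 10 kHz acquisition system; round-trips are identity at that
resolution.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .core import ElectrodeLayout, SpikeRaster, make_chip_layout
from .errors import FormatError, InvalidArgumentError

__all__ = [
    "write_raster", "read_raster",
    "write_layout", "read_layout",
    "write_graph_edgelist", "read_graph_edgelist",
    "write_metrics_table", "read_metrics_table",
]

TIME_DECIMALS = 4       # 1e-4 s = 0.1 ms, the 10 kHz sampling ceiling


def write_raster(raster: SpikeRaster, path) -> None:
    """Write ``electrode_id<TAB>time_s`` rows, one spike per row."""
    with open(path, "w") as fh:
        fh.write("electrode_id\ttime_s\n")
        for i, t in enumerate(raster.spikes):
            for v in t:
                fh.write(f"{i}\t{v:.{TIME_DECIMALS}f}\n")


def read_raster(path, layout: ElectrodeLayout,
                duration_s: float | None = None) -> SpikeRaster:
    """Read a spike event table; unknown electrode ids raise with a line
    number, unsorted times are sorted on load."""
    trains: list[list[float]] = [[] for _ in range(layout.n_electrodes)]
    t_max = 0.0
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("electrode_id"):
            raise FormatError("missing 'electrode_id' header", line=1)
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"expected 2 fields, got {len(parts)}", line=ln)
            try:
                e = int(parts[0])
                t = float(parts[1])
            except ValueError as err:
                raise FormatError(str(err), line=ln) from None
            if not (0 <= e < layout.n_electrodes):
                raise FormatError(f"electrode id {e} not in layout", line=ln)
            trains[e].append(t)
            t_max = max(t_max, t)
    if duration_s is None:
        duration_s = max(t_max + 10 ** (-TIME_DECIMALS), 1e-6)
    spikes = [np.sort(np.asarray(t)) for t in trains]
    return SpikeRaster(layout=layout, duration_s=duration_s, spikes=spikes)


def write_layout(layout: ElectrodeLayout, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_rows={layout.n_rows} n_cols={layout.n_cols} "
                 f"pitch_mm={layout.pitch_mm!r}\n")
        fh.write("electrode_id\tx_mm\ty_mm\n")
        for i, (x, y) in enumerate(layout.positions):
            fh.write(f"{i}\t{x:.6f}\t{y:.6f}\n")


def read_layout(path) -> ElectrodeLayout:
    with open(path) as fh:
        meta = fh.readline()
    if not meta.startswith("#"):
        raise FormatError("missing layout metadata header", line=1)
    fields = dict(tok.split("=") for tok in meta[1:].split())
    try:
        return make_chip_layout(int(fields["n_rows"]), int(fields["n_cols"]),
                                float(fields["pitch_mm"]))
    except (KeyError, ValueError) as err:
        raise FormatError(f"bad layout metadata: {err}", line=1) from None


def write_graph_edgelist(graph: nx.DiGraph, path) -> None:
    """``src<TAB>dst<TAB>weight`` rows (weight defaults to 1)."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, data in graph.edges(data=True):
            fh.write(f"{u}\t{v}\t{data.get('weight', 1.0)!r}\n")


def read_graph_edgelist(path) -> nx.DiGraph:
    g = nx.DiGraph()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("source"):
            raise FormatError("missing 'source' header", line=1)
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"expected 3 fields, got {len(parts)}", line=ln)
            try:
                g.add_edge(int(parts[0]), int(parts[1]), weight=float(parts[2]))
            except ValueError as err:
                raise FormatError(str(err), line=ln) from None
    return g


METRIC_COLUMNS = ["condition", "div", "metric", "value", "units", "n"]


def write_metrics_table(records, path) -> None:
    """One row per (condition, div, metric); stable column order.

    Every record must carry exactly the keys ``condition, div, metric,
    value, units, n``; numeric values are written at full precision.
    """
    records = list(records)
    for r in records:
        if set(r) != set(METRIC_COLUMNS):
            raise InvalidArgumentError(
                f"record keys {sorted(r)} != expected {sorted(METRIC_COLUMNS)}")
    df = pd.DataFrame(records, columns=METRIC_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_metrics_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
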