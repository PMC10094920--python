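"""End-to-end experiment orchestration over conditions and culture ages.

``run_experiment`` simulates (or loads) one recording per
(condition, DIV) cell, runs every analysis stage — activity map, ISI
statistics, spike/network bursts, functional-connectivity graph, graph
metrics, CAT summaries — and writes delimited result tables plus a JSON
manifest.  ``compare_conditions`` then applies per-metric, per-DIV Welch
t-tests between the two conditions.

Sampling units for the comparisons follow the corresponding figure
conventions: per electrode for rate metrics, per burst for burst
durations, per trajectory for CAT metrics.  No multiple-testing
correction is applied by default (each panel is tested on its own); a
Benjamini-Hochberg option is available for users who prefer familywise
control across DIVs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity import interspike_intervals, mean_firing_rate, welch_t_test
from .bursts import burst_stats, detect_all_bursts, detect_network_bursts, \
    network_burst_stats
from .cat import cat_summary, compute_cat
from .connectivity import ConnectivityParams, infer_graph
from .core import make_chip_layout
from .errors import DegenerateInputError, InvalidArgumentError
from .graphs import compute_graph_metrics
from .io import write_graph_edgelist, write_metrics_table, write_raster
from .synthetic import CONDITIONS, DIVS, phenotype_schedule, simulate_recording

log = logging.getLogger("meanet")

__all__ = ["RunConfig", "CellResult", "DIVSeriesResult", "run_experiment",
           "compare_conditions", "analyze_raster", "demo_config"]


@dataclass
class BurstParams:
    max_isi_ms: float = 100.0
    min_spikes: int = 5


@dataclass
class NetworkBurstParams:
    bin_ms: float = 25.0
    k: float = 3.0
    merge_gap_ms: float = 100.0
    min_participation: float = 0.1


@dataclass
class CatParams:
    bin_ms: float = 10.0


@dataclass
class RunConfig:
    """Validated configuration of one full two-condition experiment."""

    conditions: tuple = CONDITIONS
    divs: tuple = DIVS
    n_rows: int = 10
    n_cols: int = 10
    pitch_mm: float = 0.042
    duration_s: float = 300.0
    seed: int = 0
    out_dir: str | None = None
    burst: BurstParams = field(default_factory=BurstParams)
    network_burst: NetworkBurstParams = field(default_factory=NetworkBurstParams)
    connectivity: ConnectivityParams = field(default_factory=ConnectivityParams)
    cat: CatParams = field(default_factory=CatParams)
    write_rasters: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        """Build from a plain dict; unknown keys raise before anything runs."""
        known = {f.name for f in fields(cls)}
        nested = {"burst": BurstParams, "network_burst": NetworkBurstParams,
                  "connectivity": ConnectivityParams, "cat": CatParams}
        kwargs = {}
        for key, value in d.items():
            if key not in known:
                raise InvalidArgumentError(f"unknown configuration key {key!r}")
            if key in nested and isinstance(value, dict):
                sub_known = {f.name for f in fields(nested[key])}
                for sub in value:
                    if sub not in sub_known:
                        raise InvalidArgumentError(
                            f"unknown configuration key {key}.{sub}")
                value = nested[key](**value)
            kwargs[key] = value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for c in self.conditions:
            if c not in CONDITIONS:
                raise InvalidArgumentError(f"unknown condition {c!r}")
        for d in self.divs:
            if d not in DIVS:
                raise InvalidArgumentError(f"unknown DIV {d!r}")
        if self.duration_s <= 0:
            raise InvalidArgumentError("duration must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        d["divs"] = list(self.divs)
        return d


@dataclass
class CellResult:
    """Every analysis output for one (condition, DIV) recording."""

    condition: str
    div: int
    seed: int
    error: str | None = None
    activity_map: object = None
    isi_ms: object = None                   # pooled ISI array
    spike_burst_stats: object = None
    network_burst_stats: object = None
    network_bursts: list = field(default_factory=list)
    functional_graph: object = None
    graph_metrics: object = None
    trajectories: list = field(default_factory=list)
    cat_summaries: dict = field(default_factory=dict)
    ground_truth: object = None

    def samples(self) -> dict[str, np.ndarray]:
        """Unit-level samples backing the cross-condition comparisons."""
        out: dict[str, np.ndarray] = {}
        if self.activity_map is not None:
            out["mfr"] = self.activity_map.rates
        if self.isi_ms is not None and len(self.isi_ms):
            out["isi_ms"] = np.asarray(self.isi_ms)
        if self.spike_burst_stats and self.spike_burst_stats.count:
            out["spike_burst_duration_ms"] = np.array(
                [b.duration_ms for b in self._spike_bursts])
        if self.network_bursts:
            out["network_burst_duration_ms"] = np.array(
                [e.duration_ms for e in self.network_bursts])
        valid = [t for t in self.trajectories if not t.degenerate]
        if valid:
            out["cat_velocity_mm_s"] = np.array([t.mean_velocity_mm_s for t in valid])
            out["cat_duration_ms"] = np.array([t.duration_ms for t in valid])
            out["cat_terminal_distance_mm"] = np.array(
                [t.terminal_distance_mm for t in valid])
        return out

    _spike_bursts: list = field(default_factory=list, repr=False)


@dataclass
class DIVSeriesResult:
    config: RunConfig
    cells: dict = field(default_factory=dict)    # (condition, div) -> CellResult

    def cell(self, condition: str, div: int) -> CellResult:
        return self.cells[(condition, div)]

    def metric_records(self) -> list[dict]:
        recs = []
        for (cond, div), cell in sorted(self.cells.items()):
            if cell.error:
                continue
            rows = [
                ("mfr_mean", cell.activity_map.mean, "spikes/s",
                 cell.activity_map.rates.size),
                ("isi_mean", float(np.mean(cell.isi_ms)) if len(cell.isi_ms)
                 else float("nan"), "ms", len(cell.isi_ms)),
                ("spike_burst_count", cell.spike_burst_stats.count, "bursts",
                 cell.spike_burst_stats.count),
                ("spike_burst_freq", cell.spike_burst_stats.frequency_per_min,
                 "bursts/min", cell.spike_burst_stats.count),
                ("spike_burst_duration_mean",
                 cell.spike_burst_stats.mean_duration_ms, "ms",
                 cell.spike_burst_stats.count),
                ("network_burst_count", cell.network_burst_stats.count,
                 "bursts", cell.network_burst_stats.count),
                ("network_burst_freq",
                 cell.network_burst_stats.frequency_per_min, "bursts/min",
                 cell.network_burst_stats.count),
                ("network_burst_duration_mean",
                 cell.network_burst_stats.mean_duration_ms, "ms",
                 cell.network_burst_stats.count),
                ("graph_n_edges", cell.graph_metrics.n_edges if
                 cell.graph_metrics else 0, "links",
                 cell.graph_metrics.n_nodes if cell.graph_metrics else 0),
                ("avg_cc", cell.graph_metrics.avg_cc if cell.graph_metrics
                 else float("nan"), "unitless",
                 cell.graph_metrics.n_nodes if cell.graph_metrics else 0),
                ("network_pl", cell.graph_metrics.network_pl if
                 cell.graph_metrics else float("nan"), "links",
                 cell.graph_metrics.n_nodes if cell.graph_metrics else 0),
                ("nd_mean", cell.graph_metrics.nd_mean if cell.graph_metrics
                 else float("nan"), "links",
                 cell.graph_metrics.n_nodes if cell.graph_metrics else 0),
            ]
            for key, summ in cell.cat_summaries.items():
                rows.append((f"cat_{key}_mean", summ.mean,
                             key.rsplit("_", 1)[-1], summ.n))
            for metric, value, units, n in rows:
                recs.append({"condition": cond, "div": div, "metric": metric,
                             "value": value, "units": units, "n": n})
        return recs


def analyze_raster(raster, config: RunConfig, condition: str = "",
                   div: int = 0, seed: int = 0, ground_truth=None) -> CellResult:
    """Run every analysis stage on one raster."""
    cell = CellResult(condition=condition, div=div, seed=seed,
                      ground_truth=ground_truth)
    cell.activity_map = mean_firing_rate(raster)
    cell.isi_ms = interspike_intervals(raster, pooling="pooled")
    spike_bursts = detect_all_bursts(raster, config.burst.max_isi_ms,
                                     config.burst.min_spikes)
    cell._spike_bursts = spike_bursts
    cell.spike_burst_stats = burst_stats(spike_bursts, raster.duration_s)
    nb = detect_network_bursts(
        raster, config.network_burst.bin_ms, config.network_burst.k,
        config.network_burst.merge_gap_ms,
        config.network_burst.min_participation)
    cell.network_bursts = nb
    cell.network_burst_stats = network_burst_stats(nb, raster.duration_s)
    conn = config.connectivity
    if conn.seed != seed:
        conn = ConnectivityParams(**{**asdict(conn), "seed": seed})
    cell.functional_graph = infer_graph(raster, conn)
    if cell.functional_graph.n_nodes:
        cell.graph_metrics = compute_graph_metrics(cell.functional_graph.graph)
    cell.trajectories = [
        compute_cat(raster, e, config.cat.bin_ms, burst_id=i)
        for i, e in enumerate(nb)
    ]
    if any(not t.degenerate for t in cell.trajectories):
        cell.cat_summaries = cat_summary(cell.trajectories)
    return cell


def run_experiment(config: RunConfig) -> DIVSeriesResult:
    """Simulate and analyse the full DIV series for every condition.

    Deterministic under ``config.seed``; per-cell failures are recorded
    and the run continues.  When ``config.out_dir`` is set, metrics,
    graph edge lists, burst and trajectory tables and a manifest are
    written there.
    """
    config.validate()
    layout = make_chip_layout(config.n_rows, config.n_cols, config.pitch_mm)
    result = DIVSeriesResult(config=config)
    for condition in config.conditions:
        schedule = {c.div: c for c in phenotype_schedule(condition, config.seed)}
        for div in config.divs:
            cfg = schedule[div]
            t0 = time.perf_counter()
            try:
                raster, truth = simulate_recording(cfg, layout, config.duration_s)
                cell = analyze_raster(raster, config, condition, div, cfg.seed,
                                      ground_truth=truth)
                if config.out_dir and config.write_rasters:
                    out = Path(config.out_dir)
                    out.mkdir(parents=True, exist_ok=True)
                    write_raster(raster, out / f"raster_{condition}_div{div}.tsv")
            except Exception as err:   # record and continue with other cells
                cell = CellResult(condition=condition, div=div, seed=cfg.seed,
                                  error=f"{type(err).__name__}: {err}")
                log.warning("cell (%s, DIV%d) failed: %s", condition, div, err)
            result.cells[(condition, div)] = cell
            log.info("analysed %s DIV%-2d in %.1fs", condition, div,
                     time.perf_counter() - t0)
    if config.out_dir:
        _write_outputs(result)
    return result


def _write_outputs(result: DIVSeriesResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_metrics_table(result.metric_records(), out / "metrics.tsv")
    nb_rows, traj_rows, sample_rows = [], [], []
    for (cond, div), cell in sorted(result.cells.items()):
        if cell.error:
            continue
        if cell.functional_graph is not None:
            write_graph_edgelist(cell.functional_graph.graph,
                                 out / f"graph_{cond}_div{div}.tsv")
        for e in cell.network_bursts:
            nb_rows.append({"condition": cond, "div": div, "start_s": e.start,
                            "end_s": e.end, "n_participants": e.n_participants})
        for t in cell.trajectories:
            for p in t.points:
                if p.defined:
                    traj_rows.append({"condition": cond, "div": div,
                                      "burst_id": t.burst_id, "t_s": p.t,
                                      "x_mm": p.x, "y_mm": p.y,
                                      "n_spikes": p.total_activity})
        for metric, values in cell.samples().items():
            for v in values:
                sample_rows.append({"condition": cond, "div": div,
                                    "metric": metric, "value": float(v)})
    pd.DataFrame(nb_rows).to_csv(out / "network_bursts.tsv", sep="\t", index=False)
    pd.DataFrame(traj_rows).to_csv(out / "trajectories.tsv", sep="\t", index=False)
    pd.DataFrame(sample_rows).to_csv(out / "samples.tsv", sep="\t", index=False)
    manifest = {"version": __version__, "config": result.config.to_dict(),
                "cells": {f"{c}_div{d}": (cell.error or "ok")
                          for (c, d), cell in sorted(result.cells.items())}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def compare_conditions(result: DIVSeriesResult,
                       condition_a: str = "control",
                       condition_b: str = "abeta42",
                       bh_correction: bool = False) -> pd.DataFrame:
    """Welch t-tests per metric per DIV between two conditions.

    Returns a table with group means, SEMs, t, df, p and the significance
    tier.  Metrics with fewer than two observations in either group are
    skipped.  ``bh_correction`` applies Benjamini-Hochberg across all
    rows (off by default; the per-panel convention tests each metric on
    its own).
    """
    rows = []
    for div in result.config.divs:
        key_a, key_b = (condition_a, div), (condition_b, div)
        if key_a not in result.cells or key_b not in result.cells:
            log.warning("DIV%d missing one condition; skipped", div)
            continue
        cell_a, cell_b = result.cells[key_a], result.cells[key_b]
        if cell_a.error or cell_b.error:
            continue
        sa, sb = cell_a.samples(), cell_b.samples()
        for metric in sorted(set(sa) & set(sb)):
            a, b = sa[metric], sb[metric]
            if a.size < 2 or b.size < 2:
                continue
            try:
                res = welch_t_test(a, b)
            except DegenerateInputError:
                continue
            rows.append({
                "div": div, "metric": metric,
                f"mean_{condition_a}": a.mean(),
                f"sem_{condition_a}": a.std(ddof=1) / np.sqrt(a.size),
                f"mean_{condition_b}": b.mean(),
                f"sem_{condition_b}": b.std(ddof=1) / np.sqrt(b.size),
                "n_a": a.size, "n_b": b.size,
                "t": res.t, "df": res.df, "p": res.p, "tier": res.tier,
            })
    df = pd.DataFrame(rows)
    if bh_correction and len(df):
        from scipy.stats import false_discovery_control
        df["p_adj"] = false_discovery_control(df["p"], method="bh")
    return df


def demo_config(seed: int = 0, out_dir: str | None = None) -> RunConfig:
    """The packaged desk-scale demo: 10x10 grid, both conditions, 6 DIVs."""
    return RunConfig(seed=seed, out_dir=out_dir)
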