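"""Synthetic spike-raster generator for developing-culture phenotypes.

The generator produces 5-minute spike rasters whose statistics emulate two
culture phenotypes recorded on a high-density MEA across days in vitro
(DIV): an untreated control and an amyloid-beta-42-treated culture.  It is
spike-level: membrane voltages are never modelled, because every analysis
stage downstream consumes spike times only.

Forward model, per recording
----------------------------
1. A per-electrode *spatial weight map* (homogeneous, or a Gaussian
   hotspot for localized activity) scales a baseline Poisson rate.
2. A latent *ground-truth graph* over a subset of electrodes: a directed
   small-world ring lattice for the control, or a union of dense local
   modules with sparse inter-module links for the treated phenotype.
3. *Network bursts*: non-overlapping windows in which a wavefront spreads
   from an initiator node along graph out-edges; each recruited electrode
   fires a stereotyped onset volley (three spikes 2 ms apart) followed by
   an elevated-rate Poisson packet.  The per-hop propagation delay makes
   cross-correlation lag signs informative about true edge direction.

Everything is reproducible from the single seed carried by the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import networkx as nx
import numpy as np
import yaml

from .core import ElectrodeLayout, SpikeRaster
from .errors import InvalidArgumentError, PlacementError

__all__ = [
    "PhenotypeConfig",
    "GroundTruth",
    "CONDITIONS",
    "DIVS",
    "phenotype_schedule",
    "load_phenotype_table",
    "generate_ground_truth_graph",
    "spatial_weight_map",
    "simulate_recording",
    "homogeneous_poisson_raster",
]

CONDITIONS = ("control", "abeta42")
DIVS = (1, 4, 7, 10, 13, 16)

#: spikes in the deterministic onset volley of every recruited electrode
VOLLEY_SPIKES = 3
#: spacing of the volley spikes, seconds
VOLLEY_DT = 0.001
#: minimum silent gap enforced between consecutive network-burst windows, s
MIN_BURST_GAP = 0.3
#: recordings keep this margin free at both ends, s
EDGE_MARGIN = 1.0


@dataclass(frozen=True)
class PhenotypeConfig:
    """Generator parameters for one condition at one DIV."""

    condition: str
    div: int
    base_rate: float                    # spikes/s per electrode, baseline
    rate_dispersion: float              # lognormal sigma of per-electrode gain
    n_network_bursts: int
    burst_participation: float          # fraction of electrodes recruited per burst
    within_burst_rate: float            # spikes/s inside a burst packet
    burst_duration_mean_ms: float
    spatial_profile: tuple              # ("homogeneous",) or ("localized", (cx, cy), width)
    graph_params: dict
    propagation_delay_ms: float
    seed: int = 0

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise InvalidArgumentError(f"unknown condition {self.condition!r}")
        if self.base_rate < 0 or self.within_burst_rate < 0:
            raise InvalidArgumentError("rates must be non-negative")
        if not (0.0 <= self.burst_participation <= 1.0):
            raise InvalidArgumentError("burst_participation must be in [0, 1]")
        if self.n_network_bursts < 0:
            raise InvalidArgumentError("n_network_bursts must be >= 0")


@dataclass
class GroundTruth:
    """Latent structure emitted alongside a synthetic raster."""

    graph: nx.DiGraph                       # nodes are electrode ids
    network_burst_windows: list[tuple[float, float]]
    per_electrode_rate: np.ndarray          # baseline spikes/s per electrode
    spatial_weight_map: np.ndarray          # mean-1 activation weights
    burst_initiators: list[int] = field(default_factory=list)


def load_phenotype_table() -> dict:
    """Return the packaged phenotype parameter table (parsed YAML)."""
    text = resources.files("meanet.data").joinpath("phenotypes.yaml").read_text()
    return yaml.safe_load(text)


def _profile_for(table_cond: dict, div: int) -> tuple:
    profs = table_cond.get("spatial_profile", {})
    raw = profs.get(f"div{div}", profs.get("default", {"kind": "homogeneous"}))
    if raw["kind"] == "homogeneous":
        return ("homogeneous",)
    return ("localized", tuple(raw["center"]), float(raw["width"]))


def phenotype_schedule(condition: str, base_seed: int = 0) -> list[PhenotypeConfig]:
    """Build the packaged per-DIV config list for one condition.

    Seeds are derived deterministically from ``base_seed`` so that the two
    conditions and six DIVs never share a random stream.
    """
    if condition not in CONDITIONS:
        raise InvalidArgumentError(f"unknown condition {condition!r}")
    table = load_phenotype_table()
    cond = table[condition]
    configs = []
    for i, div in enumerate(table["divs"]):
        row = cond["by_div"][f"div{div}"]
        if condition == "control":
            graph_params = {
                "kind": "small_world",
                "mean_degree": int(row["mean_degree"]),
                "rewiring_prob": float(cond["graph"]["rewiring_prob"]),
            }
        else:
            graph_params = {
                "kind": "modular",
                "n_modules": int(row["n_modules"]),
                "module_size": int(row["module_size"]),
                "inter_module_edges": row.get("inter_module_edges"),
                "topology": "star" if div == 4 else "ring",
            }
        configs.append(
            PhenotypeConfig(
                condition=condition,
                div=div,
                base_rate=float(row["base_rate"]),
                rate_dispersion=float(cond["rate_dispersion"]),
                n_network_bursts=int(row["n_network_bursts"]),
                burst_participation=float(row["burst_participation"]),
                within_burst_rate=float(row["within_burst_rate"]),
                burst_duration_mean_ms=float(row["burst_duration_mean_ms"]),
                spatial_profile=_profile_for(cond, div),
                graph_params=graph_params,
                propagation_delay_ms=float(
                    row.get("propagation_delay_ms", cond["propagation_delay_ms"])
                ),
                seed=base_seed * 100 + i * 10 + (0 if condition == "control" else 1),
            )
        )
    return configs


def _ring_lattice_directed(n: int, mean_degree: int, rewiring_prob: float,
                           rng: np.random.Generator) -> nx.DiGraph:
    """Directed ring lattice: each node points at its next k/2 neighbours.

    The undirected projection is the classic ring lattice of degree
    ``mean_degree``; forward orientation keeps the graph strongly
    connected so activity wavefronts can reach every node.
    """
    if mean_degree >= n:
        raise InvalidArgumentError("mean_degree must be < n_nodes")
    if mean_degree % 2 or mean_degree < 2:
        raise InvalidArgumentError("mean_degree must be an even integer >= 2")
    f = mean_degree // 2
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for m in range(1, f + 1):
            j = (i + m) % n
            if rewiring_prob > 0 and rng.random() < rewiring_prob:
                choices = [c for c in rng.permutation(n)
                           if c != i and not g.has_edge(i, c)]
                if choices:
                    j = int(choices[0])
            g.add_edge(i, int(j))
    return g


def _modular_directed(n_modules: int, module_size: int, inter_module_edges,
                      topology: str, rng: np.random.Generator) -> nx.DiGraph:
    """Union of dense modules with sparse directed inter-module links.

    Each module is a forward tournament (node a -> node b for a < b inside
    the module), so its undirected projection is a clique and the module
    head reaches every member in one hop.  Inter-module links connect
    module heads in a ring (or a star from module 0), carrying the
    activity wavefront between modules.
    """
    g = nx.DiGraph()
    n = n_modules * module_size
    g.add_nodes_from(range(n))
    heads = [m * module_size for m in range(n_modules)]
    for m in range(n_modules):
        lo = m * module_size
        g.nodes[lo]["is_head"] = True
        for a in range(lo, lo + module_size):
            g.nodes[a]["module"] = m
            for b in range(a + 1, lo + module_size):
                g.add_edge(a, b)
    if inter_module_edges is None:
        inter_module_edges = n_modules if n_modules > 1 else 0
    if inter_module_edges and n_modules > 1:
        if topology == "star":
            for m in range(1, n_modules):
                g.add_edge(heads[0], heads[m])
        else:  # ring over modules; source node inside the module is random
            for m in range(n_modules):
                src = int(rng.integers(m * module_size, (m + 1) * module_size))
                g.add_edge(src, heads[(m + 1) % n_modules])
    return g


def generate_ground_truth_graph(cfg: PhenotypeConfig,
                                n_electrodes: int | None = None) -> nx.DiGraph:
    """Generate the latent directed graph for one phenotype config.

    Nodes are abstract indices ``0..n-1`` (grid order for the control);
    :func:`simulate_recording` maps them onto electrode ids.
    """
    rng = np.random.default_rng(cfg.seed)
    gp = cfg.graph_params
    if gp["kind"] == "small_world":
        n = gp.get("n_nodes") or n_electrodes
        if n is None:
            raise InvalidArgumentError("small_world graph needs n_nodes or a layout size")
        return _ring_lattice_directed(int(n), gp["mean_degree"], gp["rewiring_prob"], rng)
    if gp["kind"] == "modular":
        g = _modular_directed(gp["n_modules"], gp["module_size"],
                              gp.get("inter_module_edges"), gp.get("topology", "ring"),
                              rng)
        if n_electrodes is not None and g.number_of_nodes() > n_electrodes:
            raise InvalidArgumentError(
                f"modular graph needs {g.number_of_nodes()} nodes but layout has "
                f"{n_electrodes} electrodes"
            )
        return g
    raise InvalidArgumentError(f"unknown graph kind {gp['kind']!r}")


def spatial_weight_map(cfg: PhenotypeConfig, layout: ElectrodeLayout,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-electrode activation weights, normalised to mean 1.

    Homogeneous profiles give uniform weights; localized profiles a
    Gaussian hotspot (with a small floor so no electrode is fully silent).
    Multiplicative lognormal dispersion models electrode-to-electrode
    variability in cell coverage.
    """
    n = layout.n_electrodes
    if cfg.spatial_profile[0] == "homogeneous":
        w = np.ones(n)
    else:
        _, center_frac, width_frac = cfg.spatial_profile
        scale = layout.half_extent_mm or 1.0
        center = np.asarray(center_frac, dtype=float) * scale
        sigma = width_frac * scale
        d2 = np.sum((layout.positions - center) ** 2, axis=1)
        w = np.exp(-d2 / (2.0 * sigma**2)) + 0.05
    if cfg.rate_dispersion > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        w = w * rng.lognormal(mean=0.0, sigma=cfg.rate_dispersion, size=n)
    return w / w.mean()


def _map_nodes_to_electrodes(graph: nx.DiGraph, cfg: PhenotypeConfig,
                             layout: ElectrodeLayout,
                             rng: np.random.Generator) -> nx.DiGraph:
    """Relabel abstract graph nodes onto electrode ids.

    Control nodes keep grid order (the ring lattice snakes through the
    array row by row).  Treated-culture modules are placed as spatially
    contiguous electrode clusters scattered around the activity hotspot.
    """
    n_e = layout.n_electrodes
    if cfg.graph_params["kind"] == "small_world":
        mapping = {i: i for i in graph.nodes}
        return nx.relabel_nodes(graph, mapping, copy=True)
    # modular: draw module centres near the hotspot, assign nearest electrodes
    scale = layout.half_extent_mm or 1.0
    if cfg.spatial_profile[0] == "localized":
        center = np.asarray(cfg.spatial_profile[1], dtype=float) * scale
        sigma = cfg.spatial_profile[2] * scale
    else:
        center = np.zeros(2)
        sigma = 0.5 * scale
    modules: dict[int, list[int]] = {}
    for node in graph.nodes:
        modules.setdefault(graph.nodes[node]["module"], []).append(node)
    unassigned = np.ones(n_e, dtype=bool)
    mapping: dict[int, int] = {}
    for m in sorted(modules):
        members = sorted(modules[m])
        c = center + rng.normal(0.0, 0.6 * sigma, size=2)
        d = np.linalg.norm(layout.positions - c, axis=1)
        d[~unassigned] = np.inf
        chosen = np.argsort(d)[: len(members)]
        for node, e in zip(members, chosen):
            mapping[node] = int(e)
            unassigned[e] = False
    return nx.relabel_nodes(graph, mapping, copy=True)


def _bfs_depths(graph: nx.DiGraph, source) -> dict:
    return nx.single_source_shortest_path_length(graph, source)


def _place_windows(n: int, lengths: np.ndarray, duration: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Random non-overlapping window starts with a minimum gap."""
    occupied = float(lengths.sum()) + MIN_BURST_GAP * max(n - 1, 0)
    free = duration - 2 * EDGE_MARGIN - occupied
    if free < 0:
        raise PlacementError(
            f"cannot place {n} bursts totalling {occupied:.1f}s in {duration:.1f}s"
        )
    slack = np.sort(rng.uniform(0.0, free, size=n))
    offsets = np.concatenate([[0.0], np.cumsum(lengths[:-1] + MIN_BURST_GAP)])
    return EDGE_MARGIN + slack + offsets


def simulate_recording(cfg: PhenotypeConfig, layout: ElectrodeLayout,
                       duration: float = 300.0) -> tuple[SpikeRaster, GroundTruth]:
    """Simulate one recording; returns the raster and its ground truth.

    Baseline activity is independent Poisson per electrode at
    ``base_rate x spatial weight``.  Network bursts are placed without
    overlap; within each burst, recruitment spreads from an initiator
    along ground-truth out-edges at the configured per-hop delay, and each
    recruited electrode fires an onset volley plus a Poisson packet at the
    within-burst rate.
    """
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    rng = np.random.default_rng(cfg.seed)
    n_e = layout.n_electrodes

    weights = spatial_weight_map(cfg, layout, rng)
    rates = cfg.base_rate * weights

    # baseline Poisson trains
    trains: list[list[np.ndarray]] = [[] for _ in range(n_e)]
    counts = rng.poisson(rates * duration)
    for i in range(n_e):
        if counts[i]:
            trains[i].append(rng.uniform(0.0, duration, size=counts[i]))

    # latent graph on electrode ids
    abstract = generate_ground_truth_graph(cfg, n_electrodes=n_e)
    graph = _map_nodes_to_electrodes(abstract, cfg, layout, rng)

    windows: list[tuple[float, float]] = []
    initiators: list[int] = []
    n_b = cfg.n_network_bursts
    if n_b > 0 and graph.number_of_nodes() > 0:
        burst_len = cfg.burst_duration_mean_ms / 1000.0
        lengths = burst_len * rng.uniform(0.9, 1.1, size=n_b)
        starts = _place_windows(n_b, lengths, duration, rng)
        delay = cfg.propagation_delay_ms / 1000.0
        n_recruit = max(1, int(round(cfg.burst_participation * n_e)))
        nodes = list(graph.nodes)
        is_modular = cfg.graph_params["kind"] == "modular"
        if is_modular:
            module_of = nx.get_node_attributes(graph, "module")
            heads = nx.get_node_attributes(graph, "is_head")
            module_heads = {module_of[n]: n for n in heads}
            if cfg.graph_params.get("topology") == "star":
                initiator_pool = [module_heads[min(module_heads)]]
            else:
                initiator_pool = [module_heads[m] for m in sorted(module_heads)]
        else:
            initiator_pool = nodes

        for b in range(n_b):
            start, length = float(starts[b]), float(lengths[b])
            initiator = initiator_pool[int(rng.integers(len(initiator_pool)))]
            depths = _bfs_depths(graph, initiator)
            order = sorted(depths, key=lambda v: (depths[v], rng.random()))
            recruited = order[:n_recruit]
            max_onset = max(depths[v] for v in recruited) * delay
            volley_len = (VOLLEY_SPIKES - 1) * VOLLEY_DT
            packet = max(0.05, length - max_onset)
            for v in recruited:
                onset = start + depths[v] * delay
                volley = onset + VOLLEY_DT * np.arange(VOLLEY_SPIKES)
                tail_len = max(packet - volley_len, 0.0)
                k = rng.poisson(cfg.within_burst_rate * tail_len)
                tail = onset + volley_len + rng.uniform(0.0, tail_len, size=k)
                trains[v].append(volley)
                trains[v].append(tail)
            windows.append((start, start + max_onset + packet))
            initiators.append(int(initiator))

    spikes = []
    for i in range(n_e):
        if trains[i]:
            t = np.sort(np.concatenate(trains[i]))
            t = t[(t > 0.0) & (t < duration)]
        else:
            t = np.empty(0)
        spikes.append(t)

    raster = SpikeRaster(
        layout=layout, duration_s=duration, spikes=spikes,
        meta={"condition": cfg.condition, "div": cfg.div, "seed": cfg.seed},
    )
    truth = GroundTruth(
        graph=graph, network_burst_windows=windows,
        per_electrode_rate=rates, spatial_weight_map=weights,
        burst_initiators=initiators,
    )
    return raster, truth


def homogeneous_poisson_raster(layout: ElectrodeLayout, rate: float,
                               duration: float, seed: int) -> SpikeRaster:
    """Independent homogeneous Poisson trains at a common rate.

    Convenience path used for rate/ISI calibration experiments; equivalent
    to a burst-free, dispersion-free homogeneous phenotype.
    """
    cfg = PhenotypeConfig(
        condition="control", div=1, base_rate=rate, rate_dispersion=0.0,
        n_network_bursts=0, burst_participation=0.0, within_burst_rate=0.0,
        burst_duration_mean_ms=0.0, spatial_profile=("homogeneous",),
        graph_params={"kind": "small_world", "mean_degree": 2,
                      "rewiring_prob": 0.0},
        propagation_delay_ms=5.0, seed=seed,
    )
    raster, _ = simulate_recording(cfg, layout, duration)
    return raster
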