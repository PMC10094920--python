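"""Graph-theory metrics: clustering, path length, node degree.

All metrics run on the undirected projection of the (directed) functional
graph: the clustering coefficient and path-length discussion of cultured
networks is direction-agnostic.  Path lengths are unweighted shortest
paths in links; per-node average path length is taken over reachable
targets only, so fragmented networks keep every node instead of dropping
components.  The path-length histogram uses 0.25-link bins, fine enough
to represent medians such as 2.75 links.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import InvalidArgumentError, NoPathError

__all__ = [
    "GraphMetricsResult",
    "clustering_coefficient",
    "path_length_analysis",
    "degree_analysis",
    "compute_graph_metrics",
]


def _undirected(graph) -> nx.Graph:
    if isinstance(graph, nx.DiGraph):
        return nx.Graph(graph)
    return graph


@dataclass
class GraphMetricsResult:
    """Bundle of the three topology metrics for one graph."""

    n_nodes: int
    n_edges: int                      # undirected-projection edges
    avg_cc: float
    per_node_cc: dict
    network_pl: float                 # mean per-node average path length, links
    per_node_avg_pl: dict
    pl_histogram: tuple               # (bin_left_edges, counts), 0.25-link bins
    pl_median: float
    pl_median_bin: float              # left edge of the bin holding the median
    nd_histogram: tuple               # (degree values, counts), integer bins
    nd_median: float
    nd_mean: float
    nd_tail_mass: float               # fraction of nodes above the tail quantile


def clustering_coefficient(graph) -> tuple[dict, float]:
    """Per-node clustering and the average over nodes of degree >= 2.

    Node cc = 2 T_i / (k_i (k_i - 1)) on the undirected projection, with
    cc = 0 for degree < 2.  The average ignores degree < 2 nodes, which
    cannot close a triangle; it is 0.0 when no node qualifies.
    """
    und = _undirected(graph)
    if und.number_of_nodes() == 0:
        raise InvalidArgumentError("graph is empty")
    per_node = nx.clustering(und)
    eligible = [cc for n, cc in per_node.items() if und.degree(n) >= 2]
    avg = float(np.mean(eligible)) if eligible else 0.0
    return per_node, avg


def path_length_analysis(graph, bin_width: float = 0.25):
    """Per-node average shortest path length and its histogram.

    Returns ``(network_pl, per_node_avg_pl, (bin_lefts, counts),
    median_bin_left)``.  Raises :class:`NoPathError` when no pair of
    nodes is connected at all.
    """
    und = _undirected(graph)
    if und.number_of_nodes() < 2:
        raise InvalidArgumentError("need at least two nodes")
    if bin_width <= 0:
        raise InvalidArgumentError("bin_width must be positive")
    per_node = {}
    for n in und.nodes:
        lengths = nx.single_source_shortest_path_length(und, n)
        reach = [d for t, d in lengths.items() if t != n]
        if reach:
            per_node[n] = float(np.mean(reach))
    if not per_node:
        raise NoPathError("no finite path between any pair of nodes")
    vals = np.array(sorted(per_node.values()))
    network_pl = float(vals.mean())
    n_bins = int(np.floor(vals.max() / bin_width)) + 1
    lefts = np.arange(n_bins) * bin_width
    counts, _ = np.histogram(vals, bins=np.append(lefts, lefts[-1] + bin_width))
    median = float(np.median(vals))
    median_bin = float(np.floor(median / bin_width) * bin_width)
    return network_pl, per_node, (lefts, counts), median_bin


def degree_analysis(graph, tail_quantile: float = 0.9):
    """Undirected-projection degrees, histogram, median, mean, tail mass.

    Tail mass is the fraction of nodes with degree strictly above the
    ``tail_quantile`` degree value, a simple fat-tail indicator.
    """
    und = _undirected(graph)
    if und.number_of_nodes() == 0:
        raise InvalidArgumentError("graph is empty")
    degrees = dict(und.degree())
    vals = np.array(sorted(degrees.values()))
    uniq, counts = np.unique(vals, return_counts=True)
    q = np.percentile(vals, 100.0 * tail_quantile)
    tail_mass = float((vals > q).mean())
    return degrees, (uniq, counts), float(np.median(vals)), float(vals.mean()), tail_mass


def compute_graph_metrics(graph, pl_bin_width: float = 0.25,
                          tail_quantile: float = 0.9) -> GraphMetricsResult:
    """All three metric families for one graph, NaN-safe on fragmentation."""
    und = _undirected(graph)
    per_cc, avg_cc = clustering_coefficient(graph)
    degrees, nd_hist, nd_median, nd_mean, tail = degree_analysis(graph, tail_quantile)
    try:
        network_pl, per_pl, pl_hist, pl_median_bin = path_length_analysis(
            graph, pl_bin_width)
        pl_median = float(np.median(list(per_pl.values())))
    except (NoPathError, InvalidArgumentError):
        network_pl, per_pl, pl_hist = float("nan"), {}, (np.array([]), np.array([]))
        pl_median = pl_median_bin = float("nan")
    return GraphMetricsResult(
        n_nodes=und.number_of_nodes(), n_edges=und.number_of_edges(),
        avg_cc=avg_cc, per_node_cc=per_cc,
        network_pl=network_pl, per_node_avg_pl=per_pl,
        pl_histogram=pl_hist, pl_median=pl_median, pl_median_bin=pl_median_bin,
        nd_histogram=nd_hist, nd_median=nd_median, nd_mean=nd_mean,
        nd_tail_mass=tail,
    )
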