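"""Functional-connectivity inference from pairwise cross-correlation.

An edge i -> j is declared when the binned cross-correlogram of the two
spike trains (counts of t_j - t_i per lag bin, default 2 ms bins over
+/-25 ms) has a peak at positive lag (i leads j) exceeding a
surrogate-based significance threshold.  Surrogates jitter every spike of
the target train uniformly within +/-jitter (default 25 ms); the threshold
is mean + c x sd (default c=4) of the surrogate correlogram peaks.  A peak
in the zero-lag bin yields an undirected association stored as two
directed edges flagged ``mutual``.

Node roles follow the in/out-degree balance: more outgoing than incoming
links makes a *sender*, the converse a *receiver*, a tie with nonzero
degree a *broker*; isolated nodes carry no role.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .bursts import ACTIVE_RATE_THRESHOLD, active_electrodes
from .core import SpikeRaster
from .errors import InvalidArgumentError, NoDataError

__all__ = [
    "ConnectivityParams",
    "FunctionalGraph",
    "cross_correlogram",
    "significance_threshold",
    "infer_graph",
    "classify_node_roles",
]


@dataclass(frozen=True)
class ConnectivityParams:
    """Tunable parameters of the correlogram-based inference."""

    bin_ms: float = 2.0
    max_lag_ms: float = 25.0
    n_surrogates: int = 20
    jitter_ms: float = 25.0
    c: float = 4.0
    min_rate: float = ACTIVE_RATE_THRESHOLD   # active-electrode cutoff, spikes/s
    min_pair_count: int = 10                  # skip pairs with fewer close pairs
    seed: int = 0

    def __post_init__(self):
        if self.bin_ms <= 0:
            raise InvalidArgumentError("bin must be positive")
        if self.max_lag_ms < self.bin_ms:
            raise InvalidArgumentError("max_lag must be >= bin")
        if self.n_surrogates < 10:
            raise InvalidArgumentError("need at least 10 surrogates")
        if self.jitter_ms <= 0:
            raise InvalidArgumentError("jitter must be positive")

    @property
    def n_bins(self) -> int:
        return int(np.ceil(2.0 * self.max_lag_ms / self.bin_ms))

    @property
    def edges_ms(self) -> np.ndarray:
        return -self.max_lag_ms + self.bin_ms * np.arange(self.n_bins + 1)


def _lag_centers(params: ConnectivityParams) -> np.ndarray:
    e = params.edges_ms
    return (e[:-1] + e[1:]) / 2.0


def cross_correlogram(train_i, train_j, bin_ms: float = 2.0,
                      max_lag_ms: float = 25.0) -> tuple[np.ndarray, np.ndarray]:
    """Binned counts of spike-pair lags t_j - t_i over +/-max_lag.

    Returns ``(lag_bin_centers_ms, counts)``.  When both trains are the
    same, exact self-pairs (a spike against itself) are excluded, so the
    zero-lag bin of an autocorrelogram does not count n_spikes trivially.
    """
    params = ConnectivityParams(bin_ms=bin_ms, max_lag_ms=max_lag_ms)
    ti = np.asarray(train_i, dtype=float)
    tj = np.asarray(train_j, dtype=float)
    same = ti.shape == tj.shape and np.array_equal(ti, tj)
    counts = np.zeros(params.n_bins, dtype=int)
    if ti.size == 0 or tj.size == 0:
        return _lag_centers(params), counts
    max_lag = max_lag_ms / 1000.0
    lo = np.searchsorted(tj, ti - max_lag, side="left")
    hi = np.searchsorted(tj, ti + max_lag, side="right")
    n_close = hi - lo
    src = np.repeat(np.arange(ti.size), n_close)
    dst = _ranges(lo, hi)
    dt_ms = (tj[dst] - ti[src]) * 1000.0
    if same:
        keep = src != dst
        dt_ms = dt_ms[keep]
    idx = np.floor((dt_ms + max_lag_ms) / bin_ms).astype(int)
    valid = (idx >= 0) & (idx < params.n_bins)
    np.add.at(counts, idx[valid], 1)
    return _lag_centers(params), counts


def _ranges(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Concatenate arange(lo[k], hi[k]) for all k, vectorised."""
    counts = np.maximum(hi - lo, 0)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=int)
    within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    return within + np.repeat(lo, counts)


def significance_threshold(train_i, train_j, bin_ms: float = 2.0,
                           max_lag_ms: float = 25.0, n_surrogates: int = 20,
                           jitter_ms: float = 25.0, c: float = 4.0,
                           seed: int = 0) -> float:
    """Surrogate-peak threshold for one pair of trains.

    Each surrogate displaces every spike of ``train_j`` independently by a
    uniform offset in +/-jitter and records the correlogram peak; the
    threshold is mean + c x sd over surrogates.
    """
    ti = np.asarray(train_i, dtype=float)
    tj = np.asarray(train_j, dtype=float)
    if ti.size == 0 or tj.size == 0:
        raise NoDataError("both trains must contain spikes")
    if n_surrogates < 10:
        raise InvalidArgumentError("need at least 10 surrogates")
    rng = np.random.default_rng(seed)
    peaks = np.empty(n_surrogates)
    for s in range(n_surrogates):
        shifted = np.sort(tj + rng.uniform(-jitter_ms, jitter_ms, tj.size) / 1000.0)
        _, counts = cross_correlogram(ti, shifted, bin_ms, max_lag_ms)
        peaks[s] = counts.max()
    return float(peaks.mean() + c * peaks.std(ddof=1))


@dataclass
class FunctionalGraph:
    """Directed functional-connectivity graph over active electrodes.

    Edge attributes: ``weight`` (peak count over the geometric mean of the
    two spike counts), ``lag_ms`` (signed lag of the significant peak) and
    ``mutual`` (True when the peak sat in the zero-lag bin).
    """

    graph: nx.DiGraph
    params: ConnectivityParams
    roles: dict[int, str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def role_counts(self) -> dict[str, int]:
        out = {"sender": 0, "receiver": 0, "broker": 0}
        for r in self.roles.values():
            out[r] += 1
        return out


def infer_graph(raster: SpikeRaster,
                params: ConnectivityParams | None = None) -> FunctionalGraph:
    """Infer the directed functional graph of one recording.

    All electrode pairs are processed in a single vectorised pass: every
    ordered spike pair closer than ``max_lag + jitter`` is enumerated
    once, then the observed correlogram and all surrogate correlograms
    are accumulated from that pair list.  Surrogates jitter the spikes of
    the higher-numbered electrode of each pair, matching the pairwise
    definition of :func:`significance_threshold`.
    """
    if params is None:
        params = ConnectivityParams()
    rng = np.random.default_rng(params.seed)
    g = nx.DiGraph()
    active = active_electrodes(raster, params.min_rate)
    pos = {int(i): tuple(raster.layout.positions[i]) for i in active}
    g.add_nodes_from((int(i), {"pos": pos[int(i)]}) for i in active)

    times, ids = raster.events()
    keep = np.isin(ids, active)
    times, ids = times[keep], ids[keep]
    result = FunctionalGraph(graph=g, params=params)
    if times.size < 2:
        return result

    window = (params.max_lag_ms + params.jitter_ms) / 1000.0
    hi = np.searchsorted(times, times + window, side="right")
    lo = np.arange(times.size) + 1
    src = np.repeat(np.arange(times.size), np.maximum(hi - lo, 0))
    dst = _ranges(lo, hi)
    ei, ej = ids[src], ids[dst]
    cross = ei != ej
    src, dst, ei, ej = src[cross], dst[cross], ei[cross], ej[cross]
    # orient every pair as (low id, high id); dt = t(high) - t(low)
    swap = ei > ej
    p_lo = np.where(swap, ej, ei)
    p_hi = np.where(swap, ei, ej)
    dt_ms = (times[dst] - times[src]) * 1000.0
    dt_ms[swap] *= -1.0
    jit_spike = np.where(swap, src, dst)      # spike of the higher-id train

    n_e = raster.layout.n_electrodes
    pair_code = p_lo.astype(np.int64) * n_e + p_hi
    pairs, pair_idx = np.unique(pair_code, return_inverse=True)
    n_pairs = pairs.size
    n_bins = params.n_bins
    counts_sp = raster.spike_counts()

    # shift lags so that truncation equals floor; bin b is valid in [0, n_bins)
    shift = (np.ceil((params.max_lag_ms + params.jitter_ms)
                     / params.bin_ms) + 1) * params.bin_ms
    shift_bins = int(round(shift / params.bin_ms))
    dt32 = (dt_ms + (params.max_lag_ms + shift)).astype(np.float32)
    inv_bin = np.float32(1.0 / params.bin_ms)
    base_key = (pair_idx * n_bins).astype(np.int64)

    def histogram(offset: np.ndarray | None) -> np.ndarray:
        d = dt32 if offset is None else dt32 + offset
        b = (d * inv_bin).astype(np.int64) - shift_bins
        ok = (b >= 0) & (b < n_bins)
        flat = np.bincount(base_key[ok] + b[ok], minlength=n_pairs * n_bins)
        return flat.reshape(n_pairs, n_bins)

    base = histogram(None)
    peak = base.max(axis=1)
    peak_bin = base.argmax(axis=1)

    s1 = np.zeros(n_pairs)
    s2 = np.zeros(n_pairs)
    for _ in range(params.n_surrogates):
        u = rng.uniform(-params.jitter_ms, params.jitter_ms,
                        size=times.size).astype(np.float32)
        sp = histogram(u[jit_spike]).max(axis=1)
        s1 += sp
        s2 += sp**2
    m = s1 / params.n_surrogates
    var = np.maximum(s2 / params.n_surrogates - m**2, 0.0)
    sd = np.sqrt(var * params.n_surrogates / max(params.n_surrogates - 1, 1))
    thr = m + params.c * sd

    total = base.sum(axis=1)
    centers = _lag_centers(params)
    zero_bin = int(np.flatnonzero((params.edges_ms[:-1] <= 0)
                                  & (params.edges_ms[1:] > 0))[0])
    sig = (peak > thr) & (total >= params.min_pair_count)
    for p in np.flatnonzero(sig):
        i = int(pairs[p] // n_e)
        j = int(pairs[p] % n_e)
        lag = float(centers[peak_bin[p]])
        w = float(peak[p] / np.sqrt(counts_sp[i] * counts_sp[j]))
        if peak_bin[p] == zero_bin:
            g.add_edge(i, j, weight=w, lag_ms=0.0, mutual=True)
            g.add_edge(j, i, weight=w, lag_ms=0.0, mutual=True)
        elif lag > 0:        # low-id train leads
            g.add_edge(i, j, weight=w, lag_ms=lag, mutual=False)
        else:
            g.add_edge(j, i, weight=w, lag_ms=-lag, mutual=False)
    result.roles = classify_node_roles(g)
    return result


def classify_node_roles(graph: nx.DiGraph) -> dict[int, str]:
    """Sender / receiver / broker labels from the degree balance."""
    roles = {}
    for n in graph.nodes:
        out_d, in_d = graph.out_degree(n), graph.in_degree(n)
        if out_d + in_d == 0:
            continue
        if out_d > in_d:
            roles[n] = "sender"
        elif in_d > out_d:
            roles[n] = "receiver"
        else:
            roles[n] = "broker"
    return roles
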