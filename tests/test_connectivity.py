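import networkx as nx
import numpy as np
import pytest

import meanet as m
from meanet.connectivity import ConnectivityParams
from meanet.errors import NoDataError

from conftest import build_raster


def brute_force_correlogram(ti, tj, bin_ms, max_lag_ms, exclude_self=False):
    """O(n^2) double-loop pair counter: the independent oracle."""
    n_bins = int(np.ceil(2 * max_lag_ms / bin_ms))
    counts = np.zeros(n_bins, dtype=int)
    for a, t_a in enumerate(ti):
        for b, t_b in enumerate(tj):
            if exclude_self and a == b:
                continue
            lag = (t_b - t_a) * 1000.0
            idx = int(np.floor((lag + max_lag_ms) / bin_ms))
            if 0 <= idx < n_bins:
                counts[idx] += 1
    return counts


class TestCrossCorrelogram:
    def test_matches_double_loop_oracle(self, rng):
        for _ in range(25):
            ti = np.sort(rng.uniform(0, 5, rng.integers(1, 80)))
            tj = np.sort(rng.uniform(0, 5, rng.integers(1, 80)))
            _, got = m.cross_correlogram(ti, tj, bin_ms=2.0, max_lag_ms=25.0)
            want = brute_force_correlogram(ti, tj, 2.0, 25.0)
            assert got.tolist() == want.tolist()

    def test_autocorrelogram_excludes_self_pairs(self, rng):
        t = np.sort(rng.uniform(0, 10, 50))
        lags, got = m.cross_correlogram(t, t, bin_ms=2.0, max_lag_ms=25.0)
        want = brute_force_correlogram(t, t, 2.0, 25.0, exclude_self=True)
        assert got.tolist() == want.tolist()

    def test_shifted_train_peaks_at_plus_5ms(self, rng):
        ti = np.sort(rng.uniform(0, 50, 200))
        tj = ti + 0.0055
        lags, counts = m.cross_correlogram(ti, tj, bin_ms=1.0, max_lag_ms=25.0)
        assert lags[np.argmax(counts)] == pytest.approx(5.5)
        assert counts.max() >= 200

    def test_swapping_trains_mirrors_lags(self, rng):
        ti = np.sort(rng.uniform(0, 5, 40))
        tj = np.sort(rng.uniform(0, 5, 40))
        _, ab = m.cross_correlogram(ti, tj, bin_ms=5.0, max_lag_ms=25.0)
        _, ba = m.cross_correlogram(tj, ti, bin_ms=5.0, max_lag_ms=25.0)
        assert ab.tolist() == ba[::-1].tolist()


class TestSignificanceThreshold:
    def test_deterministic_under_seed(self, rng):
        ti = np.sort(rng.uniform(0, 30, 60))
        tj = np.sort(rng.uniform(0, 30, 60))
        t1 = m.significance_threshold(ti, tj, seed=4)
        t2 = m.significance_threshold(ti, tj, seed=4)
        assert t1 == t2

    def test_locked_pair_exceeds_threshold(self, rng):
        ti = np.sort(rng.uniform(0, 60, 300))
        tj = ti + 0.005
        thr = m.significance_threshold(ti, tj, seed=0)
        _, counts = m.cross_correlogram(ti, tj)
        assert counts.max() > 2 * thr

    def test_false_positive_rate_at_c4(self):
        """Independent Poisson pairs clear the c=4 threshold rarely."""
        fp = 0
        rng = np.random.default_rng(2024)
        for trial in range(60):
            ti = np.sort(rng.uniform(0, 120, 120))
            tj = np.sort(rng.uniform(0, 120, 120))
            thr = m.significance_threshold(ti, tj, seed=trial)
            _, counts = m.cross_correlogram(ti, tj)
            fp += counts.max() > thr
        assert fp <= 3          # <= 5% of trials

    def test_empty_train_raises(self):
        with pytest.raises(NoDataError):
            m.significance_threshold([], [0.1, 0.2])


class TestInferGraph:
    def test_silent_raster_gives_empty_graph(self, layout10):
        r = build_raster(layout10, {}, 10.0)
        fg = m.infer_graph(r)
        assert fg.n_nodes == 0 and fg.n_edges == 0

    def test_three_node_chain_recovered_with_direction(self):
        layout = m.make_chip_layout(1, 3, 0.042)
        rng = np.random.default_rng(8)
        starts = np.arange(1.0, 280.0, 4.7)
        trains = {0: [], 1: [], 2: []}
        for s in starts:
            for e, onset in ((0, 0.0), (1, 0.005), (2, 0.010)):
                trains[e] += (s + onset + 0.001 * np.arange(3)).tolist()
                trains[e] += (s + onset + rng.uniform(0.003, 0.05, 4)).tolist()
        for e in range(3):
            trains[e] += rng.uniform(0, 300, 30).tolist()   # baseline noise
        r = build_raster(layout, trains, 300.0)
        fg = m.infer_graph(r)
        directed = {(u, v) for u, v, d in fg.graph.edges(data=True)
                    if not d["mutual"]}
        assert {(0, 1), (1, 2)} <= directed
        assert (1, 0) not in directed and (2, 1) not in directed

    def test_inference_deterministic(self, layout10):
        cfg = {c.div: c for c in m.phenotype_schedule("abeta42", 5)}[16]
        raster, _ = m.simulate_recording(cfg, layout10, 300.0)
        g1 = m.infer_graph(raster).graph
        g2 = m.infer_graph(raster).graph
        assert set(g1.edges) == set(g2.edges)

    def test_no_self_edges_and_weights_positive(self, layout10):
        cfg = {c.div: c for c in m.phenotype_schedule("abeta42", 0)}[16]
        raster, _ = m.simulate_recording(cfg, layout10, 300.0)
        fg = m.infer_graph(raster)
        assert fg.n_edges > 0
        for u, v, d in fg.graph.edges(data=True):
            assert u != v
            assert d["weight"] > 0


class TestNodeRoles:
    def test_star_hub_is_sender(self):
        g = nx.DiGraph([(0, i) for i in range(1, 6)])
        roles = m.classify_node_roles(g)
        assert roles[0] == "sender"
        assert all(roles[i] == "receiver" for i in range(1, 6))

    def test_two_cycle_gives_brokers(self):
        g = nx.DiGraph([(0, 1), (1, 0)])
        roles = m.classify_node_roles(g)
        assert roles == {0: "broker", 1: "broker"}

    def test_isolated_node_has_no_role(self):
        g = nx.DiGraph()
        g.add_node(9)
        g.add_edge(0, 1)
        roles = m.classify_node_roles(g)
        assert 9 not in roles
        assert set(roles) == {0, 1}
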