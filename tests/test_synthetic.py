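import networkx as nx
import numpy as np
import pytest

import meanet as m
from meanet.errors import InvalidArgumentError, PlacementError
from meanet.graphs import clustering_coefficient
from meanet.synthetic import _modular_directed, _ring_lattice_directed


class TestPhenotypeSchedule:
    def test_unknown_condition_rejected(self):
        with pytest.raises(InvalidArgumentError):
            m.phenotype_schedule("vehicle")

    def test_control_rates_strictly_increase(self):
        rates = [c.base_rate for c in m.phenotype_schedule("control")]
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_abeta_rates_biphasic_peak_div10(self):
        sched = {c.div: c for c in m.phenotype_schedule("abeta42")}
        rates = [sched[d].base_rate for d in (1, 4, 7, 10)]
        assert all(b > a for a, b in zip(rates, rates[1:]))
        assert sched[13].base_rate < sched[10].base_rate
        assert sched[16].base_rate < sched[13].base_rate

    def test_control_network_burst_counts(self):
        sched = {c.div: c for c in m.phenotype_schedule("control")}
        counts = [sched[d].n_network_bursts for d in m.DIVS]
        assert counts[0] == 0                       # silent at DIV1
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert sched[16].n_network_bursts >= 55

    def test_abeta_network_burst_counts_constant(self):
        sched = {c.div: c for c in m.phenotype_schedule("abeta42")}
        assert all(sched[d].n_network_bursts == 25 for d in (4, 7, 10, 13, 16))

    def test_control_homogeneous_from_div7(self):
        sched = {c.div: c for c in m.phenotype_schedule("control")}
        for d in (7, 10, 13, 16):
            assert sched[d].spatial_profile == ("homogeneous",)
        for d in (1, 4):
            assert sched[d].spatial_profile[0] == "localized"


class TestGroundTruthGraph:
    def test_pure_ring_lattice_is_regular(self):
        g = _ring_lattice_directed(30, 6, 0.0, np.random.default_rng(0))
        und = nx.Graph(g)
        assert all(d == 6 for _, d in und.degree())

    def test_full_modules_without_bridges_have_cc_one(self):
        g = _modular_directed(4, 5, inter_module_edges=0, topology="ring",
                              rng=np.random.default_rng(0))
        _, avg = clustering_coefficient(g)
        assert avg == 1.0

    def test_seed_determinism(self):
        cfg = m.phenotype_schedule("control")[2]
        g1 = m.generate_ground_truth_graph(cfg, n_electrodes=100)
        g2 = m.generate_ground_truth_graph(cfg, n_electrodes=100)
        assert set(g1.edges) == set(g2.edges)

    def test_mean_degree_must_be_below_n(self):
        with pytest.raises(InvalidArgumentError):
            _ring_lattice_directed(6, 6, 0.1, np.random.default_rng(0))

    def test_clustering_contrast_at_matched_div(self, layout10):
        """Treated-culture graphs cluster more than control at DIV >= 4."""
        ctl = {c.div: c for c in m.phenotype_schedule("control")}
        ab = {c.div: c for c in m.phenotype_schedule("abeta42")}
        for div in (4, 7, 10, 13, 16):
            _, cc_c = clustering_coefficient(
                m.generate_ground_truth_graph(ctl[div], 100))
            _, cc_a = clustering_coefficient(
                m.generate_ground_truth_graph(ab[div], 100))
            assert cc_a > cc_c, f"DIV{div}: {cc_a} <= {cc_c}"


class TestSimulateRecording:
    def test_zero_rate_zero_bursts_gives_empty_raster(self, layout10):
        cfg = m.PhenotypeConfig(
            condition="control", div=1, base_rate=0.0, rate_dispersion=0.0,
            n_network_bursts=0, burst_participation=0.0, within_burst_rate=0.0,
            burst_duration_mean_ms=0.0, spatial_profile=("homogeneous",),
            graph_params={"kind": "small_world", "mean_degree": 2,
                          "rewiring_prob": 0.0},
            propagation_delay_ms=5.0, seed=7)
        raster, truth = m.simulate_recording(cfg, layout10, 60.0)
        assert raster.n_spikes == 0
        assert truth.network_burst_windows == []

    def test_poisson_total_count_within_5_sd(self, layout10):
        # 100 electrodes x 300 s x 1 Hz: mean 30000, sd ~173
        raster = m.homogeneous_poisson_raster(layout10, 1.0, 300.0, seed=11)
        assert abs(raster.n_spikes - 30000) < 5 * np.sqrt(30000)

    def test_embedded_windows_count_and_disjoint(self, layout10):
        cfg = {c.div: c for c in m.phenotype_schedule("abeta42")}[16]
        _, truth = m.simulate_recording(cfg, layout10, 300.0)
        w = truth.network_burst_windows
        assert len(w) == 25
        assert all(b > a for a, b in w)
        assert all(w[i + 1][0] >= w[i][1] for i in range(len(w) - 1))
        assert w[0][0] >= 0 and w[-1][1] <= 300.0

    def test_bit_identical_under_same_seed(self, layout10):
        cfg = {c.div: c for c in m.phenotype_schedule("control")}[10]
        r1, _ = m.simulate_recording(cfg, layout10, 120.0)
        r2, _ = m.simulate_recording(cfg, layout10, 120.0)
        assert r1.equals(r2)

    def test_rate_recovery_on_burst_free_raster(self, layout10):
        raster = m.homogeneous_poisson_raster(layout10, 1.0, 300.0, seed=3)
        empirical = raster.n_spikes / (300.0 * raster.n_electrodes)
        assert abs(empirical - 1.0) < 0.05

    def test_weight_map_variance_contrast(self, layout10):
        """Localized treated cultures have patchier weights at every DIV."""
        for i in range(6):
            cfg_c = m.phenotype_schedule("control")[i]
            cfg_a = m.phenotype_schedule("abeta42")[i]
            w_c = m.spatial_weight_map(cfg_c, layout10)
            w_a = m.spatial_weight_map(cfg_a, layout10)
            assert w_a.var() > w_c.var()

    def test_impossible_burst_placement_raises(self, layout10):
        cfg = {c.div: c for c in m.phenotype_schedule("control")}[16]
        with pytest.raises(PlacementError):
            m.simulate_recording(cfg, layout10, 20.0)   # 55 bursts won't fit

    def test_spikes_strictly_inside_recording(self, layout10):
        cfg = {c.div: c for c in m.phenotype_schedule("abeta42")}[10]
        raster, _ = m.simulate_recording(cfg, layout10, 300.0)
        raster.validate()
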