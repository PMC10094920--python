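import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import meanet as m
from meanet.errors import InvalidArgumentError, NoDataError

from conftest import build_raster


def uniform_raster(layout, spikes_per_electrode, duration):
    trains = {i: np.linspace(0.01, duration - 0.01, spikes_per_electrode)
              for i in range(layout.n_electrodes)}
    return build_raster(layout, trains, duration)


class TestCenterOfActivity:
    def test_uniform_activity_centres_on_origin(self, layout10):
        r = uniform_raster(layout10, 5, 1.0)
        points = m.center_of_activity(r, (0.0, 1.0), bin_ms=1000.0)
        assert len(points) == 1
        assert abs(points[0].x) < 1e-12 and abs(points[0].y) < 1e-12

    def test_point_mass_gives_electrode_position(self, layout10):
        r = build_raster(layout10, {37: [0.1, 0.2, 0.3]}, 1.0)
        p = m.center_of_activity(r, (0.0, 1.0), bin_ms=1000.0)[0]
        assert (p.x, p.y) == pytest.approx(tuple(layout10.positions[37]), abs=1e-12)

    def test_weighted_mean_of_two_electrodes(self):
        layout = m.make_chip_layout(1, 3, 1.0)    # x positions -1, 0, +1
        r = build_raster(layout, {0: [0.1, 0.2, 0.3], 2: [0.15]}, 1.0)
        p = m.center_of_activity(r, (0.0, 1.0), bin_ms=1000.0)[0]
        assert p.x == pytest.approx(-0.5)
        r2 = build_raster(layout, {0: [0.1], 2: [0.15]}, 1.0)
        assert m.center_of_activity(r2, (0.0, 1.0), bin_ms=1000.0)[0].x == 0.0

    def test_empty_bins_flagged_not_interpolated(self, layout10):
        r = build_raster(layout10, {0: [0.05, 0.25]}, 0.3)
        pts = m.center_of_activity(r, (0.0, 0.3), bin_ms=100.0)
        assert [p.defined for p in pts] == [True, False, True]
        assert np.isnan(pts[1].x)

    def test_window_outside_recording_rejected(self, layout10):
        r = build_raster(layout10, {0: [0.1]}, 1.0)
        with pytest.raises(InvalidArgumentError):
            m.center_of_activity(r, (0.5, 1.5))

    def test_ca_inside_convex_hull(self, layout10, rng):
        """CA never leaves the hull: here, the grid bounding box."""
        xmax = layout10.positions[:, 0].max()
        for _ in range(20):
            ids = rng.integers(0, 100, 30)
            trains = {}
            for i in ids:
                trains.setdefault(int(i), []).append(float(rng.uniform(0, 1)))
            r = build_raster(layout10, trains, 1.0)
            for p in m.center_of_activity(r, (0.0, 1.0), bin_ms=100.0):
                if p.defined:
                    assert abs(p.x) <= xmax + 1e-12
                    assert abs(p.y) <= xmax + 1e-12

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(-2, 2), st.floats(-2, 2))
    def test_translation_equivariance(self, dx, dy):
        layout = m.make_chip_layout(4, 4, 0.5)
        trains = {0: [0.1, 0.4], 5: [0.2], 12: [0.3, 0.35, 0.45]}
        r = build_raster(layout, trains, 1.0)
        p0 = m.center_of_activity(r, (0.0, 1.0), bin_ms=1000.0)[0]
        shifted = m.ElectrodeLayout(
            n_rows=4, n_cols=4, pitch_mm=0.5,
            positions=layout.positions + np.array([dx, dy]))
        r2 = m.SpikeRaster(layout=shifted, duration_s=1.0,
                           spikes=[np.asarray(t) for t in r.spikes])
        p1 = m.center_of_activity(r2, (0.0, 1.0), bin_ms=1000.0)[0]
        assert p1.x == pytest.approx(p0.x + dx, abs=1e-9)
        assert p1.y == pytest.approx(p0.y + dy, abs=1e-9)

    def test_count_scaling_leaves_ca_unchanged(self, layout10):
        trains = {3: [0.1], 17: [0.2], 44: [0.3]}
        r1 = build_raster(layout10, trains, 1.0)
        tripled = {k: sorted(v * 3) for k, v in
                   {3: [0.1], 17: [0.2], 44: [0.3]}.items()}
        r3 = build_raster(layout10, tripled, 1.0)
        p1 = m.center_of_activity(r1, (0.0, 1.0), bin_ms=1000.0)[0]
        p3 = m.center_of_activity(r3, (0.0, 1.0), bin_ms=1000.0)[0]
        assert (p1.x, p1.y) == pytest.approx((p3.x, p3.y))


class TestComputeCat:
    def test_stationary_trajectory(self, layout10):
        trains = {55: np.arange(0.005, 0.1, 0.01)}
        r = build_raster(layout10, trains, 1.0)
        traj = m.compute_cat(r, (0.0, 0.1), bin_ms=10.0)
        assert traj.path_length_mm == pytest.approx(0.0)
        assert traj.mean_velocity_mm_s == pytest.approx(0.0)
        assert not traj.degenerate

    def test_constant_step_velocity(self):
        layout = m.make_chip_layout(1, 6, 0.1)    # 0.1 mm apart along x
        trains = {i: [0.005 + 0.01 * i] for i in range(5)}
        r = build_raster(layout, trains, 1.0)
        traj = m.compute_cat(r, (0.0, 0.05), bin_ms=10.0)
        assert traj.duration_ms == pytest.approx(40.0)
        assert traj.path_length_mm == pytest.approx(0.4)
        assert traj.mean_velocity_mm_s == pytest.approx(10.0)

    def test_single_point_degenerate(self, layout10):
        r = build_raster(layout10, {0: [0.005]}, 1.0)
        traj = m.compute_cat(r, (0.0, 0.05), bin_ms=10.0)
        assert traj.degenerate
        assert traj.terminal_distance_mm == pytest.approx(
            np.linalg.norm(layout10.positions[0]))

    def test_velocity_equals_path_over_duration(self, layout10, rng):
        trains = {int(i): rng.uniform(0, 0.2, 5).tolist()
                  for i in rng.integers(0, 100, 20)}
        r = build_raster(layout10, trains, 1.0)
        traj = m.compute_cat(r, (0.0, 0.2), bin_ms=10.0)
        if not traj.degenerate and traj.duration_ms > 0:
            assert traj.mean_velocity_mm_s == pytest.approx(
                traj.path_length_mm / (traj.duration_ms / 1000.0))


class TestCatSummary:
    def test_single_trajectory_summary(self, layout10):
        trains = {55: np.arange(0.005, 0.1, 0.01).tolist(),
                  60: np.arange(0.006, 0.1, 0.01).tolist()}
        r = build_raster(layout10, trains, 1.0)
        traj = m.compute_cat(r, (0.0, 0.1), bin_ms=10.0)
        summary = m.cat_summary([traj])
        assert summary["velocity_mm_s"].mean == pytest.approx(
            traj.mean_velocity_mm_s)
        assert summary["duration_ms"].n == 1

    def test_degenerate_excluded_from_n(self, layout10):
        good = m.compute_cat(
            build_raster(layout10, {1: np.arange(0.005, 0.1, 0.01)}, 1.0),
            (0.0, 0.1), bin_ms=10.0)
        bad = m.compute_cat(build_raster(layout10, {0: [0.005]}, 1.0),
                            (0.0, 0.05), bin_ms=10.0)
        summary = m.cat_summary([good, bad])
        assert summary["velocity_mm_s"].n == 1

    def test_all_degenerate_raises(self, layout10):
        bad = m.compute_cat(build_raster(layout10, {0: [0.005]}, 1.0),
                            (0.0, 0.05), bin_ms=10.0)
        with pytest.raises(NoDataError):
            m.cat_summary([bad])
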