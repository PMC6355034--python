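"""Kinematic parameters: closed forms, brute-force oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st
from shapely.geometry import LineString

from casakit import AnalysisSettings, SimulationParams, simulate_population
from casakit.kinematics import (
    alh,
    analyze_track,
    average_path,
    bcf,
    classify,
    dnc,
    fractal_dimension,
    lateral_distances,
    mad,
    ratios,
    summarize,
    velocities,
)
from conftest import make_traj


def straight_traj(n=10, step=1.0):
    return make_traj(np.column_stack([np.arange(n) * step, np.zeros(n)]))


class TestAveragePath:
    def test_three_point_example(self):
        t = make_traj([[0, 0], [1, 1], [2, 0]])
        np.testing.assert_allclose(average_path(t, 2), [[0.5, 0.5], [1.5, 0.5]])

    def test_constant_trajectory_stays_constant(self):
        t = make_traj(np.tile([3.0, 4.0], (12, 1)))
        path = average_path(t, 5)
        assert path.shape == (8, 2)
        np.testing.assert_allclose(path, np.tile([3.0, 4.0], (8, 1)))

    def test_window_out_of_range_rejected(self):
        t = straight_traj(5)
        for w in (1, 5, 6):
            with pytest.raises(ValueError):
                average_path(t, w)

    def test_smoothing_shrinks_fast_oscillation(self):
        x = np.arange(64, dtype=float)
        y = 2.0 * np.sin(2 * np.pi * x / 4)  # period 4 << w = 16
        t = make_traj(np.column_stack([x, y]))
        path = average_path(t, 16)
        assert np.abs(path[:, 1]).max() < 0.2 * 2.0


class TestVelocities:
    def test_straight_line_all_equal(self, settings):
        st_ = settings.replace(fps=1.0, um_per_px=1.0, window_size=2)
        t = straight_traj(10)
        path = average_path(t, 2)
        vsl, vcl, vap = velocities(t, path, st_)
        assert vsl == pytest.approx(1.0)
        assert vcl == pytest.approx(1.0)
        assert vap == pytest.approx(1.0)

    def test_zigzag_vcl_exceeds_vsl(self, settings):
        pts = [[i, i % 2] for i in range(10)]
        t = make_traj(pts)
        vsl, vcl, _ = velocities(t, average_path(t, 2), settings)
        assert vcl > vsl

    def test_simulated_straight_swimmer_vcl(self):
        st_ = AnalysisSettings(fps=60.0, um_per_px=0.5)
        p = SimulationParams(D_rot=0.0, v0=3.0, n_cells=1, n_frames=30, seed=0)
        traj = simulate_population(p)[0]
        vsl, vcl, vap = velocities(traj, average_path(traj, 5), st_)
        assert vcl == pytest.approx(90.0)  # 3 px/frame * 60 fps * 0.5 µm/px
        assert vsl == pytest.approx(90.0)


class TestRatios:
    def test_straight_line_is_100_everywhere(self):
        assert ratios(2.0, 2.0, 2.0) == pytest.approx((100.0, 100.0, 100.0))

    def test_arithmetic_example(self):
        assert ratios(5.0, 10.0, 8.0) == pytest.approx((50.0, 80.0, 62.5))

    def test_undefined_reported_as_nan(self):
        lin, wob, str_ = ratios(0.0, 0.0, 0.0)
        assert np.isnan(lin) and np.isnan(wob) and np.isnan(str_)

    @given(
        vsl=st.floats(0.01, 100), vap=st.floats(0.01, 100), vcl=st.floats(0.01, 100)
    )
    @hyp_settings(max_examples=50, derandomize=True)
    def test_lin_equals_wob_times_str(self, vsl, vcl, vap):
        lin, wob, str_ = ratios(vsl, vcl, vap)
        assert lin == pytest.approx(wob * str_ / 100.0, rel=1e-9)


class TestALH:
    def test_straight_line_is_zero(self, settings):
        t = straight_traj(20)
        assert alh(t, average_path(t, 5), 1.0) == (0.0, 0.0)

    def test_max_at_least_mean(self, settings):
        rng = np.random.default_rng(3)
        t = make_traj(np.cumsum(rng.normal(size=(50, 2)), axis=0))
        mean_, max_ = alh(t, average_path(t, 5), 1.0)
        assert max_ >= mean_ >= 0.0

    def test_triangle_wave_bounded_by_twice_amplitude(self):
        # period-8 triangle wave of half-amplitude a; w spans one period, so
        # the average path hugs the axis and the lateral excursion is between
        # a (peak read against a slanted neighbour segment) and 2a
        a, w = 2.0, 8
        x = np.arange(64, dtype=float)
        tri = a * (2 * np.abs(2 * (x / 8 - np.floor(x / 8 + 0.5))) - 1)
        t = make_traj(np.column_stack([x, tri]))
        _, max_ = alh(t, average_path(t, w), 1.0)
        assert a <= max_ <= 2 * a * 1.05

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_alh_oracle(self, seed):
        """Full independent re-derivation: O(N·w) distance scan + local maxima."""
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(size=(40, 2)), axis=0)
        w, mu = 6, 0.7
        t = make_traj(pts)
        path = average_path(t, w)

        def seg_dist(p, a, b):
            ab = b - a
            if ab @ ab == 0:
                return np.linalg.norm(p - a)
            u = np.clip((p - a) @ ab / (ab @ ab), 0, 1)
            return np.linalg.norm(p - (a + u * ab))

        series = []
        for i in range(len(path) - 1):
            qm = (path[i] + path[i + 1]) / 2
            series.append(
                min(seg_dist(qm, pts[j], pts[j + 1]) for j in range(i, i + w - 1))
            )
        peaks = [
            series[i]
            for i in range(1, len(series) - 1)
            if series[i] > series[i - 1] and series[i] > series[i + 1]
        ]
        expect = (
            (2 * mu * np.mean(peaks), 2 * mu * np.max(peaks)) if peaks else (0.0, 0.0)
        )
        assert alh(t, path, mu) == pytest.approx(expect)

    def test_distance_series_matches_brute_force(self, settings):
        rng = np.random.default_rng(5)
        pts = np.cumsum(rng.normal(size=(30, 2)), axis=0)
        t = make_traj(pts)
        w = 5
        path = average_path(t, w)
        series = lateral_distances(pts, path, w)

        def seg_dist(p, a, b):
            ab = b - a
            if ab @ ab == 0:
                return np.linalg.norm(p - a)
            u = np.clip((p - a) @ ab / (ab @ ab), 0, 1)
            return np.linalg.norm(p - (a + u * ab))

        for i in range(len(path) - 1):
            qm = (path[i] + path[i + 1]) / 2
            expect = min(
                seg_dist(qm, pts[j], pts[j + 1]) for j in range(i, i + w - 1)
            )
            assert series[i] == pytest.approx(expect, abs=1e-12)


def _bcf_oracle(pts, path):
    """Count proper crossings with shapely (touch/overlap excluded)."""
    count = 0
    for i in range(len(pts) - 1):
        raw = LineString([pts[i], pts[i + 1]])
        for j in range(len(path) - 1):
            if raw.crosses(LineString([path[j], path[j + 1]])):
                count += 1
    return count


class TestBCF:
    def test_straight_line_zero(self, settings):
        st_ = settings.replace(fps=1.0)
        t = straight_traj(20)
        assert bcf(t, average_path(t, 5), st_) == 0.0

    def test_disjoint_paths_zero(self, settings):
        t = straight_traj(20)
        shifted = average_path(t, 5) + [0.0, 50.0]
        assert bcf(t, shifted, settings) == 0.0

    def test_zigzag_hand_count(self, settings):
        st_ = settings.replace(fps=1.0)
        # w=3 keeps the average path off the raw segments, so the zig-zag
        # crossings are transversal rather than endpoint touches
        pts = np.column_stack([np.arange(10, dtype=float),
                               np.tile([1.0, -0.6], 5)])
        t = make_traj(pts)
        path = average_path(t, 3)
        n, w = 10, 3
        expect = _bcf_oracle(pts, path)
        assert expect > 0
        assert bcf(t, path, st_) == pytest.approx(expect * 1.0 / (n - w))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_walks(self, seed, settings):
        rng = np.random.default_rng(seed)
        n = 60
        pts = np.cumsum(rng.normal(size=(n, 2)), axis=0)
        t = make_traj(pts)
        path = average_path(t, settings.window_size)
        expect = _bcf_oracle(pts, path)
        got = bcf(t, path, settings)
        assert got == pytest.approx(expect * settings.fps / (n - settings.window_size))


class TestMAD:
    def test_straight_line_zero(self):
        assert mad(straight_traj(10)) == 0.0

    def test_single_right_angle_turn(self):
        t = make_traj([[0, 0], [1, 0], [2, 0], [2, 1]])
        # direction series: 0, 0, 90 -> turns 0, 90 -> mean 45
        assert mad(t, 1) == pytest.approx(45.0)

    @pytest.mark.parametrize("sides", [5, 6, 8])
    def test_regular_polygon_exterior_angle(self, sides):
        ang = np.linspace(0, 2 * np.pi, sides, endpoint=False)
        pts = np.column_stack([np.cos(ang), np.sin(ang)])
        pts = np.vstack([pts, pts[0]])
        assert mad(make_traj(pts), 1) == pytest.approx(360.0 / sides)

    def test_literal_mode_is_mean_direction(self):
        t = make_traj([[0, 0], [1, 0], [1, 1]])
        # vector angles: 0 and 90 degrees
        assert mad(t, 1, mode="literal") == pytest.approx(45.0)


class TestFractalDimension:
    def test_straight_line_is_one(self):
        assert fractal_dimension(straight_traj(20)) == pytest.approx(1.0)

    def test_at_least_one_for_random_walks(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pts = np.cumsum(rng.normal(size=(40, 2)), axis=0)
            assert fractal_dimension(make_traj(pts)) >= 1.0

    def test_confined_walk_approaches_two(self):
        # rotational diffusion dominates: the track folds onto itself
        p = SimulationParams(D_rot=5.0, v0=1.0, n_cells=1, n_frames=500, seed=0)
        traj = simulate_population(p)[0]
        assert fractal_dimension(traj) > 1.5

    def test_stationary_track_undefined(self):
        t = make_traj(np.zeros((5, 2)))
        assert np.isnan(fractal_dimension(t))


class TestClassify:
    def test_stationary_cell_never_motile(self, settings):
        pts = np.zeros((6, 2))
        pts[2] = [5.0, 0.0]  # moves but returns: p1 == pN
        t = make_traj(pts)
        motile, prog = classify(t, vcl=50.0, str_=90.0, vap=40.0, settings=settings)
        assert not motile and not prog

    def test_motile_and_progressive(self, settings):
        t = straight_traj(5)
        assert classify(t, 50.0, 90.0, 40.0, settings) == (True, True)

    def test_vcl_threshold_is_strict(self, settings):
        t = straight_traj(5)
        motile, _ = classify(t, settings.min_vcl, 90.0, 40.0, settings)
        assert not motile


class TestInvariants:
    def test_vsl_at_most_vcl_over_random_walks(self, settings):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            pts = np.cumsum(rng.normal(size=(20, 2)), axis=0)
            t = make_traj(pts)
            vsl, vcl, vap = velocities(t, average_path(t, 5), settings)
            assert vsl <= vcl + 1e-9
            assert vap <= vcl + 1e-9

    def test_straight_swimmer_closed_forms(self, settings):
        st_ = settings.replace(fps=1.0, window_size=5)
        t = straight_traj(30)
        r = analyze_track(t, st_)
        assert r.lin == pytest.approx(100.0)
        assert r.wob == pytest.approx(100.0)
        assert r.str_ == pytest.approx(100.0)
        assert r.alh_mean == r.alh_max == 0.0
        assert r.bcf == 0.0
        assert r.mad == pytest.approx(0.0)
        assert r.fd == pytest.approx(1.0)
        assert r.dnc == 0.0

    def test_unit_consistency_under_rescaling(self, settings):
        rng = np.random.default_rng(21)
        pts = np.cumsum(rng.normal(size=(40, 2)), axis=0) * 3
        c = 4.0
        a = analyze_track(make_traj(pts), settings)
        b = analyze_track(
            make_traj(pts * c), settings.replace(um_per_px=settings.um_per_px / c)
        )
        for f in ("vsl", "vcl", "vap", "lin", "wob", "str_", "alh_mean",
                  "alh_max", "bcf", "dnc", "mad", "fd"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), rel=1e-9), f

    def test_dnc_is_product(self):
        assert dnc(100.0, 2.0) == 200.0
        assert dnc(123.0, 0.0) == 0.0


def test_population_summary_excludes_nan_per_parameter(settings):
    t1 = straight_traj(30)  # well-defined everywhere
    t2 = make_traj(np.tile([1.0, 1.0], (30, 1)))  # stationary: ratios undefined
    rs = [analyze_track(t, settings.replace(min_vcl=0.0)) for t in (t1, t2)]
    out = summarize(rs)
    assert out["n_tracks"] == 2
    assert out["pct_motile"] == 50.0
    assert np.isfinite(out["mean_lin"])
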