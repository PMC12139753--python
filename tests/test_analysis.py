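import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fclsim.analysis import (
    FrameStats,
    area_stats,
    compare_groups,
    compute_tc,
    dwell_segments,
    hull_area,
    identify_clusters,
    most_possible_pattern,
    neighbor_counts,
    summarize,
)
from fclsim.model_core import SiteGeometryParams
from fclsim.synthetic_data import make_bond_graph


from helpers import (  # noqa: E402
    oracle_components as _oracle_components,
    oracle_hull_area as _oracle_hull_area,
)


# ---------------------------------------------------------------------------

class TestIdentifyClusters:
    def test_no_bonds_no_clusters(self):
        frame = make_bond_graph([1, 1, 1])
        cf = identify_clusters(frame, SiteGeometryParams(), min_cluster_size=5)
        assert cf.n_clusters == 0
        assert cf.n_membrane_clathrin == 3

    def test_threshold_counts_only_large_components(self):
        frame = make_bond_graph([30, 1])
        cf = identify_clusters(frame, SiteGeometryParams(), min_cluster_size=5)
        assert cf.n_clusters == 1
        assert cf.cluster_sizes == [30]

    def test_two_components(self):
        frame = make_bond_graph([12, 7])
        cf = identify_clusters(frame, SiteGeometryParams(), min_cluster_size=5)
        assert cf.n_clusters == 2
        assert sorted(cf.cluster_sizes) == [7, 12]

    def test_cytosolic_members_excluded(self):
        frame = make_bond_graph([8])
        frame.clat_mem[:] = False
        cf = identify_clusters(frame, SiteGeometryParams(), min_cluster_size=5)
        assert cf.n_clusters == 0

    def test_against_union_find_oracle_on_random_graphs(self):
        rng = np.random.default_rng(12)
        geom = SiteGeometryParams()
        for _ in range(1000):
            sizes = rng.integers(1, 9, size=rng.integers(1, 6)).tolist()
            frame = make_bond_graph(sizes)
            n = len(frame.clat_pos)
            edges = []
            for i in range(n):
                for s in range(3):
                    j = frame.leg_bond[i, s, 0]
                    if j >= 0 and i < j:
                        edges.append((i, int(j)))
            comps = _oracle_components(n, edges)
            min_size = int(rng.integers(1, 6))
            expect_sizes = sorted(len(c) for c in comps if len(c) >= min_size)
            cf = identify_clusters(frame, geom, min_cluster_size=min_size)
            assert sorted(cf.cluster_sizes) == expect_sizes


class TestHullArea:
    def test_single_point_disc(self):
        assert hull_area(np.array([[10.0, 20.0]]), pad=5.0) == pytest.approx(
            np.pi * 25.0, rel=1e-12
        )
        assert hull_area(np.array([[10.0, 20.0]]), pad=5.0) == pytest.approx(78.54, rel=1e-4)

    def test_square_no_pad(self):
        pts = np.array([[0, 0], [100.0, 0], [100.0, 100.0], [0, 100.0]])
        assert hull_area(pts, pad=0.0) == pytest.approx(1e4, rel=1e-12)
        # 1e4 nm^2 = 0.01 um^2
        assert hull_area(pts, pad=0.0) / 1e6 == pytest.approx(0.01)

    def test_collinear_segment(self):
        pts = np.array([[0.0, 0.0], [50.0, 0.0], [100.0, 0.0]])
        assert hull_area(pts, pad=5.0) == pytest.approx(
            2 * 5.0 * 100.0 + np.pi * 25.0, rel=1e-9
        )

    def test_against_hull_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            pts = rng.uniform(0, 500, size=(rng.integers(3, 50), 2))
            assert hull_area(pts, pad=0.0) == pytest.approx(
                _oracle_hull_area(pts), rel=1e-9
            )

    def test_pad_formula_on_triangle(self):
        pts = np.array([[0.0, 0.0], [30.0, 0.0], [0.0, 40.0]])
        pad = 5.0
        expect = 600.0 + (30 + 40 + 50) * pad + np.pi * pad**2
        assert hull_area(pts, pad) == pytest.approx(expect, rel=1e-12)


class TestComputeTc:
    def test_linear_ramp(self):
        times = np.arange(0.0, 1801.0, 1.0)
        counts = times / 1800.0 * 100.0
        assert compute_tc(times, counts, 1800.0) == pytest.approx(27.0 * 60.0)

    def test_constant_trace(self):
        times = np.array([0.0, 1.0, 2.0])
        counts = np.array([40.0, 40.0, 40.0])
        assert compute_tc(times, counts) == 0.0

    def test_zero_end_convention(self):
        times = np.array([0.0, 1.0, 2.0])
        counts = np.array([10.0, 5.0, 0.0])
        assert compute_tc(times, counts) == 0.0

    def test_empty_trace_errors(self):
        with pytest.raises(ValueError):
            compute_tc(np.array([]), np.array([]))


class TestMostPossiblePattern:
    def test_simple_mode(self):
        mode, freq = most_possible_pattern([2, 2, 1, 2, 2])
        assert mode == 2
        assert freq == {2: pytest.approx(0.8), 1: pytest.approx(0.2)}

    def test_constant_series(self):
        mode, freq = most_possible_pattern([3] * 10)
        assert mode == 3
        assert freq == {3: 1.0}

    def test_tie_breaks_toward_smaller(self):
        mode, _ = most_possible_pattern([1, 2, 1, 2])
        assert mode == 1

    def test_recovers_generator_mode(self):
        rng = np.random.default_rng(99)
        series = rng.choice([1, 2, 3], size=10**4, p=[0.3, 0.6, 0.1])
        mode, _ = most_possible_pattern(series)
        assert mode == 2


class TestDwellSegments:
    def test_rle_with_censoring(self):
        segs = dwell_segments([1, 1, 1, 2, 2], 0.1)
        assert [(s.value, pytest.approx(s.duration_s)) for s in segs] == [
            (1, pytest.approx(0.3)),
            (2, pytest.approx(0.2)),
        ]
        assert all(s.censored for s in segs)

    def test_constant_series_single_censored_run(self):
        segs = dwell_segments([4] * 20, 0.5)
        assert len(segs) == 1
        assert segs[0].duration_s == pytest.approx(10.0)
        assert segs[0].censored

    def test_geometric_runs_recover_mean(self):
        rng = np.random.default_rng(5)
        p_stay = 0.9  # mean run length 10
        n = 10**5
        series = np.empty(n, dtype=int)
        series[0] = 0
        flips = rng.random(n - 1) > p_stay
        series[1:] = (np.cumsum(flips) + 0) % 2
        dt = 0.1
        segs = dwell_segments(series, dt)
        durations = [s.duration_s for s in segs if not s.censored]
        mean_expected = dt / (1 - p_stay)
        se = np.std(durations, ddof=1) / np.sqrt(len(durations))
        assert abs(np.mean(durations) - mean_expected) < 3 * se

    @given(st.lists(st.integers(0, 4), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_rle_reconstructs_series(self, series):
        segs = dwell_segments(series, 1.0)
        rebuilt = []
        for s in segs:
            rebuilt.extend([s.value] * int(round(s.duration_s)))
        assert rebuilt == list(series)


class TestSummarize:
    def _hand_stats(self):
        # hand-worked 6-frame example (see assertions for the arithmetic)
        return FrameStats(
            times_s=np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0]),
            n_membrane=np.array([50, 90, 95, 95, 95, 95]),
            n_clusters=np.array([1, 2, 2, 1, 2, 1]),
            total_area_um2=np.array([0.02, 0.08, 0.06, 0.03, 0.10, 0.04]),
        )

    def test_hand_worked_example(self):
        stats = self._hand_stats()
        rep = summarize(stats, t_end_s=5.0)
        # end count 95 -> threshold 85.5 -> first crossing at t = 1
        assert rep.tc_s == pytest.approx(1.0)
        # post-tc cluster numbers [2,2,1,2,1]: mode 2 with frequency 3/5
        assert rep.modal_cluster_number == 2
        assert rep.cluster_number_freq[2] == pytest.approx(0.6)
        assert rep.cluster_number_freq[1] == pytest.approx(0.4)
        # modal frames t=1,2,4: mean of (0.08/2, 0.06/2, 0.10/2) = 0.04
        assert rep.mean_mean_cluster_size_um2 == pytest.approx(0.04)
        # segments of [2,2,1,2,1]: (2,2s,cens)(1,1s)(2,1s)(1,1s,cens)
        # uncensored modal dwell: the single 1 s run of value 2
        assert rep.mean_dwelling_time_s == pytest.approx(1.0)
        assert not rep.dwell_mean_censored_fallback

    def test_all_frames_identical(self):
        stats = FrameStats(
            times_s=np.arange(5.0),
            n_membrane=np.full(5, 80),
            n_clusters=np.full(5, 2),
            total_area_um2=np.full(5, 0.06),
        )
        rep = summarize(stats)
        assert rep.modal_cluster_number == 2
        assert rep.mean_mean_cluster_size_um2 == pytest.approx(0.03)
        # single fully censored run -> censored fallback mean = whole span
        assert rep.dwell_mean_censored_fallback
        assert rep.mean_dwelling_time_s == pytest.approx(5.0)

    def test_mode_zero_size_zero(self):
        stats = FrameStats(
            times_s=np.arange(4.0),
            n_membrane=np.full(4, 3),
            n_clusters=np.array([0, 0, 1, 0]),
            total_area_um2=np.array([0.0, 0.0, 0.01, 0.0]),
        )
        rep = summarize(stats)
        assert rep.modal_cluster_number == 0
        assert rep.mean_mean_cluster_size_um2 == 0.0

    def test_oversampling_invariance(self):
        stats = self._hand_stats()
        double = FrameStats(
            times_s=np.repeat(stats.times_s, 2) + np.tile([0.0, 0.5], 6),
            n_membrane=np.repeat(stats.n_membrane, 2),
            n_clusters=np.repeat(stats.n_clusters, 2),
            total_area_um2=np.repeat(stats.total_area_um2, 2),
        )
        r1 = summarize(stats, t_end_s=5.0)
        r2 = summarize(double, t_end_s=5.5)
        assert r1.modal_cluster_number == r2.modal_cluster_number
        assert r2.mean_mean_cluster_size_um2 == pytest.approx(
            r1.mean_mean_cluster_size_um2, rel=0.1
        )
        assert r2.mean_dwelling_time_s == pytest.approx(
            r1.mean_dwelling_time_s, rel=0.3
        )

    def test_no_frames_errors(self):
        with pytest.raises(ValueError):
            summarize(
                FrameStats(
                    times_s=np.array([]),
                    n_membrane=np.array([]),
                    n_clusters=np.array([]),
                    total_area_um2=np.array([]),
                )
            )


class TestNeighborCounts:
    def test_single_point(self):
        assert neighbor_counts(np.array([[0.5, 0.5]]))[0] == 0

    def test_two_points_inside_window(self):
        counts = neighbor_counts(np.array([[0.0, 0.0], [0.4, 0.0]]))
        np.testing.assert_array_equal(counts, [1, 1])

    def test_two_points_outside_window(self):
        counts = neighbor_counts(np.array([[0.0, 0.0], [0.6, 0.0]]))
        np.testing.assert_array_equal(counts, [0, 0])

    def test_grid_2x2(self):
        pts = np.array([[0.0, 0.0], [0.4, 0.0], [0.0, 0.4], [0.4, 0.4]])
        np.testing.assert_array_equal(neighbor_counts(pts), [3, 3, 3, 3])

    def test_against_double_loop(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            pts = rng.uniform(0, 5, size=(rng.integers(1, 80), 2))
            counts = neighbor_counts(pts, 1.0)
            for i in range(len(pts)):
                manual = 0
                for j in range(len(pts)):
                    if i != j and abs(pts[j, 0] - pts[i, 0]) <= 0.5 and abs(
                        pts[j, 1] - pts[i, 1]
                    ) <= 0.5:
                        manual += 1
                assert counts[i] == manual


class TestAreaStats:
    def test_single_value(self):
        s = area_stats([1.0])
        assert s["median"] == s["q1"] == s["q3"] == 1.0
        assert s["whisker_low"] == s["whisker_high"] == 1.0
        assert s["outliers"] == []

    def test_one_to_nine_type7_quartiles(self):
        # documented convention: linear interpolation (numpy default, type 7)
        s = area_stats(list(range(1, 10)))
        assert s["median"] == 5.0
        assert s["q1"] == 3.0
        assert s["q3"] == 7.0
        assert s["whisker_low"] == 1.0
        assert s["whisker_high"] == 9.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        vals = rng.lognormal(size=40)
        s1 = area_stats(vals)
        s2 = area_stats(rng.permutation(vals))
        assert s1 == s2

    def test_outlier_detection(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 100.0]
        s = area_stats(vals)
        assert s["outliers"] == [100.0]
        assert s["whisker_high"] == 5.0


class TestCompareGroups:
    def test_identical_groups(self):
        t, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = a + 10.0
        t, _ = compare_groups(a, b, welch=False)
        sp = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0)
        expect = (np.mean(a) - np.mean(b)) / (sp * np.sqrt(2.0 / 3.0))
        assert t == pytest.approx(expect, rel=1e-12)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 2, 6)
        t1, p1 = compare_groups(a, b)
        t2, p2 = compare_groups(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])
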