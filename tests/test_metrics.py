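import numpy as np
import pytest

from operant_arena import (
    NOSA,
    ROSA,
    Bout,
    OccupancySeries,
    bout_metrics,
    compute_metrics_record,
    duration_histogram,
    metric_time_series,
    occupancy_from_trajectory,
    operant_learning_index,
    pca_valence,
    preference_index,
    preference_index_from_occupancy,
    session_metrics,
)


class TestSessionMetrics:
    def test_toy_path_hand_arithmetic(self, geom, make_traj):
        traj = make_traj([1, 6, 7, 7, 4, 8])
        occ = occupancy_from_trajectory(traj, geom)
        m = session_metrics(traj, occ, geom, ROSA)
        assert m["total_time_s"] == pytest.approx(4.0)
        assert m["total_distance"] == pytest.approx(10.0)  # 5 + 1 + 0 + 4
        assert m["max_depth"] == pytest.approx(3.0)

    def test_never_entering_fly(self, geom, make_traj):
        traj = make_traj([1, 2, 3])
        occ = occupancy_from_trajectory(traj, geom)
        m = session_metrics(traj, occ, geom, ROSA)
        assert (m["total_time_s"], m["total_distance"], m["max_depth"]) == (0, 0, 0)

    def test_region_times_conserve_session(self, geom, make_traj):
        traj = make_traj(np.linspace(0.5, 9.5, 40), fps=2.0)
        occ = occupancy_from_trajectory(traj, geom)
        t_rosa = session_metrics(traj, occ, geom, ROSA)["total_time_s"]
        t_nosa = session_metrics(traj, occ, geom, NOSA)["total_time_s"]
        assert t_rosa + t_nosa == pytest.approx(traj.duration_s)


class TestBoutMetrics:
    def test_means(self):
        bouts = [Bout(ROSA, 0, 2, fps=1.0, distance=3.0), Bout(ROSA, 3, 4, fps=1.0, distance=1.0)]
        m = bout_metrics(bouts, np.array([1.0]))
        assert m["n_bouts"] == 2
        assert m["mean_bout_duration_s"] == pytest.approx(1.5)
        assert m["mean_bout_distance"] == pytest.approx(2.0)
        assert m["mean_latency_s"] == pytest.approx(1.0)

    def test_no_bouts_undefined_not_zero(self):
        m = bout_metrics([], np.empty(0))
        assert m["n_bouts"] == 0
        assert m["mean_bout_duration_s"] is None
        assert m["mean_latency_s"] is None


class TestDurationHistogram:
    def test_default_edges(self):
        counts = duration_histogram(np.array([2.0, 7.0, 31.0]))
        np.testing.assert_array_equal(counts, [1, 1, 0, 0, 0, 0, 1])

    def test_empty(self):
        assert duration_histogram(np.empty(0)).sum() == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        durations = rng.exponential(10.0, 500)
        edges = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
        counts = duration_histogram(durations, edges)
        brute = [
            sum(1 for d in durations if lo <= d < hi)
            for lo, hi in zip(edges, list(edges[1:]) + [np.inf])
        ]
        np.testing.assert_array_equal(counts, brute)
        assert counts.sum() == 500

    def test_non_monotone_edges(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            duration_histogram(np.array([1.0]), edges=(0.0, 5.0, 5.0))


class TestPreferenceIndex:
    @pytest.mark.parametrize(
        "r, n, expected", [(300, 120, 3.0 / 7.0), (420, 0, 1.0), (0, 10, -1.0), (5, 5, 0.0)]
    )
    def test_formula(self, r, n, expected):
        assert preference_index(r, n) == pytest.approx(expected)

    def test_undefined_when_empty(self):
        assert preference_index(0, 0) is None

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            preference_index(-1.0, 5.0)

    def test_equals_two_occupancy_minus_one(self, random_occupancy):
        """PI over a window is algebraically 2 * (window occupancy) - 1."""
        for seed in range(100):
            occ = random_occupancy(900, fps=1.0, p=0.3, seed=seed)
            pi = preference_index_from_occupancy(occ, window=(480.0, 900.0))
            frac = occ.values[480:900].mean()
            assert pi == pytest.approx(2 * frac - 1)

    def test_monotone_in_rosa_time(self):
        """Growing a ROSA residence (NoSA time fixed elsewhere) never lowers PI."""
        base = np.zeros(900, dtype=bool)
        base[500:520] = True
        prev = -1.0
        for grow in (0, 40, 120, 300):
            v = base.copy()
            v[500 : 520 + grow] = True
            pi = preference_index_from_occupancy(OccupancySeries(v, 1.0), (480.0, 900.0))
            assert pi >= prev
            prev = pi


class TestOperantLearningIndex:
    @pytest.mark.parametrize("late, early, expected", [(30, 10, 0.5), (7, 7, 0.0), (0, 30, -1.0)])
    def test_formula(self, late, early, expected):
        assert operant_learning_index(late, early) == pytest.approx(expected)

    def test_degenerate_undefined(self):
        assert operant_learning_index(0.0, 0.0) is None

    def test_negative_rejected_unless_allowed(self):
        with pytest.raises(ValueError):
            operant_learning_index(-1.0, 2.0)
        assert operant_learning_index(-1.0, 2.0, allow_negative=True) == pytest.approx(-3.0)


class TestMetricTimeSeries:
    def test_time_isolated_to_one_bin(self, geom):
        v = np.zeros(900, dtype=bool)
        v[60:120] = True
        occ = OccupancySeries(v, fps=1.0)
        x = np.where(v, 7.0, 2.0)
        from operant_arena import trajectory_from_arrays

        traj = trajectory_from_arrays(x, np.ones_like(x), fps=1.0)
        ts = metric_time_series(traj, occ, geom, "time", bin_seconds=60.0)
        assert ts[1] == pytest.approx(60.0)
        assert ts.sum() == pytest.approx(60.0)

    def test_binned_sums_conserve_session_totals(self, geom, make_traj):
        rng = np.random.default_rng(2)
        traj = make_traj(rng.uniform(0.2, 9.8, 900), rng.uniform(0.2, 1.8, 900), fps=15.0)
        occ = occupancy_from_trajectory(traj, geom)
        sess = session_metrics(traj, occ, geom, ROSA)
        ts = metric_time_series(traj, occ, geom, "time")
        ds = metric_time_series(traj, occ, geom, "distance")
        assert ts.sum() == pytest.approx(sess["total_time_s"])
        assert ds.sum() == pytest.approx(sess["total_distance"])
        depth = metric_time_series(traj, occ, geom, "depth")
        assert depth.max() == pytest.approx(sess["max_depth"])

    def test_matches_brute_force_bins(self, geom, make_traj):
        rng = np.random.default_rng(9)
        traj = make_traj(rng.uniform(0.2, 9.8, 300), fps=5.0)
        occ = occupancy_from_trajectory(traj, geom)
        ts = metric_time_series(traj, occ, geom, "time", bin_seconds=10.0)
        per_bin = 50
        brute = [
            occ.values[k * per_bin : (k + 1) * per_bin].sum() / 5.0 for k in range(6)
        ]
        np.testing.assert_allclose(ts, brute)

    def test_unknown_metric(self, geom, make_traj):
        traj = make_traj([1.0, 2.0])
        occ = occupancy_from_trajectory(traj, geom)
        with pytest.raises(ValueError, match="unknown metric"):
            metric_time_series(traj, occ, geom, "altitude")


class TestComputeMetricsRecord:
    def test_full_record_consistency(self, geom):
        rng = np.random.default_rng(4)
        from operant_arena import trajectory_from_arrays

        traj = trajectory_from_arrays(
            rng.uniform(0.2, 9.8, 13500), rng.uniform(0.2, 1.8, 13500), fps=15.0
        )
        occ = occupancy_from_trajectory(traj, geom)
        rec, bouts = compute_metrics_record(traj, occ, geom, ROSA)
        assert rec.n_bouts == len(bouts)
        assert rec.duration_histogram.sum() == rec.n_bouts
        assert -1 <= rec.preference_index <= 1
        for oli in (rec.oli_time, rec.oli_distance, rec.oli_depth):
            assert oli is None or -1 <= oli <= 1
        assert rec.time_series.sum() == pytest.approx(rec.total_time_s)
        # bout durations sum to total region time when nothing is discarded
        assert sum(b.duration_s for b in bouts) == pytest.approx(rec.total_time_s)


class TestPCA:
    def test_perfectly_correlated_columns(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        X = np.column_stack([a, 2 * a + 3])
        res = pca_valence(X)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_orthonormal_loadings_and_total_variance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 5))
        res = pca_valence(X)
        np.testing.assert_allclose(
            res.loadings @ res.loadings.T, np.eye(len(res.loadings)), atol=1e-10
        )
        assert res.explained_variance.sum() == pytest.approx(5.0)

    def test_matches_correlation_eigendecomposition(self):
        """Agreement with a brute-force eigendecomposition of corrcoef."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 6))
        res = pca_valence(X)
        corr = np.corrcoef(X, rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        np.testing.assert_allclose(res.explained_variance, evals[: len(res.explained_variance)], atol=1e-8)

    def test_sign_convention(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 4))
        res = pca_valence(X)
        for row in res.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([rng.normal(size=15), np.full(15, 2.0), rng.normal(size=15)])
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca_valence(X, ["a", "const", "b"])
        assert res.columns == ["a", "b"]
        assert res.dropped_columns == ["const"]

    def test_nan_rows_dropped_and_reported(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 3))
        X[4, 1] = np.nan
        res = pca_valence(X)
        assert res.dropped_rows == [4]
        assert res.scores.shape[0] == 11

    def test_kaiser_retention(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=50)
        X = np.column_stack([a + 0.1 * rng.normal(size=50) for _ in range(3)] + [rng.normal(size=50)])
        res = pca_valence(X)
        assert res.retained[0]
        assert res.retained.sum() < len(res.explained_variance)
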