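import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from naiveomics.preprocess import TrajectoryMatrix
from naiveomics.trend_overlap import (gap_statistic, hypergeom_overlap, hypergeom_pmf,
                                      kmeans_trajectories, trend_correlation)


def enumerate_tail(k, K, n, N):
    """Brute-force P(X >= k) by enumerating all C(N, n) draws."""
    universe = list(range(N))
    members = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        hits += len(members & set(draw)) >= k
    return hits / total


class TestHypergeomOverlap:
    def test_zero_overlap_has_unit_tail(self):
        assert hypergeom_overlap(0, 10, 5, 30).p == 1.0

    def test_small_enumeration_example(self):
        # (2, 3, 3, 6): 10 of the C(6,3)=20 draws share >= 2 members
        assert hypergeom_overlap(2, 3, 3, 6).p == pytest.approx(0.5, abs=1e-12)

    def test_matches_enumeration_for_all_small_parameterizations(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        p = hypergeom_overlap(k, K, n, N).p
                        assert p == pytest.approx(
                            enumerate_tail(k, K, n, N), abs=1e-12), (k, K, n, N)

    def test_log_space_agrees_with_direct_summation(self):
        from scipy.stats import hypergeom as hg
        cases = [(10, 40, 50, 500), (60, 100, 150, 400), (219, 717, 444, 4408)]
        for k, K, n, N in cases:
            direct = float(hg.pmf(np.arange(k, min(K, n) + 1), N, K, n).sum())
            if direct > 1e-250:
                assert hypergeom_overlap(k, K, n, N).p == pytest.approx(direct, rel=1e-9)

    def test_representation_factor_is_one_at_independence(self):
        # K*n/N = 20*30/100 = 6 = k
        assert hypergeom_overlap(6, 20, 30, 100).rf == pytest.approx(1.0)

    def test_extreme_tail_keeps_finite_log10(self):
        stat = hypergeom_overlap(500, 600, 600, 5000)
        assert stat.p == 0.0 or stat.p < 1e-300
        assert math.isfinite(stat.log10_p)

    @pytest.mark.parametrize("bad", [(5, 4, 4, 10), (3, 12, 4, 10), (1, 4, 4, 3)])
    def test_inconsistent_counts_rejected(self, bad):
        with pytest.raises(ValueError):
            hypergeom_overlap(*bad)

    def test_point_mass_matches_scipy(self):
        from scipy.stats import hypergeom as hg
        assert hypergeom_pmf(3, 5, 6, 20) == pytest.approx(hg.pmf(3, 20, 5, 6), rel=1e-12)


def _tm(rows_2i, rows_cdk, features=None):
    rows_2i = np.atleast_2d(rows_2i)
    rows_cdk = np.atleast_2d(rows_cdk)
    features = features or [f"F{i}" for i in range(len(rows_2i))]
    tps = list(range(rows_2i.shape[1]))
    cols = pd.MultiIndex.from_tuples(
        [("2i", float(t)) for t in tps] + [("Cdk8i", float(t)) for t in tps],
        names=["treatment", "timepoint"])
    data = pd.DataFrame(np.hstack([rows_2i, rows_cdk]), index=features, columns=cols)
    return TrajectoryMatrix(data=data, mode="per_treatment")


class TestTrendCorrelation:
    def test_identical_trajectories_retained(self):
        t = np.array([[0.0, 1, 2, 3, 4, 5, 6]])
        table, kept = trend_correlation(_tm(t, t))
        assert table["r"].iloc[0] == pytest.approx(1.0)
        assert kept == ["F0"]

    def test_negated_trajectory_excluded(self):
        t = np.array([[0.0, 1, 2, 3, 4, 5, 6]])
        table, kept = trend_correlation(_tm(t, -t))
        assert table["r"].iloc[0] == pytest.approx(-1.0)
        assert kept == []

    def test_orthogonal_shapes_have_low_correlation(self):
        x = np.linspace(0, 2 * np.pi, 7, endpoint=False)
        s, c = np.sin(x), np.cos(x)
        table, _ = trend_correlation(_tm(s[None, :], c[None, :]))
        assert abs(table["r"].iloc[0]) < 0.3

    def test_constant_trajectory_skipped_with_reason(self):
        t = np.array([[0.0, 1, 2, 3, 4, 5, 6]])
        table, kept = trend_correlation(_tm(np.zeros_like(t), t))
        assert table["skipped"].iloc[0] == "constant"
        assert kept == []


class TestGapStatistic:
    def test_dispersion_decreases_with_k_on_random_data(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(80, 5))
        gp = gap_statistic(x, k_max=6, B=10, seed=0)
        w = gp.table["W"].to_numpy()
        assert np.all(np.diff(w) < 0)

    def test_single_blob_chooses_one_cluster(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, size=(100, 6))
        assert gap_statistic(x, k_max=6, B=30, seed=1).chosen_K == 1

    def test_k_max_must_be_below_row_count(self):
        with pytest.raises(ValueError):
            gap_statistic(np.zeros((5, 2)), k_max=5)

    def test_planted_five_modules_recovered(self):
        rng = np.random.default_rng(2)
        centers = rng.normal(0, 5, size=(5, 8))
        x = centers[np.repeat(np.arange(5), 30)] + rng.normal(0, 0.5, size=(150, 8))
        assert gap_statistic(x, k_max=8, B=30, seed=2).chosen_K == 5


class TestKmeansTrajectories:
    def test_one_point_per_cluster_gives_zero_dispersion(self):
        rows = np.arange(12.0).reshape(3, 4)
        tm = _tm(rows[:, :2], rows[:, 2:])
        model = kmeans_trajectories(tm, K=3, seed=0, restarts=5)
        assert model.inertia == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_rows_share_a_cluster(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(4, 6))
        rows = np.vstack([base, base[0]])
        tm = _tm(rows[:, :3], rows[:, 3:])
        model = kmeans_trajectories(tm, K=3, seed=0, restarts=5)
        assert model.assignments.iloc[0] == model.assignments.iloc[4]

    def test_planted_modules_recovered_with_high_ari(self):
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(3)
        shapes = np.array([[0, 0.2, 0.5, 1.0], [1.0, 0.5, 0.2, 0], [0, 1.0, 1.0, 0]])
        labels = np.repeat(np.arange(3), 40)
        rows = shapes[labels] * 2 + rng.normal(0, 0.15, size=(120, 4))
        tm = _tm(rows[:, :2], rows[:, 2:])
        model = kmeans_trajectories(tm, K=3, seed=0, restarts=10)
        assert adjusted_rand_score(labels, model.assignments.to_numpy()) >= 0.8

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        rows = rng.normal(size=(50, 6))
        tm = _tm(rows[:, :3], rows[:, 3:])
        a = kmeans_trajectories(tm, K=4, seed=9, restarts=5)
        b = kmeans_trajectories(tm, K=4, seed=9, restarts=5)
        assert a.assignments.equals(b.assignments)


class TestCentroidCorrelation:
    def test_shared_shape_correlates_positively(self):
        shape = np.array([0.0, 0.3, 0.7, 1.0, 0.8])
        rng = np.random.default_rng(0)
        rows = np.tile(shape, (30, 2)) + rng.normal(0, 0.05, size=(30, 10))
        tm = _tm(rows[:, :5], rows[:, 5:])
        model = kmeans_trajectories(tm, K=1, seed=0, restarts=3)
        assert model.centroid_correlations["r"].iloc[0] > 0.9

    def test_inverted_shape_correlates_negatively(self):
        shape = np.array([0.0, 0.3, 0.7, 1.0, 0.8])
        rng = np.random.default_rng(1)
        rows = np.hstack([np.tile(shape, (30, 1)), np.tile(-shape, (30, 1))])
        rows += rng.normal(0, 0.05, size=rows.shape)
        tm = _tm(rows[:, :5], rows[:, 5:])
        model = kmeans_trajectories(tm, K=1, seed=0, restarts=3)
        assert model.centroid_correlations["r"].iloc[0] < -0.9

    def test_constant_centroid_flagged_degenerate(self):
        rows = np.hstack([np.zeros((10, 4)), np.tile([0, 1, 2, 3.0], (10, 1))])
        tm = _tm(rows[:, :4], rows[:, 4:])
        model = kmeans_trajectories(tm, K=1, seed=0, restarts=3)
        cc = model.centroid_correlations
        assert bool(cc["degenerate"].iloc[0]) and np.isnan(cc["r"].iloc[0])
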