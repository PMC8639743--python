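import numpy as np
import pytest

from lifegaps.moran import (
    DegenerateInputError,
    LocalMoran,
    bonferroni_threshold,
    classify_clusters,
    local_moran_statistic,
    permutation_pvalues,
)
from lifegaps.weights import DistanceBandWeights, build_distance_band


def complete_graph_weights(n: int) -> DistanceBandWeights:
    pts = np.zeros((n, 2))
    pts[:, 0] = np.arange(n)  # all within one band
    return build_distance_band(pts, radius_m=float(n))


class TestStatistic:
    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            local_moran_statistic(np.ones(4), complete_graph_weights(4))

    def test_four_point_hand_example(self):
        # complete mutual neighborhood, y = (1, 1, -1, -1):
        # z = y, m2 = 1, lag_i = mean of the other three,
        # e.g. lag_0 = (1 - 1 - 1)/3 = -1/3 and I_0 = 1 * (-1/3) / 1 = -1/3.
        y = np.array([1.0, 1.0, -1.0, -1.0])
        z, lag, stat = local_moran_statistic(y, complete_graph_weights(4))
        np.testing.assert_allclose(z, y)
        np.testing.assert_allclose(lag, [-1 / 3, -1 / 3, 1 / 3, 1 / 3])
        np.testing.assert_allclose(stat, [-1 / 3, -1 / 3, -1 / 3, -1 / 3])

    @pytest.mark.parametrize("seed", range(10))
    def test_mean_of_local_equals_global_moran(self, seed, csr_points):
        rng = np.random.default_rng(seed)
        pts = csr_points(200, seed, extent=6000.0)
        y = rng.normal(size=200)
        w = build_distance_band(pts, 1200.0)
        z, lag, stat = local_moran_statistic(y, w)
        a = ~w.neighborless
        global_moran = np.sum(z[a] * lag[a]) / np.sum(z[a] ** 2)
        assert np.nanmean(stat[a]) == pytest.approx(global_moran, abs=1e-12)

    def test_neighborless_points_carry_no_statistic(self):
        pts = np.array([[0.0, 0], [100.0, 0], [99_999.0, 0]])
        w = build_distance_band(pts, 1200.0)
        z, lag, stat = local_moran_statistic(np.array([1.0, -1.0, 50.0]), w)
        assert np.isnan(stat[2]) and np.isnan(lag[2]) and np.isnan(z[2])
        # the outlying value does not contaminate the analyzed mean
        np.testing.assert_allclose(z[:2], [1.0, -1.0])


class TestPermutations:
    def test_pvalue_floor(self):
        # two tight opposite-valued blobs: observed I far beyond any permutation
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 50, (20, 2)), rng.normal(10_000, 50, (20, 2))])
        y = np.r_[np.full(20, 10.0), np.full(20, -10.0)] + rng.normal(0, 0.1, 40)
        w = build_distance_band(pts, 1200.0)
        m = 199
        p = permutation_pvalues(y, w, n_permutations=m, seed=1)
        assert np.nanmin(p) == pytest.approx(1.0 / (m + 1))
        assert np.nanmin(p) > 0

    def test_conditional_mean_matches_closed_form(self):
        # E[I_i^perm] = -z_i^2 / (m2 * (n-1)) for row-standardized weights
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 4000, (60, 2))
        y = rng.normal(size=60)
        w = build_distance_band(pts, 1200.0)
        z, _, stat = local_moran_statistic(y, w)
        a = np.flatnonzero(~w.neighborless)
        n = a.size
        m2 = np.sum(z[a] ** 2) / n
        m_perm = 8_000
        _, perm_mean, perm_sd = permutation_pvalues(
            y, w, n_permutations=m_perm, seed=2, return_moments=True
        )
        expected = -z[a] ** 2 / (m2 * (n - 1))
        se = perm_sd[a] / np.sqrt(m_perm)
        assert np.all(np.abs(perm_mean[a] - expected) <= 4 * se)

    def test_engine_mean_matches_brute_force_oracle(self):
        # the engine's permutation mean agrees with naive resampling
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 3000, (30, 2))
        y = rng.normal(size=30)
        w = build_distance_band(pts, 1200.0)
        z, _, stat = local_moran_statistic(y, w)
        a = np.flatnonzero(~w.neighborless)
        m2 = np.sum(z[a] ** 2) / a.size
        m_perm = 5_000
        _, perm_mean, perm_sd = permutation_pvalues(
            y, w, n_permutations=m_perm, seed=3, return_moments=True
        )
        i = int(a[0])
        pool = np.delete(z[a], int(np.searchsorted(a, i)))
        k = len(w.neighbors[i])
        sims = np.array(
            [z[i] / m2 * rng.choice(pool, size=k, replace=False).mean() for _ in range(m_perm)]
        )
        se = np.sqrt(sims.var() / m_perm + perm_sd[i] ** 2 / m_perm)
        assert perm_mean[i] == pytest.approx(sims.mean(), abs=4 * se)

    def test_same_seed_identical_pvalues(self, csr_points):
        pts = csr_points(100, 3, extent=6000.0)
        y = np.random.default_rng(3).normal(size=100)
        w = build_distance_band(pts, 1200.0)
        p1 = permutation_pvalues(y, w, n_permutations=499, seed=11)
        p2 = permutation_pvalues(y, w, n_permutations=499, seed=11)
        a = ~w.neighborless
        assert np.array_equal(p1[a], p2[a])

    def test_null_pvalue_calibration(self, csr_points):
        """Under CSR + iid values, the sign-matched tail rule gives pseudo
        p-values bounded by twice uniform (the directional p behaves
        two-sidedly because the reported tail follows the observed sign)."""
        rng = np.random.default_rng(8)
        pooled = []
        for rep in range(8):
            pts = csr_points(150, 100 + rep, extent=10_000.0)
            y = rng.normal(size=150)
            w = build_distance_band(pts, 1200.0)
            p = permutation_pvalues(y, w, n_permutations=199, seed=rep)
            pooled.append(p[~w.neighborless])
        pooled = np.concatenate(pooled)
        for t in (0.05, 0.1, 0.25):
            rate = (pooled <= t).mean()
            se = np.sqrt(2 * t * (1 - 2 * t) / pooled.size)
            assert rate <= 2 * t + 3 * se

    def test_invalid_permutation_count(self):
        w = complete_graph_weights(3)
        with pytest.raises(ValueError, match="n_permutations"):
            permutation_pvalues(np.array([1.0, 2.0, 3.0]), w, n_permutations=0)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, n, expected", [(0.1, 10_000, 1e-5), (0.1, 1, 0.1), (0.05, 5, 0.01)]
    )
    def test_threshold(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected, rel=1e-15)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestClassification:
    def test_quadrants(self):
        z = np.array([2.0, -2.0, -1.0, 1.5, 2.0])
        lag = np.array([1.5, -1.0, 2.0, -0.5, 1.0])
        p = np.array([1e-6, 1e-6, 1e-6, 1e-6, 0.5])
        labels = classify_clusters(z, lag, p, threshold=1e-5)
        assert labels.tolist() == ["HH", "LL", "LH", "HL", "NS"]

    def test_p_equal_threshold_is_not_significant(self):
        labels = classify_clusters(
            np.array([2.0]), np.array([1.0]), np.array([1e-5]), threshold=1e-5
        )
        assert labels.tolist() == ["NS"]

    def test_exact_zero_tie_breaks_to_ns(self):
        labels = classify_clusters(
            np.array([0.0, 1.0]), np.array([1.0, 0.0]), np.array([1e-6, 1e-6]), threshold=1e-5
        )
        assert labels.tolist() == ["NS", "NS"]

    def test_neighborless_label(self):
        labels = classify_clusters(
            np.array([np.nan]), np.array([np.nan]), np.array([np.nan]), threshold=1e-5
        )
        assert labels.tolist() == ["NEIGHBORLESS"]


class TestLocalMoranEstimator:
    def test_params_roundtrip(self):
        model = LocalMoran(radius_m=800.0, n_permutations=99, alpha=0.05, random_state=1)
        params = model.get_params()
        clone = LocalMoran().set_params(**params)
        assert clone.get_params() == params
        with pytest.raises(ValueError, match="invalid parameter"):
            model.set_params(bogus=3)

    def test_fit_attributes_and_detection(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.uniform(0, 20_000, (150, 2)), rng.normal(10_000, 400, (50, 2))])
        y = np.r_[rng.normal(0, 1, 150), rng.normal(5, 1, 50)]
        model = LocalMoran(radius_m=1200.0, n_permutations=2999, alpha=0.1, random_state=0)
        labels = model.fit_predict(pts, y)
        assert model.threshold_ == pytest.approx(0.1 / 200)
        assert labels.shape == (200,)
        in_blob = labels[150:]
        assert (in_blob == "HH").mean() > 0.5
        frame = model.results_frame()
        assert {"id", "z", "lag", "I", "pseudo_p", "label"} <= set(frame.columns)
        assert (frame["label"] == "NEIGHBORLESS").sum() == model.neighborless_.sum()

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        model = LocalMoran(radius_m=900.0, n_permutations=9, random_state=4)
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()
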