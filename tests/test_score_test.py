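"""Score statistic, null moments, and the sup-bandwidth p-value bound."""

import numpy as np
import pytest
from scipy.stats import norm

from kernmet.kernels import gram_matrix
from kernmet.score_test import (
    BandwidthGrid,
    DegenerateKernelError,
    NullModel,
    ScoreTestResult,
    davies_upper_bound,
    fit_null_intercept,
    kernel_score_test,
    null_moments,
    score_profile,
    score_quadratic,
)
from conftest import random_zero_inflated


class TestNullFit:
    def test_balanced_labels(self):
        null = fit_null_intercept([1, 1, 0, 0])
        assert null.mu0 == 0.5
        assert null.beta0 == 0.0

    def test_closed_form_matches_iterative_logistic_fit(self):
        null = fit_null_intercept([1, 0, 0, 0])
        assert null.mu0 == 0.25
        assert null.beta0 == pytest.approx(np.log(1 / 3))
        # oracle: Newton iterations on the intercept-only logistic likelihood
        y = np.array([1.0, 0, 0, 0])
        beta = 0.0
        for _ in range(50):
            mu = 1 / (1 + np.exp(-beta))
            beta += (y - mu).sum() / (len(y) * mu * (1 - mu))
        assert null.beta0 == pytest.approx(beta, abs=1e-10)

    @pytest.mark.parametrize("y", [[1, 1, 1, 1], [0, 0, 0]])
    def test_single_class_is_degenerate(self, y):
        with pytest.raises(ValueError, match="degenerate"):
            fit_null_intercept(y)

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            fit_null_intercept([0, 1, 2])


class TestScoreQuadratic:
    null = NullModel(mu0=0.5, beta0=0.0)

    def test_zero_kernel(self):
        assert score_quadratic(np.zeros((2, 2)), [1, 0], self.null) == 0.0

    def test_two_sample_hand_value(self):
        K = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert score_quadratic(K, [1, 0], self.null) == pytest.approx(0.25)

    def test_identity_kernel(self):
        assert score_quadratic(np.eye(2), [1, 0], self.null) == pytest.approx(0.5)

    def test_matches_double_sum(self, rng):
        K = rng.random((6, 6))
        K = 0.5 * (K + K.T)
        y = np.array([1, 0, 1, 0, 0, 1])
        null = fit_null_intercept(y)
        expected = sum(K[i, j] * (y[i] - null.mu0) * (y[j] - null.mu0)
                       for i in range(6) for j in range(6))
        assert score_quadratic(K, y, null) == pytest.approx(expected)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            score_quadratic(np.eye(3), [1, 0], self.null)


class TestNullMoments:
    def test_identity_kernel_closed_form(self):
        # tr(HIH) = n-1 for idempotent H
        mu_q, sigma_q = null_moments(np.eye(4), NullModel(0.5, 0.0))
        assert mu_q == pytest.approx(0.75)
        assert sigma_q == pytest.approx(np.sqrt(2 * 0.0625 * 3))

    def test_constant_kernel_is_degenerate(self):
        with pytest.raises(DegenerateKernelError):
            null_moments(np.full((5, 5), 0.7), NullModel(0.5, 0.0))

    @pytest.mark.parametrize("mu0", [0.5, 1 / 3])
    def test_mean_matches_relabeling_monte_carlo(self, rng, mu0):
        """Oracle: Q averaged over iid Bernoulli(mu0) relabelings, each refit."""
        n = 6
        K = gram_matrix(random_zero_inflated(rng, n, 3, 0.3), "distance", 2.0)
        mu_q, sigma_q = null_moments(K, NullModel(mu0, float(np.log(mu0 / (1 - mu0)))))
        draws = 100_000
        Y = (rng.random((draws, n)) < mu0).astype(float)
        U = Y - Y.mean(axis=1, keepdims=True)  # per-draw intercept refit
        Q = np.einsum("ni,ij,nj->n", U, K, U)
        se = Q.std() / np.sqrt(draws)
        assert abs(Q.mean() - mu_q) < 3 * se


class TestScoreProfile:
    def test_joint_sample_permutation_invariance(self, rng):
        X = random_zero_inflated(rng, 14, 3, 0.3)
        y = np.array([1, 0] * 7)
        grid = BandwidthGrid(count=25)
        base = score_profile(X, y, "distance", grid)
        perm = rng.permutation(14)
        shuffled = score_profile(X[perm], y[perm], "distance", grid)
        np.testing.assert_allclose(shuffled.scores, base.scores, rtol=1e-9)

    def test_label_swap_invariance(self, rng):
        """y -> 1-y flips the sign of every residual, leaving Q unchanged."""
        X = random_zero_inflated(rng, 12, 2, 0.3)
        y = np.array([1, 1, 0, 0, 1, 0, 0, 1, 0, 1, 0, 0])
        grid = BandwidthGrid(count=25)
        a = score_profile(X, y, "distance", grid)
        b = score_profile(X, 1 - y, "distance", grid)
        np.testing.assert_allclose(a.scores, b.scores, rtol=1e-9)

    def test_distance_family_equals_gaussian_without_zeros(self, rng):
        """With every metabolite present the penalty vanishes."""
        X = rng.uniform(0.5, 4.0, size=(16, 3))
        y = np.array([1, 0] * 8)
        grid = BandwidthGrid(count=40)
        d = score_profile(X, y, "distance", grid)
        g = score_profile(X, y, "gaussian", grid)
        np.testing.assert_allclose(d.scores, g.scores, rtol=1e-12)

    def test_constant_data_all_bandwidths_degenerate(self):
        X = np.ones((8, 2))
        y = np.array([1, 0] * 4)
        with pytest.raises(DegenerateKernelError):
            score_profile(X, y, "distance")

    def test_total_variation_and_max(self, rng):
        X = random_zero_inflated(rng, 10, 2, 0.2)
        y = np.array([1, 0] * 5)
        res = score_profile(X, y, "distance", BandwidthGrid(count=30))
        assert res.max_score == res.scores.max()
        assert res.total_variation == pytest.approx(np.abs(np.diff(res.scores)).sum())


def _result(scores):
    scores = np.asarray(scores, dtype=float)
    return ScoreTestResult(
        bandwidths=np.arange(scores.size, dtype=float) + 1.0,
        scores=scores, q_values=scores, max_score=float(scores.max()),
        total_variation=float(np.abs(np.diff(scores)).sum()),
        family="distance", spacing="linear")


class TestDaviesBound:
    def test_constant_profile_is_normal_tail(self):
        m = 1.6449
        assert davies_upper_bound(_result([m])) == norm.cdf(-m)
        assert davies_upper_bound(_result([m])) == pytest.approx(0.05, abs=1e-4)

    def test_hand_derived_point(self):
        res = _result([1.0, 2.0])  # M = 2, V = 1
        assert davies_upper_bound(res) == pytest.approx(0.049745615204773226, abs=1e-9)

    def test_capped_at_one(self):
        res = _result([0.0, -5.0, 0.0, -5.0, 0.0])  # M = 0, V = 20
        assert davies_upper_bound(res) == 1.0

    def test_empty_profile_rejected(self):
        res = _result([1.0])
        res.scores = np.array([])
        with pytest.raises(ValueError, match="empty"):
            davies_upper_bound(res)


class TestKernelScoreTest:
    def test_toy_separation_significant(self, toy_separation):
        x, y = toy_separation
        res = kernel_score_test(x, y, family="distance")
        assert res.p_upper is not None and res.p_upper < 0.05

    @pytest.mark.parametrize("family", ["distance", "stratified"])
    def test_p_upper_in_unit_interval(self, rng, family):
        for _ in range(10):
            X = random_zero_inflated(rng, 12, 3, 0.3)
            y = np.array([1, 0] * 6)
            res = kernel_score_test(X, y, family=family, grid=BandwidthGrid(count=30))
            assert 0.0 < res.p_upper <= 1.0

    def test_log_spacing_option(self, toy_separation):
        x, y = toy_separation
        grid = BandwidthGrid(spacing="log", count=50)
        res = kernel_score_test(x, y, family="distance", grid=grid)
        assert res.spacing == "log"
        assert np.all(np.diff(np.log(res.bandwidths)) > 0)
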