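"""Single-effect regression: closed-form posterior and empirical Bayes."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from susie2 import (
    DomainError,
    PriorWeights,
    SERSufficientStats,
    fit_ser,
    optimize_prior_variance,
)
from susie2.ser import ser_logbf


def _stats_from(X, y):
    return SERSufficientStats(
        xty=X.T @ y, xtx=(X * X).sum(0), n=X.shape[0], yty=float(y @ y)
    )


class TestFitSer:
    def test_single_candidate_gets_full_posterior(self):
        stats = SERSufficientStats(xty=[1.3], xtx=[10.0], n=10, yty=5.0)
        post = fit_ser(stats, sigma_sq=1.0, sigma0_sq=0.5, pi=PriorWeights.uniform(1))
        assert post.alpha == pytest.approx([1.0])

    def test_identical_evidence_splits_evenly(self):
        stats = SERSufficientStats(xty=[2.0, 2.0], xtx=[10.0, 10.0], n=10, yty=8.0)
        post = fit_ser(stats, 1.0, 0.5, PriorWeights.uniform(2))
        assert post.alpha == pytest.approx([0.5, 0.5])

    def test_alpha_matches_numeric_integration(self, rng):
        """alpha against per-variable marginal likelihoods integrated over lambda."""
        n, p = 10, 3
        X = np.linalg.qr(rng.standard_normal((n, p)))[0]  # orthonormal columns
        X = X - X.mean(0)
        X = X / np.sqrt((X * X).mean(0))
        y = rng.standard_normal(n) + 0.9 * X[:, 1]
        sigma_sq, sigma0_sq = 1.0, 0.5

        def marginal(j):
            def integrand(lam):
                resid = y - lam * X[:, j]
                return (
                    np.exp(-0.5 * resid @ resid / sigma_sq)
                    * norm.pdf(lam, 0, np.sqrt(sigma0_sq))
                )
            val, _ = quad(integrand, -6, 6, limit=200)
            return val

        like = np.array([marginal(j) for j in range(p)])
        null = np.exp(-0.5 * y @ y / sigma_sq)
        bf = like / null
        expected = bf / bf.sum()

        post = fit_ser(_stats_from(X, y), sigma_sq, sigma0_sq, PriorWeights.uniform(p))
        np.testing.assert_allclose(post.alpha, expected, rtol=1e-6)
        np.testing.assert_allclose(np.exp(post.logbf_per_var), bf, rtol=1e-6)

    def test_posterior_moments_are_conjugate_update(self, toy_suffstats):
        stats, _, _ = toy_suffstats
        post = fit_ser(stats, 1.0, 0.3, PriorWeights.uniform(stats.p))
        s2 = 1.0 / stats.xtx
        expected_var = 1.0 / (1.0 / 0.3 + 1.0 / s2)
        np.testing.assert_allclose(
            post.post_mean2 - post.post_mean**2, expected_var, rtol=1e-10
        )
        assert np.all(post.post_mean2 >= post.post_mean**2)

    def test_prior_scale_invariance(self, toy_suffstats):
        stats, _, _ = toy_suffstats
        pi1 = PriorWeights(np.array([0.1, 0.2, 0.3, 0.4]))
        pi2 = PriorWeights(np.array([1.0, 2.0, 3.0, 4.0]))  # normalized identically
        a1 = fit_ser(stats, 1.0, 0.2, pi1).alpha
        a2 = fit_ser(stats, 1.0, 0.2, pi2).alpha
        np.testing.assert_allclose(a1, a2, atol=1e-14)

    def test_vanishing_prior_variance_recovers_prior(self, toy_suffstats):
        stats, _, _ = toy_suffstats
        pi = PriorWeights(np.array([0.4, 0.3, 0.2, 0.1]))
        for s0 in (1e-12, 0.0):
            post = fit_ser(stats, 1.0, s0, pi)
            np.testing.assert_allclose(post.alpha, pi.pi, atol=1e-5)
        post0 = fit_ser(stats, 1.0, 0.0, pi)
        assert post0.logbf == 0.0
        assert np.all(post0.post_mean == 0.0)

    def test_raw_data_equals_sufficient_stats(self, toy_suffstats):
        """The SER depends on the data only through its sufficient statistics."""
        stats, X, y = toy_suffstats
        rebuilt = SERSufficientStats(
            xty=X.T @ y, xtx=(X * X).sum(0), n=X.shape[0], yty=float(y @ y)
        )
        a = fit_ser(stats, 0.7, 0.2, PriorWeights.uniform(4))
        b = fit_ser(rebuilt, 0.7, 0.2, PriorWeights.uniform(4))
        np.testing.assert_array_equal(a.alpha, b.alpha)

    def test_huge_z_scores_stay_normalized(self):
        """Log-space arithmetic keeps alpha finite at |z| ~ 40."""
        xtx = np.full(3, 100.0)
        xty = np.array([400.0, 390.0, 0.0])  # z = 40, 39, 0
        stats = SERSufficientStats(xty=xty, xtx=xtx, n=200, yty=2000.0)
        post = fit_ser(stats, 1.0, 1.0, PriorWeights.uniform(3))
        assert np.all(np.isfinite(post.alpha))
        assert post.alpha.sum() == pytest.approx(1.0, abs=1e-10)
        assert post.alpha[0] > 0.9

    def test_input_errors(self, toy_suffstats):
        stats, _, _ = toy_suffstats
        with pytest.raises(ValueError):
            fit_ser(stats, 1.0, 0.5, PriorWeights.uniform(7))
        with pytest.raises(DomainError):
            fit_ser(stats, -1.0, 0.5, PriorWeights.uniform(4))
        with pytest.raises(ValueError):
            SERSufficientStats(xty=[1.0, 2.0], xtx=[1.0], n=10, yty=1.0)
        with pytest.raises(ValueError):
            SERSufficientStats(xty=[1.0], xtx=[0.0], n=10, yty=1.0)


class TestOptimizePriorVariance:
    def test_no_signal_returns_zero(self):
        stats = SERSufficientStats(
            xty=np.zeros(4), xtx=np.full(4, 20.0), n=20, yty=19.0
        )
        assert optimize_prior_variance(stats, 1.0, PriorWeights.uniform(4)) == 0.0

    def test_agrees_with_grid_search(self, rng):
        """Bounded optimizer vs a dense grid over log sigma0^2, p=1 toy."""
        n = 40
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        y = 0.5 * x + rng.standard_normal(n)
        y -= y.mean()
        stats = SERSufficientStats(
            xty=np.array([x @ y]), xtx=np.array([x @ x]), n=n, yty=float(y @ y)
        )
        pi = PriorWeights.uniform(1)
        grid = np.exp(np.linspace(np.log(1e-10), np.log(stats.yty / n), 4001))
        logbfs = np.array([ser_logbf(stats, 1.0, s, pi) for s in grid])
        best_grid = grid[np.argmax(logbfs)]
        found = optimize_prior_variance(stats, 1.0, pi)
        assert np.isclose(np.log(found), np.log(best_grid), atol=0.02)

    def test_returned_value_is_a_maximizer(self, toy_suffstats):
        stats, _, _ = toy_suffstats
        pi = PriorWeights.uniform(4)
        s_star = optimize_prior_variance(stats, 1.0, pi)
        assert s_star > 0  # toy data has real signal on x2
        at_star = ser_logbf(stats, 1.0, s_star, pi)
        assert at_star >= ser_logbf(stats, 1.0, 0.0, pi)
        assert at_star >= ser_logbf(stats, 1.0, 2.0 * s_star, pi)
        assert at_star >= ser_logbf(stats, 1.0, 0.5 * s_star, pi)


class TestPriorWeights:
    def test_rejects_zeros_and_floors_on_request(self):
        with pytest.raises(ValueError):
            PriorWeights(np.array([0.5, 0.0, 0.5]))
        pw = PriorWeights.with_floor(np.array([0.5, 0.0, 0.5]), floor=1e-10)
        assert pw.pi[1] > 0
        assert pw.pi.sum() == pytest.approx(1.0)
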