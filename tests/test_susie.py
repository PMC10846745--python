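"""SuSiE fitting: IBSS, PIP aggregation, credible sets, summary statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from susie2 import (
    DomainError,
    PriorWeights,
    SERSufficientStats,
    SummaryData,
    SusieModel,
    build_credible_sets,
    compute_pip,
    fit_ser,
    ibss_fit,
    ibss_fit_ss,
    marginal_z,
    summarize_fit,
)
from susie2.susie import standardize


def _two_causal_data(rng, n=600, p=10, noise_sd=0.1):
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    y = X[:, 2] + X[:, 7] + rng.normal(0, noise_sd, n)
    return X, y


class TestIbssFit:
    def test_k1_reduces_to_single_effect_regression(self, rng):
        X, y = _two_causal_data(rng)
        model = ibss_fit(X, y, K=1, estimate_sigma=False, estimate_sigma0=False,
                         sigma0_sq=0.4)
        Xs, _ = standardize(X)
        yc = y - y.mean()
        stats = SERSufficientStats(
            xty=Xs.T @ yc, xtx=(Xs * Xs).sum(0), n=len(y), yty=float(yc @ yc)
        )
        post = fit_ser(stats, float(yc @ yc) / len(y), 0.4, PriorWeights.uniform(X.shape[1]))
        np.testing.assert_allclose(model.alpha[0], post.alpha, atol=1e-12)

    def test_two_causal_recovered_and_match_enumeration(self, rng):
        """PIPs > 0.95 at both causals; top pair agrees with exhaustive
        enumeration of all two-causal configurations."""
        X, y = _two_causal_data(rng)
        n, p = X.shape
        model = ibss_fit(X, y, K=2)
        pip = model.pip()
        assert pip[2] > 0.95 and pip[7] > 0.95

        # oracle: marginal likelihood of y under exactly-two-causal models,
        # effects ~ N(0, sigma0^2), residual variance at the true value
        Xs, _ = standardize(X)
        yc = y - y.mean()
        sigma_sq, sigma0_sq = 0.01, 1.0
        best, best_ll = None, -np.inf
        for j1 in range(p):
            for j2 in range(j1 + 1, p):
                U = Xs[:, [j1, j2]]
                G = U.T @ U
                M = np.eye(2) + (sigma0_sq / sigma_sq) * G
                Uy = U.T @ yc
                quad = (yc @ yc - (sigma0_sq / sigma_sq) * Uy @ np.linalg.solve(M, Uy))
                ll = -0.5 * (np.linalg.slogdet(M)[1] + quad / sigma_sq)
                if ll > best_ll:
                    best, best_ll = (j1, j2), ll
        top = tuple(sorted(int(np.argmax(model.alpha[k])) for k in range(2)))
        assert top == best == (2, 7)

    def test_null_response_yields_nothing(self, rng):
        X = rng.standard_normal((100, 8))
        model = ibss_fit(X, np.zeros(100), K=3)
        assert np.all(model.sigma0_sq == 0.0)
        assert np.all(model.pip() == 0.0)
        R = np.corrcoef(X.T)
        assert build_credible_sets(model, R) == []

    def test_elbo_non_decreasing_with_fixed_hyperparameters(self, rng):
        X, y = _two_causal_data(rng, noise_sd=1.0)
        model = ibss_fit(X, y, K=3, estimate_sigma=False, estimate_sigma0=False,
                         sigma0_sq=0.2, tol=1e-10, max_iter=50)
        diffs = np.diff(model.elbo_trace)
        assert np.all(diffs > -1e-8)

    def test_constant_column_dropped_and_reported_zero(self, rng):
        X, y = _two_causal_data(rng)
        X = np.column_stack([X, np.ones(len(y))])
        model = ibss_fit(X, y, K=2)
        assert model.pip()[-1] == 0.0
        assert np.all(model.alpha[:, -1] == 0.0)
        assert model.pip()[2] > 0.9

    def test_rejects_bad_k(self, rng):
        X, y = _two_causal_data(rng)
        with pytest.raises(ValueError):
            ibss_fit(X, y, K=0)


class TestSummaryStatistics:
    def test_matches_individual_level_with_insample_ld(self, rng):
        X, y = _two_causal_data(rng, n=300, p=12, noise_sd=0.5)
        model_ind = ibss_fit(X, y, K=3)
        Xs, _ = standardize(X)
        R = Xs.T @ Xs / len(y)
        z = marginal_z(X, y)
        model_ss = ibss_fit_ss(SummaryData(z=z, R=R, n=len(y)), K=3)
        np.testing.assert_allclose(model_ind.pip(), model_ss.pip(), atol=1e-6)

    def test_zero_z_scores_give_no_credible_sets(self):
        p = 15
        data = SummaryData(z=np.zeros(p), R=np.eye(p), n=1000)
        model = ibss_fit_ss(data, K=3)
        assert build_credible_sets(model, np.eye(p)) == []

    def test_no_ld_argmax_pip_is_argmax_z(self, rng):
        p = 20
        z = rng.normal(0, 1, p)
        z[13] = 7.5
        model = ibss_fit_ss(SummaryData(z=z, R=np.eye(p), n=5000), K=1)
        assert int(np.argmax(model.pip())) == 13

    def test_non_psd_ld_raises_naming_eigenvalue(self):
        R = np.array([[1.0, 0.99, 0.0], [0.99, 1.0, 0.99], [0.0, 0.99, 1.0]])
        with pytest.raises(DomainError, match="eigenvalue"):
            ibss_fit_ss(SummaryData(z=np.ones(3), R=R, n=100), K=1)


class TestComputePip:
    def test_single_row_is_identity(self):
        np.testing.assert_allclose(compute_pip([[0.2, 0.8]]), [0.2, 0.8])

    def test_two_rows_complement_product(self):
        alpha = np.array([[0.5, 0.5, 0.0], [0.5, 0.5, 0.0]])
        np.testing.assert_allclose(compute_pip(alpha), [0.75, 0.75, 0.0])

    def test_against_monte_carlo_assignment_sampling(self, rng):
        """PIP formula vs inclusion frequency of independently sampled effects."""
        K, p, draws = 5, 20, 10**6
        alpha = rng.dirichlet(np.full(p, 0.3), size=K)
        pip = compute_pip(alpha)
        included = np.zeros((draws, p), dtype=bool)
        for k in range(K):
            picks = rng.choice(p, size=draws, p=alpha[k])
            included[np.arange(draws), picks] = True
        freq = included.mean(0)
        se = np.sqrt(pip * (1 - pip) / draws)
        assert np.all(np.abs(freq - pip) <= 3 * se + 1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            compute_pip([[0.5, 1.2]])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounds_between_max_and_sum(self, seed):
        rng = np.random.default_rng(seed)
        alpha = rng.dirichlet(np.full(8, 0.5), size=4)
        pip = compute_pip(alpha)
        assert np.all(pip <= np.minimum(1.0, alpha.sum(0)) + 1e-12)
        assert np.all(pip >= alpha.max(0) - 1e-12)


def _model_from_rows(rows, sigma0=None):
    rows = np.atleast_2d(np.asarray(rows, float))
    K, p = rows.shape
    return SusieModel(
        K=K, alpha=rows, mu=np.zeros((K, p)), mu2=np.zeros((K, p)),
        sigma_sq=1.0,
        sigma0_sq=np.ones(K) if sigma0 is None else np.asarray(sigma0, float),
        pi=PriorWeights.uniform(p), elbo_trace=np.array([0.0]),
        converged=True, n_iter=1,
    )


class TestCredibleSets:
    def test_dominant_variant_singleton(self):
        model = _model_from_rows([[0.97, 0.02, 0.01]])
        (cs,) = build_credible_sets(model, np.eye(3), level=0.95)
        assert cs.members == (0,)
        assert cs.purity == 1.0
        assert cs.lead == 0

    def test_flat_row_discarded_by_purity(self):
        p = 100
        model = _model_from_rows([np.full(p, 1.0 / p)])
        assert build_credible_sets(model, np.eye(p), level=0.95, min_purity=0.5) == []

    def test_smallest_prefix_reaching_level(self):
        model = _model_from_rows([[0.5, 0.3, 0.15, 0.05]])
        R = np.full((4, 4), 0.9)
        np.fill_diagonal(R, 1.0)
        (cs,) = build_credible_sets(model, R, level=0.9)
        assert set(cs.members) == {0, 1, 2}

    def test_null_effects_produce_no_sets(self):
        model = _model_from_rows([[0.99, 0.01]], sigma0=[1e-12])
        assert build_credible_sets(model, np.eye(2)) == []

    def test_duplicate_sets_deduplicated(self):
        rows = [[0.96, 0.03, 0.01], [0.97, 0.02, 0.01]]
        model = _model_from_rows(rows)
        assert len(build_credible_sets(model, np.eye(3), dedup=True)) == 1
        assert len(build_credible_sets(model, np.eye(3), dedup=False)) == 2

    @given(st.floats(0.5, 0.94), st.floats(0.01, 0.049))
    @settings(max_examples=30, deadline=None)
    def test_higher_level_never_shrinks_set(self, lo, bump):
        alpha = np.array([0.4, 0.25, 0.2, 0.1, 0.05])
        R = np.full((5, 5), 0.95)
        np.fill_diagonal(R, 1.0)
        model = _model_from_rows([alpha])
        small = build_credible_sets(model, R, level=lo, min_purity=0.0)
        big = build_credible_sets(model, R, level=lo + bump, min_purity=0.0)
        assert set(small[0].members) <= set(big[0].members)

    def test_summarize_bundles_pip_and_sets(self, rng):
        X, y = _two_causal_data(rng)
        model = ibss_fit(X, y, K=2)
        Xs, _ = standardize(X)
        fit = summarize_fit(model, Xs.T @ Xs / len(y))
        assert len(fit.credible_sets) == 2
        assert fit.pip.shape == (X.shape[1],)
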