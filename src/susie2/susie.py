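"""Sum-of-single-effects (SuSiE) regression fit by IBSS.

The model writes the effect vector as a sum of ``K`` single-effect
vectors, each governed by an SER prior (see :mod:`susie2.ser`).  Fitting
is by Iterative Bayesian Stepwise Selection (IBSS): coordinate ascent
that, for each effect in turn, removes the expected contribution of all
other effects from the response and refits that effect's SER in closed
form.  The variational objective (ELBO) is tracked per outer iteration
and is non-decreasing for fixed hyperparameters.

Both individual-level data ``(X, y)`` and summary statistics ``(z, R,
n)`` are supported.  Internally both routes reduce to the same
sufficient statistics ``(X'X, X'y, y'y, n)`` under the
standardized-genotype convention, so with an in-sample LD matrix the two
fits coincide.

Credible sets are the smallest per-effect sets of variables reaching a
target cumulative inclusion probability, filtered by purity (the
minimum absolute pairwise LD among members).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ser import (
    DomainError,
    PriorWeights,
    SERSufficientStats,
    fit_ser,
    optimize_prior_variance,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SusieModel",
    "CredibleSet",
    "SusieFit",
    "SummaryData",
    "ibss_fit",
    "ibss_fit_ss",
    "compute_pip",
    "build_credible_sets",
    "summarize_fit",
    "marginal_z",
    "standardize",
]

#: effects with estimated prior variance below this are treated as null
PRIOR_VAR_TOL = 1e-9


@dataclass
class SusieModel:
    """Fitted K-effect variational state."""

    K: int
    alpha: np.ndarray          # K x p inclusion probabilities per effect
    mu: np.ndarray             # K x p posterior means given inclusion
    mu2: np.ndarray            # K x p posterior second moments
    sigma_sq: float            # residual variance
    sigma0_sq: np.ndarray      # length-K prior effect variances
    pi: PriorWeights
    elbo_trace: np.ndarray
    converged: bool
    n_iter: int

    @property
    def p(self) -> int:
        return self.alpha.shape[1]

    def effective_effects(self, prior_tol: float = PRIOR_VAR_TOL) -> np.ndarray:
        """Indices of effects with non-negligible prior variance."""
        return np.flatnonzero(self.sigma0_sq >= prior_tol)

    def pip(self, prior_tol: float = PRIOR_VAR_TOL) -> np.ndarray:
        """Per-variable PIP over non-null effects: 1 - prod_k (1 - alpha_kj)."""
        keep = self.effective_effects(prior_tol)
        if keep.size == 0:
            return np.zeros(self.p)
        return compute_pip(self.alpha[keep])


@dataclass(frozen=True)
class CredibleSet:
    """A level-rho credible set for one effect.

    ``members`` are 0-based variant indices ordered by decreasing
    inclusion probability (so ``members[0]`` is the lead variant).
    """

    members: tuple[int, ...]
    level: float
    purity: float
    lead: int
    effect_index: int

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class SusieFit:
    """A fitted model with its summaries: PIPs and credible sets."""

    model: SusieModel
    pip: np.ndarray
    credible_sets: list[CredibleSet]


@dataclass(frozen=True)
class SummaryData:
    """GWAS summary statistics: z-scores, LD correlation matrix, sample size."""

    z: np.ndarray
    R: np.ndarray
    n: int

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        R = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "R", R)
        if z.ndim != 1:
            raise ValueError("z must be a 1-d vector")
        if not np.all(np.isfinite(z)):
            raise ValueError("z-scores must be finite")
        if R.shape != (z.size, z.size):
            raise ValueError(f"R shape {R.shape} does not match {z.size} variants")
        if not np.allclose(R, R.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-8):
            raise ValueError("LD matrix must have unit diagonal")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale columns to unit variance.

    Returns the standardized matrix and a boolean mask of retained
    (non-constant) columns; constant columns are dropped.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    sd = np.sqrt((Xc * Xc).mean(axis=0))
    keep = sd > 0
    if not np.all(keep):
        logger.warning(
            "dropping %d constant genotype column(s); reported as PIP 0",
            int((~keep).sum()),
        )
    return Xc[:, keep] / sd[keep], keep


def marginal_z(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-variant z-scores from simple linear regression of y on each column.

    Uses the t-statistic of the slope with ``n - 2`` residual degrees of
    freedom, ``z_j = r_j * sqrt((n-2) / (1-r_j^2))`` with ``r_j`` the
    sample correlation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc * Xc).sum(axis=0))
    sy = np.sqrt((yc * yc).sum())
    r = Xc.T @ yc / (sx * sy)
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    return r * np.sqrt((n - 2) / (1 - r * r))


def compute_pip(alpha: np.ndarray) -> np.ndarray:
    """Aggregate per-effect inclusion probabilities into PIPs.

    ``PIP_j = 1 - prod_k (1 - alpha_kj)``: the probability that at least
    one effect assigns its variable to j, treating effects as
    independent under the variational posterior.
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha entries must lie in [0, 1]")
    # log1p for accuracy when many alphas are tiny
    return -np.expm1(np.sum(np.log1p(-np.clip(alpha, 0.0, 1.0 - 1e-16)), axis=0))


# ---------------------------------------------------------------------------
# IBSS on sufficient statistics
# ---------------------------------------------------------------------------


def _ibss_suffstat(
    XtX: np.ndarray,
    Xty: np.ndarray,
    yty: float,
    n: int,
    K: int,
    pi: PriorWeights,
    tol: float,
    max_iter: int,
    estimate_sigma0: bool,
    estimate_sigma: bool,
    sigma0_sq_init: float | None = None,
) -> SusieModel:
    p = Xty.shape[0]
    d = np.diag(XtX).copy()
    var_y = yty / n

    alpha = np.full((K, p), 1.0 / p)
    mu = np.zeros((K, p))
    mu2 = np.zeros((K, p))
    sigma_sq = var_y
    s0_init = 0.2 * var_y if sigma0_sq_init is None else sigma0_sq_init
    sigma0_sq = np.full(K, s0_init)

    b_bar = alpha * mu                       # K x p
    XtXb = np.zeros((K, p))                  # XtX @ b_bar_k per effect
    XtXb_total = np.zeros(p)

    elbo_trace: list[float] = []
    converged = False
    n_iter = 0

    for it in range(max_iter):
        kl = np.zeros(K)
        for k in range(K):
            Xtr = Xty - (XtXb_total - XtXb[k])
            stats = SERSufficientStats(xty=Xtr, xtx=d, n=n, yty=yty)
            if estimate_sigma0:
                sigma0_sq[k] = optimize_prior_variance(stats, sigma_sq, pi)
            post = fit_ser(stats, sigma_sq, sigma0_sq[k], pi)
            alpha[k] = post.alpha
            mu[k] = post.post_mean
            mu2[k] = post.post_mean2

            new_b = alpha[k] * mu[k]
            new_XtXb = XtX @ new_b
            XtXb_total += new_XtXb - XtXb[k]
            b_bar[k] = new_b
            XtXb[k] = new_XtXb

            # KL(q_k || prior) via the SER evidence identity
            b_mk = b_bar.sum(axis=0) - new_b
            rk_sq = yty - 2.0 * b_mk @ Xty + b_mk @ (XtXb_total - new_XtXb)
            e_quad = rk_sq - 2.0 * Xtr @ new_b + d @ (alpha[k] * mu2[k])
            kl[k] = -post.logbf + (rk_sq - e_quad) / (2.0 * sigma_sq)

        b_total = b_bar.sum(axis=0)
        erss = (
            yty
            - 2.0 * b_total @ Xty
            + b_total @ XtXb_total
            - np.einsum("kp,kp->", b_bar, XtXb)
            + np.einsum("p,kp->", d, alpha * mu2)
        )
        erss = max(erss, 1e-12 * max(yty, 1.0))
        if estimate_sigma:
            sigma_sq = erss / n

        elbo = (
            -0.5 * n * np.log(2.0 * np.pi * sigma_sq)
            - erss / (2.0 * sigma_sq)
            - kl.sum()
        )
        elbo_trace.append(float(elbo))
        n_iter = it + 1
        if it > 0 and abs(elbo_trace[-1] - elbo_trace[-2]) < tol:
            converged = True
            break

    return SusieModel(
        K=K,
        alpha=alpha,
        mu=mu,
        mu2=mu2,
        sigma_sq=float(sigma_sq),
        sigma0_sq=sigma0_sq,
        pi=pi,
        elbo_trace=np.asarray(elbo_trace),
        converged=converged,
        n_iter=n_iter,
    )


def _reinsert(model: SusieModel, keep: np.ndarray, pi_full: PriorWeights) -> SusieModel:
    """Re-expand a model fitted on a column subset to the full variant set.

    Dropped columns get zero inclusion probability and zero effects.
    """
    p_full = keep.size
    if keep.all():
        return model
    alpha = np.zeros((model.K, p_full))
    mu = np.zeros((model.K, p_full))
    mu2 = np.zeros((model.K, p_full))
    alpha[:, keep] = model.alpha
    mu[:, keep] = model.mu
    mu2[:, keep] = model.mu2
    return SusieModel(
        K=model.K,
        alpha=alpha,
        mu=mu,
        mu2=mu2,
        sigma_sq=model.sigma_sq,
        sigma0_sq=model.sigma0_sq,
        pi=pi_full,
        elbo_trace=model.elbo_trace,
        converged=model.converged,
        n_iter=model.n_iter,
    )


def ibss_fit(
    X: np.ndarray,
    y: np.ndarray,
    K: int = 5,
    pi: PriorWeights | None = None,
    tol: float = 1e-3,
    max_iter: int = 100,
    estimate_sigma0: bool = True,
    estimate_sigma: bool = True,
    sigma0_sq: float | None = None,
) -> SusieModel:
    """Fit SuSiE on individual-level data by IBSS.

    ``X`` columns are centered and scaled to unit variance internally
    (constant columns are dropped and reported with PIP 0); ``y`` is
    centered.  ``pi`` defaults to uniform; when ``estimate_sigma0`` is
    off, ``sigma0_sq`` fixes the per-effect prior variance.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError(f"incompatible shapes X {X.shape}, y {y.shape}")
    n, p_full = X.shape
    if pi is None:
        pi = PriorWeights.uniform(p_full)
    if pi.p != p_full:
        raise ValueError(f"prior length {pi.p} != number of variants {p_full}")

    Xs, keep = standardize(X)
    yc = y - y.mean()
    pi_sub = pi if keep.all() else PriorWeights(pi.pi[keep])

    XtX = Xs.T @ Xs
    Xty = Xs.T @ yc
    yty = float(yc @ yc)
    if yty == 0.0:
        yty = float(n)  # degenerate constant response; fit proceeds to the null
        Xty = np.zeros_like(Xty)

    model = _ibss_suffstat(
        XtX, Xty, yty, n, K, pi_sub, tol, max_iter,
        estimate_sigma0, estimate_sigma,
        sigma0_sq_init=sigma0_sq,
    )
    if not estimate_sigma0 and sigma0_sq is not None:
        model.sigma0_sq[:] = sigma0_sq
    return _reinsert(model, keep, pi)


def ibss_fit_ss(
    data: SummaryData,
    K: int = 5,
    pi: PriorWeights | None = None,
    tol: float = 1e-3,
    max_iter: int = 100,
    estimate_sigma0: bool = True,
    estimate_sigma: bool = True,
    sigma0_sq: float | None = None,
    ld_reg: float = 0.0,
) -> SusieModel:
    """Fit SuSiE from summary statistics (z, R, n).

    Sufficient statistics are reconstructed under the
    standardized-genotype, unit-variance-phenotype convention:
    ``r_j = z_j / sqrt(n - 2 + z_j^2)`` inverts the marginal t-statistic,
    then ``X'X = n R``, ``X'y = n r``, ``y'y = n``.  With an in-sample
    LD matrix this reproduces the individual-level fit.

    ``ld_reg`` shrinks R towards the identity, ``(1-ld_reg) R + ld_reg I``,
    for external reference panels with inconsistent LD.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    z, R, n = data.z, data.R, data.n
    p = z.size
    if pi is None:
        pi = PriorWeights.uniform(p)
    if pi.p != p:
        raise ValueError(f"prior length {pi.p} != number of variants {p}")

    if ld_reg > 0:
        R = (1.0 - ld_reg) * R + ld_reg * np.eye(p)
    min_eig = float(np.linalg.eigvalsh(R).min())
    if min_eig < -1e-8:
        raise DomainError(
            f"LD matrix is not positive semi-definite "
            f"(smallest eigenvalue {min_eig:.3e}); increase ld_reg"
        )

    r = z / np.sqrt(n - 2.0 + z * z)
    XtX = float(n) * R
    Xty = float(n) * r
    yty = float(n)
    return _ibss_suffstat(
        XtX, Xty, yty, n, K, pi, tol, max_iter,
        estimate_sigma0, estimate_sigma,
        sigma0_sq_init=sigma0_sq,
    )


# ---------------------------------------------------------------------------
# Credible sets
# ---------------------------------------------------------------------------


def build_credible_sets(
    model: SusieModel,
    R: np.ndarray,
    level: float = 0.95,
    min_purity: float = 0.5,
    dedup: bool = True,
    prior_tol: float = PRIOR_VAR_TOL,
) -> list[CredibleSet]:
    """Construct level-``level`` credible sets from a fitted model.

    For each non-null effect, variables are ranked by inclusion
    probability and the smallest prefix whose cumulative probability
    reaches ``level`` forms the candidate set.  Sets whose purity (the
    minimum absolute pairwise correlation; 1 for singletons) falls below
    ``min_purity`` are discarded, as are effects with prior variance
    below ``prior_tol``.  Identical member sets from different effects
    are deduplicated when ``dedup``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    R = np.asarray(R, dtype=float)
    if R.shape != (model.p, model.p):
        raise ValueError(f"R shape {R.shape} does not match p={model.p}")

    sets: list[CredibleSet] = []
    seen: set[frozenset[int]] = set()
    for k in model.effective_effects(prior_tol):
        row = model.alpha[k]
        order = np.argsort(-row, kind="stable")
        csum = np.cumsum(row[order])
        size = int(np.searchsorted(csum, level) + 1)
        size = min(size, model.p)
        if csum[size - 1] < level:
            continue  # row cannot reach the level (numerical edge)
        members = order[:size]
        if size == 1:
            purity = 1.0
        else:
            sub = np.abs(R[np.ix_(members, members)])
            iu = np.triu_indices(size, k=1)
            purity = float(sub[iu].min())
        if purity < min_purity:
            continue
        key = frozenset(int(j) for j in members)
        if dedup and key in seen:
            continue
        seen.add(key)
        sets.append(
            CredibleSet(
                members=tuple(int(j) for j in members),
                level=level,
                purity=purity,
                lead=int(members[0]),
                effect_index=int(k),
            )
        )
    return sets


def summarize_fit(
    model: SusieModel,
    R: np.ndarray,
    level: float = 0.95,
    min_purity: float = 0.5,
    dedup: bool = True,
) -> SusieFit:
    """Bundle a fitted model with its PIPs and credible sets."""
    return SusieFit(
        model=model,
        pip=model.pip(),
        credible_sets=build_credible_sets(
            model, R, level=level, min_purity=min_purity, dedup=dedup
        ),
    )
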