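"""Bayesian single-effect regression (SER).

The SER model assumes exactly one of ``p`` candidate variables carries a
nonzero effect ``lambda ~ N(0, sigma0_sq)``; which variable carries it is
multinomial with prior weights ``pi``.  Conditional on Gaussian residuals
with variance ``sigma_sq`` the posterior is available in closed form:

* per-variable Bayes factor against the null, computed from the marginal
  least-squares estimate ``bhat_j = xty_j / xtx_j`` and its sampling
  variance ``s_j^2 = sigma_sq / xtx_j``,
* posterior inclusion probabilities ``alpha_j`` proportional to
  ``pi_j * BF_j``,
* conjugate normal posterior for the effect given inclusion, with
  variance ``(1/sigma0_sq + xtx_j/sigma_sq)^-1``.

All Bayes-factor arithmetic is done in log space so the posterior stays
finite and normalized even for very large z-scores.  The prior effect
variance can be fixed or estimated by empirical Bayes (maximizing the SER
marginal likelihood).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

__all__ = [
    "DomainError",
    "SERSufficientStats",
    "PriorWeights",
    "SERPosterior",
    "fit_ser",
    "optimize_prior_variance",
]


class DomainError(ValueError):
    """A numerically valid input lies outside the model's domain."""


@dataclass(frozen=True)
class SERSufficientStats:
    """Sufficient statistics of one response against p predictors.

    ``xty[j] = x_j' y`` and ``xtx[j] = x_j' x_j`` for centered (and
    typically scaled) predictor columns; ``yty = y'y`` and ``n`` are used
    for residual-variance updates and prior-variance brackets.
    """

    xty: np.ndarray
    xtx: np.ndarray
    n: int
    yty: float

    def __post_init__(self) -> None:
        xty = np.asarray(self.xty, dtype=float)
        xtx = np.asarray(self.xtx, dtype=float)
        object.__setattr__(self, "xty", xty)
        object.__setattr__(self, "xtx", xtx)
        if xty.ndim != 1 or xtx.ndim != 1 or xty.shape != xtx.shape:
            raise ValueError(
                f"xty and xtx must be 1-d with equal length, "
                f"got {xty.shape} and {xtx.shape}"
            )
        if not np.all(xtx > 0):
            raise ValueError("xtx must be strictly positive for every variable")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")

    @property
    def p(self) -> int:
        return self.xty.shape[0]


@dataclass(frozen=True)
class PriorWeights:
    """Prior inclusion probabilities over p candidate variables.

    Entries must be strictly positive after any flooring applied upstream;
    they are normalized to sum to one on construction.
    """

    pi: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.ndim != 1 or pi.size == 0:
            raise ValueError("pi must be a non-empty 1-d vector")
        if not np.all(pi > 0):
            raise ValueError("prior weights must be strictly positive; floor zeros first")
        total = pi.sum()
        if not np.isfinite(total):
            raise ValueError("prior weights must be finite")
        object.__setattr__(self, "pi", pi / total)

    @classmethod
    def uniform(cls, p: int) -> "PriorWeights":
        return cls(np.full(p, 1.0 / p))

    @classmethod
    def with_floor(cls, weights: np.ndarray, floor: float = 1e-10) -> "PriorWeights":
        """Floor non-positive/small entries at ``floor`` then normalize."""
        w = np.asarray(weights, dtype=float)
        if floor <= 0:
            raise ValueError("floor must be positive")
        return cls(np.maximum(w, floor))

    @property
    def p(self) -> int:
        return self.pi.shape[0]


@dataclass(frozen=True)
class SERPosterior:
    """Closed-form SER posterior.

    ``alpha`` are posterior inclusion probabilities (summing to one);
    ``post_mean``/``post_mean2`` are the first two posterior moments of
    the effect *given* inclusion; ``logbf`` is the overall log Bayes
    factor of the SER against the all-null model.
    """

    alpha: np.ndarray
    post_mean: np.ndarray
    post_mean2: np.ndarray
    logbf_per_var: np.ndarray
    logbf: float
    sigma0_sq: float

    def __post_init__(self) -> None:
        if not np.isclose(self.alpha.sum(), 1.0, atol=1e-10):
            raise ValueError("alpha must sum to 1")


def _log_bf(
    stats: SERSufficientStats, sigma_sq: float, sigma0_sq: float
) -> np.ndarray:
    """Per-variable log Bayes factor of a N(0, sigma0_sq) effect vs null."""
    s2 = sigma_sq / stats.xtx
    bhat = stats.xty / stats.xtx
    z2 = bhat * bhat / s2
    return 0.5 * np.log(s2 / (s2 + sigma0_sq)) + 0.5 * z2 * sigma0_sq / (
        sigma0_sq + s2
    )


def _validate(stats: SERSufficientStats, sigma_sq: float, pi: PriorWeights) -> None:
    if pi.p != stats.p:
        raise ValueError(
            f"prior length {pi.p} does not match number of variables {stats.p}"
        )
    if sigma_sq <= 0 or not np.isfinite(sigma_sq):
        raise DomainError(f"residual variance must be positive, got {sigma_sq}")


def fit_ser(
    stats: SERSufficientStats,
    sigma_sq: float,
    sigma0_sq: float,
    pi: PriorWeights,
) -> SERPosterior:
    """Fit the single-effect regression posterior in closed form.

    Parameters
    ----------
    stats
        Sufficient statistics of the (residualized) response.
    sigma_sq
        Residual variance, must be positive.
    sigma0_sq
        Prior variance of the single effect; ``0`` collapses the SER to
        the null (alpha reverts to the normalized prior, zero effects).
    pi
        Prior inclusion weights.
    """
    _validate(stats, sigma_sq, pi)
    if sigma0_sq < 0 or not np.isfinite(sigma0_sq):
        raise DomainError(f"prior variance must be nonnegative, got {sigma0_sq}")

    if sigma0_sq == 0.0:
        p = stats.p
        zeros = np.zeros(p)
        return SERPosterior(
            alpha=pi.pi.copy(),
            post_mean=zeros,
            post_mean2=zeros.copy(),
            logbf_per_var=zeros.copy(),
            logbf=0.0,
            sigma0_sq=0.0,
        )

    lbf = _log_bf(stats, sigma_sq, sigma0_sq)
    log_w = np.log(pi.pi) + lbf
    log_total = logsumexp(log_w)
    alpha = np.exp(log_w - log_total)
    alpha /= alpha.sum()

    post_var = 1.0 / (1.0 / sigma0_sq + stats.xtx / sigma_sq)
    post_mean = post_var * stats.xty / sigma_sq
    post_mean2 = post_var + post_mean * post_mean
    return SERPosterior(
        alpha=alpha,
        post_mean=post_mean,
        post_mean2=post_mean2,
        logbf_per_var=lbf,
        logbf=float(log_total),
        sigma0_sq=float(sigma0_sq),
    )


def ser_logbf(
    stats: SERSufficientStats, sigma_sq: float, sigma0_sq: float, pi: PriorWeights
) -> float:
    """Overall SER log Bayes factor: logsumexp over pi-weighted variable BFs."""
    if sigma0_sq == 0.0:
        return 0.0
    lbf = _log_bf(stats, sigma_sq, sigma0_sq)
    return float(logsumexp(np.log(pi.pi) + lbf))


_SIGMA0_FLOOR = 1e-10


def optimize_prior_variance(
    stats: SERSufficientStats,
    sigma_sq: float,
    pi: PriorWeights,
    check_null_threshold: float = 0.1,
) -> float:
    """Empirical-Bayes estimate of the SER prior effect variance.

    Maximizes the SER marginal log-likelihood (equivalently the overall
    log Bayes factor) over ``sigma0_sq`` by bounded scalar search on the
    log scale, bracketed by ``[1e-10, yty/n]`` (the response variance is
    an upper bound for any single effect's variance share).  Returns 0
    when the null is competitive: the optimum must beat log BF = 0 by
    ``check_null_threshold`` nats, a parsimony bias that keeps pure-noise
    responses from retaining spurious effects.
    """
    _validate(stats, sigma_sq, pi)
    upper = max(stats.yty / stats.n, 10.0 * _SIGMA0_FLOOR)

    def neg_logbf(log_s0: float) -> float:
        return -ser_logbf(stats, sigma_sq, np.exp(log_s0), pi)

    res = minimize_scalar(
        neg_logbf,
        bounds=(np.log(_SIGMA0_FLOOR), np.log(upper)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if -res.fun <= check_null_threshold:
        return 0.0
    return float(np.exp(res.x))
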