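"""Synthetic two-layer genotype/expression/trait generator.

Emulates the generative model used throughout the package's benchmark
suite: ``L`` risk genes each carry ``M_el`` causal eQTLs drawn inside
the gene's cis window; half of each gene's eQTLs additionally act
directly on the trait, together with ``n_extra_direct`` causal SNPs
outside any gene.  Expression and trait follow additive linear models

    Y_el = sum_i beta_eli X_i + e_l,     e_l ~ N(0, sigma_el^2),
    Y_t  = sum_i beta_ti  X_i + sum_l gamma_l Y_el + e_0,

with effect sizes drawn ``beta_eli ~ N(0, (1 - sigma_el^2)/M_el)`` and
``beta_ti ~ N(0, (1 - sigma_t^2)/M_t)`` on standardized genotypes, and
``gamma_l = 1``.  Expression columns and the trait are standardized to
empirical unit variance, honoring Var(Y_el) = Var(Y_t) = 1.

Genotypes are LD-structured: latent Gaussian haplotypes with
block-diagonal AR(1) correlation (``rho^|i-j|`` within blocks) are
thresholded at MAF-derived quantiles and summed to diploid 0/1/2
dosages.

The error variances are solved from target heritabilities.  Writing
``g = L * gamma^2``, the independence approximation gives total trait
variance ``1 + g`` before standardization, of which the genetic share is
``(1 - sigma_t^2) + g * h2_eqtl``; hence

    sigma_t^2 = 1 + g * h2_eqtl - h2_total * (1 + g),

which requires ``h2_total >= g * h2_eqtl / (1 + g)`` (the mediated
genetic variance alone already contributes that much).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

__all__ = [
    "ScenarioConfig",
    "SimulatedRegion",
    "simulate_genotypes",
    "simulate_region",
    "scenario_preset",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Configuration of one simulated fine-mapping region."""

    L: int = 4                      # number of risk genes
    M_el: int = 2                   # causal eQTLs per gene (must be even)
    n_extra_direct: int = 0         # causal SNPs outside risk genes
    h2_total: float = 0.1           # trait heritability (genetic variance share)
    h2_eqtl: float = 0.04           # expression heritability per gene, 1 - sigma_el^2
    gamma: float = 1.0              # expression-on-trait coefficient
    n_e: int = 2000                 # eQTL cohort size
    n_t: int = 10000                # trait cohort size
    p: int = 1000                   # SNPs in the region
    gene_window: int = 100          # SNPs per gene cis window
    ld_rho: float = 0.9             # AR(1) latent LD within blocks
    block_size: int = 100           # SNPs per LD block
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    shared_cohort: bool = False     # trait cohort doubles as eQTL cohort

    def __post_init__(self) -> None:
        if self.M_el % 2 != 0 or self.M_el < 2:
            raise ValueError(f"M_el must be a positive even number, got {self.M_el}")
        if not 0.0 <= self.h2_total < 1.0:
            raise ValueError(f"h2_total must be in [0, 1), got {self.h2_total}")
        if not 0.0 < self.h2_eqtl < 1.0:
            raise ValueError(f"h2_eqtl must be in (0, 1), got {self.h2_eqtl}")
        if self.L >= 1 and self.gene_window * self.L > self.p:
            raise ValueError(
                f"{self.L} gene windows of {self.gene_window} SNPs do not fit "
                f"in p={self.p}"
            )
        g = self.L * self.gamma**2
        if self.h2_total > 0 and self.h2_total * (1 + g) < g * self.h2_eqtl:
            raise ValueError(
                "h2_total too small for the mediated variance: need "
                f"h2_total >= {g * self.h2_eqtl / (1 + g):.4f} with "
                f"L={self.L}, gamma={self.gamma}, h2_eqtl={self.h2_eqtl}"
            )

    @property
    def M_t(self) -> int:
        """Number of direct trait effects: half of each gene's eQTLs plus extras."""
        return self.L * self.M_el // 2 + self.n_extra_direct

    @property
    def sigma_el_sq(self) -> float:
        return 1.0 - self.h2_eqtl

    @property
    def sigma_t_sq(self) -> float:
        """Trait error variance solved from the heritability mapping."""
        g = self.L * self.gamma**2
        return 1.0 + g * self.h2_eqtl - self.h2_total * (1.0 + g)

    def gene_windows(self) -> list[np.ndarray]:
        """Evenly spaced, non-overlapping cis windows of ``gene_window`` SNPs."""
        starts = [int(np.floor(l * self.p / self.L)) for l in range(self.L)]
        return [np.arange(s, s + self.gene_window) for s in starts]


def scenario_preset(name: str, **overrides) -> ScenarioConfig:
    """Benchmark scenario presets.

    - ``"a"`` *all causal SNPs are eQTLs*: 4 genes x 2 eQTLs, no causal
      SNPs outside genes; 8 causal SNPs in total.
    - ``"b"`` *some causal SNPs are eQTLs*: as (a) plus 2 causal SNPs
      outside genes; 10 in total.
    - ``"c"`` *more genes and causal SNPs*: 10 genes x 2 eQTLs plus 10
      outside genes; 30 in total, heritability 0.2.
    """
    presets = {
        "a": dict(L=4, M_el=2, n_extra_direct=0, h2_total=0.1),
        "b": dict(L=4, M_el=2, n_extra_direct=2, h2_total=0.1),
        "c": dict(L=10, M_el=2, n_extra_direct=10, h2_total=0.2, gene_window=40),
    }
    if name not in presets:
        raise ValueError(f"unknown scenario {name!r}; choose from a, b, c")
    kwargs = {**presets[name], **overrides}
    return ScenarioConfig(**kwargs)


@dataclass
class SimulatedRegion:
    """One simulated region with ground truth.

    ``causal_eqtl[l]`` are gene ``l``'s causal eQTL indices;
    ``causal_direct`` the SNPs with direct trait effects.  Power and
    coverage downstream treat :attr:`causal_trait` — the union of
    direct and mediated causal SNPs — as truth.
    """

    config: ScenarioConfig
    X_e: np.ndarray               # n_e x p dosages (eQTL cohort)
    X_t: np.ndarray               # n_t x p dosages (trait cohort)
    Y_e: np.ndarray               # n_e x L standardized expression
    Y_t: np.ndarray               # length n_t standardized trait
    causal_eqtl: list[np.ndarray]
    causal_direct: np.ndarray
    beta_e: list[np.ndarray]      # per-gene eQTL effects (pre-standardization)
    beta_t: np.ndarray            # direct effects aligned with causal_direct
    R_insample: np.ndarray        # trait-cohort genotype correlation
    R_latent: np.ndarray          # latent block-AR(1) correlation
    maf: np.ndarray
    realized: dict = field(default_factory=dict)

    @property
    def causal_trait(self) -> np.ndarray:
        """Union of direct and mediated (eQTL) causal SNPs, sorted."""
        parts = [self.causal_direct] + list(self.causal_eqtl)
        return np.unique(np.concatenate(parts)) if parts else np.array([], int)


def _latent_ar1_correlation(p: int, rho: float, block_size: int) -> np.ndarray:
    R = np.eye(p)
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        idx = np.arange(start, stop)
        R[np.ix_(idx, idx)] = rho ** np.abs(idx[:, None] - idx[None, :])
    return R


def simulate_genotypes(
    n: int,
    p: int,
    ld_rho: float = 0.9,
    maf_range: tuple[float, float] = (0.05, 0.5),
    block_size: int = 100,
    rng: np.random.Generator | int | None = None,
    maf: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` diploid genotypes at ``p`` LD-structured variants.

    Two latent Gaussian haplotypes per individual follow block-diagonal
    AR(1) correlation and are thresholded at ``Phi^{-1}(maf_j)``; the
    dosage is the sum of the two derived alleles.  Returns ``(X, R)``
    with ``R`` the latent correlation (the reference LD).
    """
    if n < 2 or p < 1:
        raise ValueError(f"need n >= 2 and p >= 1, got n={n}, p={p}")
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError(f"ld_rho must be in [0, 1), got {ld_rho}")
    lo, hi = maf_range
    if not 0.0 < lo < hi <= 0.5:
        raise ValueError(f"degenerate maf_range {maf_range}")
    rng = np.random.default_rng(rng)
    if maf is None:
        maf = rng.uniform(lo, hi, size=p)

    scale = np.sqrt(1.0 - ld_rho**2)
    Z = rng.standard_normal((2 * n, p))
    for j in range(1, p):
        if j % block_size:  # block boundaries restart the AR(1) chain
            Z[:, j] = ld_rho * Z[:, j - 1] + scale * Z[:, j]
    thresh = norm.ppf(maf)
    alleles = (Z < thresh).astype(np.int8)
    X = (alleles[:n] + alleles[n:]).astype(float)
    R = _latent_ar1_correlation(p, ld_rho, block_size)
    return X, R


def _standardize_cols(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    return Xc / sd


def simulate_region(config: ScenarioConfig) -> SimulatedRegion:
    """Simulate one region under the two-layer model of ``config``."""
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_ge, rng_gt, rng_eff, rng_ne, rng_nt = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    cfg = config
    p, L = cfg.p, cfg.L

    maf = rng_struct.uniform(*cfg.maf_range, size=p)
    windows = cfg.gene_windows()
    in_gene = np.zeros(p, dtype=bool)
    for w in windows:
        in_gene[w] = True

    # causal bookkeeping: M_el eQTLs per window, half of them direct,
    # plus extra direct SNPs outside every gene window
    causal_eqtl = [
        np.sort(rng_struct.choice(w, size=cfg.M_el, replace=False)) for w in windows
    ]
    direct: list[np.ndarray] = [
        np.sort(rng_struct.choice(ce, size=cfg.M_el // 2, replace=False))
        for ce in causal_eqtl
    ]
    outside = np.flatnonzero(~in_gene)
    if cfg.n_extra_direct > 0:
        if outside.size < cfg.n_extra_direct:
            raise ValueError(
                f"only {outside.size} SNPs outside gene windows, cannot place "
                f"{cfg.n_extra_direct} extra direct effects"
            )
        direct.append(
            np.sort(rng_struct.choice(outside, size=cfg.n_extra_direct, replace=False))
        )
    causal_direct = np.sort(np.concatenate(direct)) if direct else np.array([], int)

    X_t, R_latent = simulate_genotypes(
        cfg.n_t, p, cfg.ld_rho, cfg.maf_range, cfg.block_size, rng=rng_gt, maf=maf
    )
    if cfg.shared_cohort:
        X_e = X_t[: cfg.n_e]
    else:
        X_e, _ = simulate_genotypes(
            cfg.n_e, p, cfg.ld_rho, cfg.maf_range, cfg.block_size, rng=rng_ge, maf=maf
        )

    Xs_e = _standardize_cols(X_e)
    Xs_t = _standardize_cols(X_t)

    beta_e = [
        rng_eff.normal(0.0, np.sqrt(cfg.h2_eqtl / cfg.M_el), size=cfg.M_el)
        for _ in range(L)
    ]
    if cfg.M_t > 0 and cfg.sigma_t_sq < 1.0:
        beta_t = rng_eff.normal(
            0.0, np.sqrt((1.0 - cfg.sigma_t_sq) / cfg.M_t), size=causal_direct.size
        )
    else:
        beta_t = np.zeros(causal_direct.size)

    sd_el = np.sqrt(cfg.sigma_el_sq)
    # observed expression (eQTL cohort) and latent expression (trait cohort)
    Y_e = np.empty((cfg.n_e, L))
    expr_t_genetic = np.zeros(cfg.n_t)
    expr_t_total = np.zeros(cfg.n_t)
    for l in range(L):
        g_e = Xs_e[:, causal_eqtl[l]] @ beta_e[l]
        Y_e[:, l] = g_e + rng_ne.normal(0.0, sd_el, size=cfg.n_e)
        g_t = Xs_t[:, causal_eqtl[l]] @ beta_e[l]
        lat = g_t + rng_nt.normal(0.0, sd_el, size=cfg.n_t)
        expr_t_genetic += cfg.gamma * g_t
        expr_t_total += cfg.gamma * lat

    direct_t = Xs_t[:, causal_direct] @ beta_t if causal_direct.size else 0.0
    e0 = rng_nt.normal(0.0, np.sqrt(max(cfg.sigma_t_sq, 0.0)), size=cfg.n_t)
    Y_t_raw = direct_t + expr_t_total + e0

    # standardize to empirical unit variance; record realized shares
    sd_e = Y_e.std(axis=0)
    sd_e[sd_e == 0] = 1.0
    Y_e = Y_e / sd_e
    sd_t = Y_t_raw.std()
    if sd_t == 0:
        sd_t = 1.0
    Y_t = Y_t_raw / sd_t

    genetic = np.asarray(direct_t) + expr_t_genetic
    realized = {
        "scale_expression": sd_e,
        "scale_trait": float(sd_t),
        "var_direct": float(np.var(np.asarray(direct_t))) / sd_t**2,
        "var_mediated_genetic": float(np.var(expr_t_genetic)) / sd_t**2,
        "h2_realized": float(np.var(genetic)) / sd_t**2,
        "sigma_t_sq": cfg.sigma_t_sq,
        "sigma_el_sq": cfg.sigma_el_sq,
    }

    R_insample = Xs_t.T @ Xs_t / cfg.n_t
    return SimulatedRegion(
        config=cfg,
        X_e=X_e,
        X_t=X_t,
        Y_e=Y_e,
        Y_t=Y_t,
        causal_eqtl=causal_eqtl,
        causal_direct=causal_direct,
        beta_e=beta_e,
        beta_t=beta_t,
        R_insample=R_insample,
        R_latent=R_latent,
        maf=maf,
        realized=realized,
    )
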