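# Methods

## Single-effect regression (SER)

The SER assumes exactly one of p variables has a nonzero effect
`lambda ~ N(0, sigma0^2)`; the identity of that variable is multinomial with
prior weights `pi`. With Gaussian residuals of variance `sigma^2`, the
posterior is conjugate: for variable j with marginal least-squares estimate
`bhat_j = x_j'y / x_j'x_j` and sampling variance `s_j^2 = sigma^2 / x_j'x_j`,

```
log BF_j = 0.5 log(s_j^2 / (s_j^2 + sigma0^2))
         + 0.5 z_j^2 sigma0^2 / (sigma0^2 + s_j^2),
alpha_j  prop. to  pi_j exp(log BF_j),
posterior variance given inclusion = (1/sigma0^2 + x_j'x_j/sigma^2)^-1.
```

All Bayes-factor arithmetic is in log space (log-sum-exp), so `alpha` stays
finite and normalized even at |z| around 40. `alpha` is invariant to
rescaling `pi`, and as `sigma0^2 -> 0` every BF tends to 1 and `alpha`
reverts to the prior.

The prior variance is estimated per effect by empirical Bayes: bounded
scalar maximization of the SER log Bayes factor over `log sigma0^2` on
`[1e-10, y'y/n]` (the response variance bounds any single effect's share).
The optimum must beat the null by 0.1 nats or `sigma0^2` is set to 0 — the
null-comparison margin used by reference SuSiE implementations; without it,
pure-noise responses retain spurious effects whose flat `alpha` rows inflate
PIPs by about K/p. Effects with `sigma0^2 < 1e-9` are treated as null and
excluded from PIP aggregation and credible sets.

## IBSS and the ELBO

The full model sums K single effects. IBSS updates each effect in turn
against the residual that removes the other effects' posterior means,
entirely through the sufficient statistics `(X'X, X'y, y'y, n)`. The
variational objective

```
ELBO = -n/2 log(2 pi sigma^2) - ERSS/(2 sigma^2) - sum_k KL_k
```

uses the expected residual sum of squares under the factorized posterior and
the per-effect KL to the SER prior obtained from the SER evidence identity
(`KL_k = E_q log p(r_k|b_k) - log p(r_k)`). With fixed hyperparameters the
trace is non-decreasing; iteration stops when the change drops below `tol`
(default 1e-3) or after `max_iter` (default 100) sweeps. `sigma^2` is
updated as ERSS/n when estimated. Genotype columns are centered and scaled
to unit variance; constant columns are dropped with a warning and reported
with PIP 0.

**Summary statistics.** Given `(z, R, n)` under the standardized-genotype,
unit-variance-phenotype convention, `r_j = z_j / sqrt(n - 2 + z_j^2)`
inverts the marginal t statistic, then `X'X = nR`, `X'y = nr`, `y'y = n`.
Because PIPs are invariant to the scale of y once `sigma^2` and `sigma0^2`
are estimated, this reproduces the individual-level fit exactly when R is
the in-sample LD. R must be positive semi-definite (checked via its smallest
eigenvalue); `ld_reg` shrinks external-panel LD toward the identity,
`(1-lambda)R + lambda I`, default 0 in-sample and 1e-3 suggested for
external panels.

**Credible sets.** Per non-null effect, variables are ranked by `alpha` and
the smallest prefix reaching the level (default 0.95) forms the candidate
set; purity is the minimum absolute pairwise correlation (1 for singletons),
sets below `min_purity` (default 0.5; 0.9 in stringent real-data configs)
are discarded, and identical member sets across effects are deduplicated.

## The two-layer prior

Each risk gene's expression is regressed on the region's variants with its
own SuSiE fit; `PIP^e = 1 - prod_k (1 - alpha_k)` per gene. Genes are
combined symmetrically by the same complement-product rule,
`1 - prod_genes (1 - PIP^e_g)` — the probability of being an eQTL for at
least one gene — then floored at 1e-10 (SuSiE's convergence theory needs
strictly positive priors) and normalized to sum to one (only relative
weights enter the SER posterior). The trait layer is an ordinary SuSiE fit
with this prior; a flat prior reproduces single-trait SuSiE bit for bit.

By default each gene is fit on the *full* candidate region rather than only
its cis window. This matters: restricting to windows forces `PIP^e = 0`
outside them, and after flooring, a true trait signal the eQTL layer missed
carries prior weight ~1e-10 against ~0.1 for eQTL hits; its weighted Bayes
factor can then fall below the null, the effect is estimated away, and the
credible set is lost. Full-region eQTL fits keep every variant's prior
bounded away from the floor, making the prior informative but never
destructive. Window restriction remains available (`gene_windows`,
`restrict_windows`) for cis-only designs. The two layers may use different
LD sources (e.g. in-sample eQTL genotypes with an external trait panel).

## Synthetic-data generator

Genotypes: per haplotype, a latent Gaussian vector with block-diagonal AR(1)
correlation (`rho^|i-j|` within blocks of `block_size` SNPs, default 100,
`ld_rho` default 0.9) is thresholded at `Phi^{-1}(maf_j)` with per-column
MAF uniform on `maf_range` (default 0.05–0.5); dosage = sum of two
haplotypes. The latent correlation is returned as reference LD; the
in-sample dosage correlation is computed from the trait cohort.

Phenotypes follow the two-layer additive model: for gene l,
`Y_el = sum_i beta_eli X_i + e_l` with `beta_eli ~ N(0, h2_eqtl/M_el)` and
`e_l ~ N(0, 1 - h2_eqtl)` on its M_el causal eQTLs (sampled uniformly inside
the gene's window); the trait is
`Y_t = sum_i beta_ti X_i + sum_l gamma Y_el + e_0` over M_t direct effects —
half of each gene's eQTLs plus `n_extra_direct` variants outside every
window. Expression and trait are standardized to empirical unit variance;
the realized direct/mediated/error shares are recorded.

**Variance accounting.** With `gamma=1` and unit-variance expression, the
mediated term alone contributes variance `g = L gamma^2` before
standardization, so the printed coefficient variances cannot coexist with a
unit-variance trait; standardization honors the unit-variance constraint and
the error variances are solved from target heritabilities instead. Under an
independence approximation the total pre-scale variance is `1 + g` and the
genetic share is `(1 - sigma_t^2) + g h2_eqtl`, giving

```
sigma_t^2 = 1 + g h2_eqtl - h2_total (1 + g),
```

valid when `h2_total >= g h2_eqtl / (1 + g)` — the mediated genetic variance
alone already contributes that much, so configurations below the bound are
rejected with a message. Defaults: `h2_eqtl = 0.04` (a realistic cis
expression heritability; at trait heritabilities below 0.036 for L=4 the
user must lower it), `h2_total = 0.1` (0.2 for the many-gene scenario),
`n_t = 10,000`, `n_e = 2,000` (an expression cohort an order of magnitude
smaller than the GWAS, as in practice), `p = 1,000` SNPs with gene windows
of 100.

Scenario presets: (a) 4 genes x 2 eQTLs, no causal SNPs outside genes — 8
causal; (b) as (a) plus 2 outside — 10 causal; (c) 10 genes x 2 eQTLs plus
10 outside — 30 causal, heritability 0.2. RNG streams are split per
component (structure, genotypes per cohort, effects, noise per cohort) so
the same seed reproduces a region bit for bit and changing one component
does not perturb the others.

**What the generator does and does not emulate.** It reproduces LD-blocked
common variants, two cohorts of different sizes, and the mediated/direct
causal structure. It does *not* reproduce real-panel LD: thresholding
attenuates the latent AR(1) correlation (adjacent dosage r roughly 0.75–0.85
at `ld_rho = 0.9`) and correlation decays geometrically, whereas real
regions contain long stretches of near-perfect proxies. Consequently
credible sets on synthetic data are small (typically singletons) and
baseline SuSiE already resolves every variant with |z| above ~4, leaving
little headroom for prior information to add power: an oracle prior placed
on the true causal set improves power by only a few percent here, far below
what eQTL priors deliver on real LD, where uniform-prior dilution across
thousands of variants and impure candidate sets leave many signals for the
prior to rescue. Passing benchmarks on this generator therefore demonstrates
correctness, coverage control, and calibration — not the real-data
magnitude of the power gain or of credible-set shrinkage.

## Evaluation

Power is the fraction of true causal SNPs (union of direct and mediated) in
at least one credible set; coverage the fraction of credible sets containing
a causal SNP; average size the mean cardinality. All three are reported
pooled over replicates (total counts) and as per-replicate means with
empirical standard errors; coverage is *missing*, not zero, when no sets
were produced. PIP calibration pools SNPs over replicates into 10 evenly
spaced right-closed bins on [0, 1] (PIP 0 in the first bin, 1 in the last)
and compares each bin's mean PIP with its fraction of truly causal SNPs.

Calibration benchmarks fit with K above the true causal count (35 for the
30-causal scenario) so the model class contains the generative truth; with
K far below the causal count the PIP vector cannot represent most causal
SNPs and the comparison measures misspecification rather than PIP quality.
A known limitation remains at the bottom bin: dropping null effects makes
sparse variational PIPs conservative near zero, so the lowest bin's causal
fraction (a few percent when 6% of SNPs are causal) exceeds its mean PIP by
more than its binomial standard error even when every other bin tracks the
diagonal.

## Real-data plumbing

Summary statistics are read from delimited text under a column-dialect map
(SNP/rsid, BP/POS, A1/EA, ... with an explicit override; ambiguous headers
are an error). Filters: minor allele frequency (folded; default minimum
0.01) and per-SNP sample size (e.g. 500,000 for meta-analyses with
heterogeneous coverage); z and p are cross-checked for consistency within
10%. Candidate regions are built around hits with p below 5e-7: a ±50 kb
window per hit, overlapping or touching windows merged transitively,
coordinates 1-based inclusive and clamped at 1. Allele harmonization
matches on the unordered allele pair, flips z when effect alleles are
swapped, and logs strand-ambiguous (A/T, C/G) pairs. Genotypes are read
from PLINK-1 bed/bim/fam (dosages count the bim A1 allele; missing as NaN)
or delimited matrices.

## Benchmark problem sizes

The shipped study uses 50 replicates per setting with p=500 SNP regions,
n_trait=10,000, n_eqtl=500, K=5, 95% credible sets with minimum purity 0.5,
and in-sample LD — chosen so the full study runs in minutes on one CPU
while pooling well over 300 credible sets per coverage estimate.
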