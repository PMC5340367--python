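# Methods and numerical notes

## Model

A continuous trait `y` on a rooted tree with branch lengths is modelled as
multivariate normal, `y ~ N(mu * 1, sigma2 * C)`, where `C[i, j]` is the
root-to-MRCA path length shared by tips `i` and `j` (the BM
variance–covariance matrix, "VCV"). For every candidate covariance the
profile ML estimates are

```
mu_hat     = (1' C^-1 1)^-1  1' C^-1 y
sigma2_hat = r' C^-1 r / n            with r = y - mu_hat * 1
lnL        = -1/2 [ n ln 2pi + n ln sigma2_hat + ln det C + n ]
```

computed through a Cholesky factor of `C` (never an explicit inverse). If a
factorization fails, a ridge of `1e-10 * mean(diag C)` is added once.

### Pagel transforms

- `lambda` in `[0, 1]`: multiplies the off-diagonal of `C`.
- `kappa` in `[0, 3]`: raises every branch length to the power kappa before
  `C` is assembled. `0 ** 0 = 1` (zero-length branches become length 1 under
  kappa = 0), matching the numpy convention.
- `delta` in `(0, 3]`: raises the entries of `C` (node depths) to the power
  delta. Because `delta = 0` degenerates the covariance, the numerical
  lower bound is `1e-6`; the "test versus zero" LR statistic compares
  against this bound, and any boundary test where the estimate already sits
  on the tested bound reports p = 1.

When a simulated trait combines transforms, the order is kappa (branch
lengths), then delta (depths), then lambda (off-diagonal scaling).

### Estimation

Each parameter is profiled with L-BFGS-B (`ftol 1e-12`, `gtol 1e-10`,
finite-difference step `1e-7`) from starts at 0.25, 0.5 and 0.75 of the
parameter range, and the candidate set additionally includes both bounds
and the value 1. Ties in log-likelihood break toward the smaller parameter
value. Boundary tests use the likelihood ratio against chi-square with one
degree of freedom; this is the conventional reference distribution even
though the null lies on the boundary, so boundary p-values are
conservative by up to a factor of two.

## Permutation statistics

All three use tip-label shuffles of the trait and the `(r + 1) /
(n_perm + 1)` p-value convention (smallest reportable p with 999
permutations: 0.001).

- **Blomberg's K**: ratio of the observed MSE0/MSE to its BM expectation
  `[tr C - n / (1' C^-1 1)] / (n - 1)`; the permutation test counts
  permutations whose phylogenetic MSE is at most the observed one.
  Permutations are evaluated vectorised through one Cholesky solve.
- **Abouheif's Cmean**: the proximity between two tips is the product of
  `1 / (number of direct descendants)` over the internal nodes on the path
  through their MRCA (the MRCA itself included, the tips excluded). The
  weight matrix is row-normalised and then divided by its total, and the
  statistic is `z' W z` with `z` the trait standardised with divisor `n`.
- **Moran's I**: weights `1 / patristic distance`, row-standardised;
  `I = z' W z / z' z`; null expectation `-1 / (n - 1)`. Two tips at
  patristic distance zero are reported as an error (the weight is
  undefined), naming the offending pair.

## Regression

OLS and PGLS share one whitened-least-squares core: with `L` the Cholesky
factor of the error covariance, the model is fitted on `L^-1 y` and
`L^-1 X`. The model F statistic compares the full fit to the
intercept-only fit under the same error structure, with `F(p, n - p - 1)`
reference. PGLS profiles lambda over [0, 1] by ML (same optimizer settings
as above); `lambda_` fixes it instead. Species present in the tree, trait
and covariate tables are intersected, with dropped species logged. Rank
deficiency is reported with the names of columns whose removal restores
full rank. Perfect fits and zero-variance responses are flagged
`degenerate` rather than reported as significant.

## Subsampling reliability experiment

For taxa counts (5, 10, 15, 20, 30) and 20 replicates per count, a random
subtree is drawn and all six statistics recomputed. Per-replicate seeds
come from a splitmix64-style hash of (master seed, count, replicate), so
any single replicate can be regenerated in isolation. One-way fixed-effects
ANOVA tests dependence of each statistic (or its boundary p-value; the
"opposite bound" p is `p_vs_zero` when the estimate is ≥ 0.5 and `p_vs_one`
otherwise) on taxa count. The ANCOVA uses sequential (type-I) sums of
squares for Taxa, trait range, and their interaction; a constant trait
range drops the interaction with a warning, and designs without residual
degrees of freedom are rejected.

## Synthetic generators

- Yule trees: crown start with two lineages, waiting times
  `Exp(k * birth_rate)`, uniform choice of the splitting lineage, final
  common extension — trees are exactly ultrametric. Default birth rate 1.
- BM traits: exact draws `root + sqrt(sigma2) * L z` from the transformed
  VCV. Defaults `root = 215` and `sigma2 = 1000` put tip values on the
  scale of drosophilid genome sizes in Mbp (sd ~ 60 Mbp on a ~90-tip
  unit-rate Yule tree), roughly the 3-fold spread of the packaged table.
- Climate covariates: independent BM draws under a chosen signal lambda,
  standardised and affinely rescaled to plausible ranges for eight named
  variables (thermal limits, temperatures, precipitation, latitude). The
  affine rescaling does not change any regression F statistic because the
  design includes an intercept.
- The packaged genome-size table: 87 species, female 1C sizes in Mbp to one
  decimal, guarded by a SHA-256 checksum. Its mean is 215.8; a published
  summary of the same values states 215.5, an internal inconsistency in the
  source that the package preserves rather than edits.

The generators reproduce statistical structure (tree shape, trait scale,
covariate signal), not biology: no extinction, no rate heterogeneity across
clades, no measurement error, and covariates are mutually independent.

## Known limitation: PGLS type-I error with estimated lambda

With the error covariance *known* (lambda fixed at its generating value),
the PGLS model F test is exact: across 3000 null replicates (38-tip trees,
eight phylogenetic covariates, independent BM trait) the rejection rate at
alpha = 0.05 was 0.045–0.050 and the p-values were KS-uniform.

With lambda *estimated* by ML from the same data — the realistic pipeline —
the rate rises to ~0.13 under these conditions (600 tree-marginal
replicates; 0.09–0.17 across individual trees), while ordinary regression
rejects ~80% of the time. The excess is the finite-sample cost of
estimating the error structure with n = 38 and p = 8 heavily collinear
phylogenetic covariates; it shrinks with more tips or fewer covariates and
is a known property of ML-lambda PGLS, not a defect of the fitting code.
`tests/test_acceptance.py` asserts the exact-calibration and
OLS-versus-PGLS contrasts (both pass) and keeps the literal near-nominal
band as an intentionally failing test documenting this behaviour.

A practical footnote from the same investigation: deriving per-replicate
seeds as arithmetic sequences (e.g. `11 s + 1`, `11 s + 2`) produced a
spuriously elevated rate in one experiment; all replicated experiments in
the tests draw seeds from a single generator stream instead.

## Problem sizes

Typical runtimes on this codebase: an 87-tip signal panel with 999
permutations in ~1 s; the full subsampling design (100 subtrees, six
statistics, 199 permutations each) in ~5 s; the acceptance script in ~10 s;
the full test suite in ~5 minutes (dominated by the calibration and
recovery experiments).
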