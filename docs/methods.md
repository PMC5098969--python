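# Methods

This note documents the statistical machinery implemented in `phenonet`, the
assumptions behind it, and the choices made where the design was genuinely
open.

## The model

Behavioural descriptors of working dogs are rated by their handlers on an
ordinal 1–5 agreement scale. The analysis treats each descriptor as a
coarsened view of a latent continuous trait: subject latents follow a
multivariate normal whose inverse covariance (precision) matrix K encodes
conditional independence. The quantity of scientific interest is the sparse
partial-correlation network

    W_ij = -K_ij / sqrt(K_ii K_jj),   i != j,

whose absent edges mean "no association beyond what the remaining
descriptors explain". Estimation proceeds in stages:

1. **Cleaning.** Descriptors with ≥ 10% zero ("not relevant / don't know")
   codes are removed (inclusive boundary); subjects with more than 15% zeros
   are dropped (the instance-derived default; configurable); remaining zeros
   become missing; descriptors with **strictly more** than 5% missing are
   removed; near-duplicate descriptor pairs (pairwise-complete polychoric
   |rho| > 0.8) are collapsed, dropping the member with the larger mean
   absolute correlation to everything else (a keep-list can override, since
   "which member is more specific" is not computable from data).
2. **Multiple imputation.** An EM-with-bootstrap imputer: each of m = 15
   imputations bootstraps the rows, fits a multivariate-normal mean and
   covariance by EM (ordinal codes treated as continuous; group and rater
   entered as single numeric codes), and draws missing cells from their
   conditional normals. Copies are averaged, rounded half away from zero
   and clamped to [1, 5]; observed cells are never altered.
3. **Rater screens.** For raters contributing ≥ 2 subjects, a
   between/within-rater mean-square ratio flags descriptors whose repeated
   ratings by the same handler lack independence; the cut-off is the 99th
   percentile of a permutation null (responses shuffled across subjects
   within group, 500 permutations) — a scale-free rule chosen because no
   absolute threshold is defensible a priori. A final screen drops
   descriptors with variation ratio (share of non-modal responses) below
   0.15.
4. **Polychoric correlation.** Two-step maximum likelihood per pair:
   thresholds from the inverse-normal transforms of the marginal cumulative
   proportions, then the latent correlation by bounded scalar optimization
   of the multinomial likelihood with bivariate-normal rectangle
   probabilities. Estimates are clamped at |rho| = 0.999 (flagged). The
   bivariate normal CDF is computed exactly through Owen's T function
   (`scipy.special.owens_t`); the generic `multivariate_normal.cdf` agrees
   to ~1e-14 but is two orders of magnitude slower, which matters because
   the bootstrap machinery re-estimates hundreds of thousands of pairs.
   Pairwise matrices need not be positive semidefinite; repair is by
   eigenvalue clipping at 1e-6 followed by rescaling to unit diagonal,
   applied only when needed and recorded.
5. **Network estimation.** Graphical lasso (L1-penalized precision
   estimation, diagonal unpenalized) along a 100-point log-spaced lambda
   path from lambda_max = max|S_ij| down to 1% of it. Model selection
   minimizes the Extended Bayesian Information Criterion

       EBIC = -2 l + E log n + 4 E gamma log p,

   with ties broken toward the sparser model. The solver is an in-package
   numba block-coordinate-descent implementation, warm-started along the
   path; sklearn's `graphical_lasso` is used as an independent cross-check
   in the tests (support and values agree), not as the implementation —
   sklearn's solver is orders of magnitude slower on the small-n,
   ill-conditioned matrices the bootstrap produces, and its LARS mode fails
   outright on them.
6. **Gamma choice.** gamma is scanned over [0, 1] in 0.05 steps and the
   largest ("most conservative") value at which every group's network is
   still non-empty is chosen jointly across groups; a fixed gamma can be
   forced in the config.
7. **Centrality.** Strength s(v) = sum of |incident weights|; betweenness
   b(v) counts shortest paths through v with edge length 1/|w| and
   fractional credit for ties (Brandes), unnormalized. This is the weighted
   convention of the network-psychometrics tooling; it is recorded as an
   assumption because no formal definition is available to verify against.
8. **Comparison and stability.** Non-parametric bootstrap (subjects
   resampled with replacement; default B = 2000) per group; per replicate
   the combined centrality of a node is the raw mean of betweenness and
   strength (a z-standardized variant is available — the scales differ, and
   which was intended is ambiguous; the raw mean is the literal reading).
   Group differences per descriptor use Cliff's delta on the two B-length
   combined-centrality distributions, with |delta| < 0.25 labelled
   negligible, and a normal CI from the consistent variance estimator.
   Stability uses node-wise resampling (random node subsets, all subjects)
   and subject-wise case-dropping (random subject subsets **without**
   replacement, ten retention levels from 25% to 95%), reporting the mean
   product-moment and rank correlation between bootstrapped and original
   centralities per level. Node-wise re-estimation uses the cached full
   polychoric matrix restricted to the drawn nodes — pairwise estimates do
   not depend on the other columns, so this is mathematically identical and
   much faster.

### EBIC likelihood: penalized vs refit

Two scoring variants are implemented. The default scores each path model
with the penalized estimate's own likelihood (the behaviour of the common
software implementations). The `refit=True` variant scores (and returns)
each candidate support as its support-restricted maximum-likelihood fit
(classical covariance selection, implemented as a block-coordinate numba
kernel), which is the form in which the criterion's model-selection
consistency holds. The difference matters: with the penalized likelihood
the selected model carries many spurious edges of negligible magnitude
(|partial| < 0.03 in our calibration runs), because reducing shrinkage bias
on true edges pays for the extra penalty; with refit scoring those edges no
longer buy likelihood and specificity rises from ~0.8 to > 0.9 at p = 10,
n = 2000, gamma = 0.5. The recovery suites therefore evaluate the refit
variant; the pipeline default remains the software convention.

## Synthetic data generator

No raw survey data are deposited, so a generator stands in for them and
gives every downstream stage a known truth:

- **True network**: p nodes, a requested fraction of the p(p-1)/2 edges,
  magnitudes uniform in [0.2, 0.4] by default, 25% negative. Weights are
  placed in a unit-diagonal precision matrix; if its smallest eigenvalue
  falls below 0.05, delta·I is added and the matrix rescaled to correlation
  form — this guarantees validity at any density but shrinks all partial
  correlations by 1/(1+delta); a delta above 1 is treated as an infeasible
  request.
- **Latent scores** are multivariate normal with the implied correlation;
  each rater contributes an additive N(0, rater_sd²) intercept shared by
  all of that rater's subjects and all descriptors — the simplest mechanism
  that induces the between-rater dependence the cleaning stage screens for.
  The study-shaped datasets use rater_sd = 0.3 (no empirical value exists;
  it is exposed in the config).
- **Discretization** by four per-descriptor cut-points on the latent scale;
  the study-shaped fixture uses strongly skewed category probabilities
  (modal response 5 for desirable items, 1 for undesirable ones, variation
  ratios ~0.2–0.6) mimicking published handler-survey marginals.
- **Missingness** is completely at random, by default at different rates
  per group (0.8% patrol, 2% detection; ~1.2% overall), because missingness
  empirically differed by dog type. Zero codes are injected at low rates
  concentrated in a few relevance-dependent descriptors. Missing is a
  dedicated sentinel, distinct from the zero code.
- The **study-shaped fixture** has 117 + 54 subjects, 20 descriptors and
  117 raters (171/117 = 1.46 surveys per rater), deterministic under its
  seed.

What the generator does **not** emulate: breed structure, longitudinal
ratings, informative missingness beyond group membership, rater effects
that vary by descriptor, and the semantic redundancy structure of a real
instrument. Passing tests therefore demonstrate internal statistical
correctness and recoverability under the latent-normal model, not
robustness to violations of it.

## Numerical choices

- Polychoric optimizer: bounded Brent on [-0.999, 0.999], xatol 1e-5;
  rectangle probabilities floored at 1e-12; boundary solutions clamped and
  flagged. Degenerate variables (< 2 observed categories) are excluded and
  reported rather than fatal in matrix estimation, but any degenerate
  column fails a bootstrap replicate (counted, and > 20% failures abort).
- Glasso: convergence when the mean absolute covariance update falls below
  tol × mean|S_offdiag| (tol 1e-5 in selection); edges are entries with
  |W| > 1e-10 after symmetrization.
- EM imputer: convergence when the largest parameter change < 1e-4, cap 200
  iterations; singular covariances repaired with a 1e-3 ridge and logged.
- Edge-count monotonicity along the lambda path is **not** a theorem:
  on noisy sample matrices the exact glasso solution occasionally drops an
  edge of negligible magnitude as lambda decreases (verified against an
  independent solver at tolerance 1e-12; consistent with the known
  non-nestedness of glasso sparsity patterns). On noise-free latent
  correlation matrices of sparse truths the property holds exactly, and
  that is the regime the invariant suite asserts.
- All randomness flows from explicit integer seeds; the pipeline splits one
  master seed into per-stage seeds, so a manifest replay is bit-identical.

## Problem sizes in tests and examples

The study analysis used B = 2000 bootstrap replicates throughout; that
remains the library default. The packaged examples, the acceptance script
and the test suite use down-scaled sizes chosen as reasonable demonstration
workloads: B = 100–200 for bootstrap and stability runs, 30–50 generator
seeds for recovery summaries, and reduced stability level grids
(node subsets {3, 10, 19}, retention {60%, 95%}) in the end-to-end
determinism check. Directional and calibration conclusions are insensitive
to these sizes; only Monte-Carlo noise changes.

## Known limitations

- Ordinal codes are treated as continuous during imputation (by design,
  matching the average-then-round convention); with five strongly skewed
  categories this can bias extreme-category probabilities slightly.
- The rater-independence permutation screen tests marginal rater
  dependence per descriptor; a rater effect shared across all descriptors
  (as the generator produces) inflates all ratios jointly, so the screen's
  per-descriptor removals on synthetic data are somewhat arbitrary.
- Cliff's-delta CIs use the asymptotic normal form without the Fisher-type
  transformation; at B = 2000 the difference is negligible.
- The gamma scan refits the whole path at every grid value; with very
  ill-conditioned inputs the low-lambda end of the path can dominate run
  time.
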