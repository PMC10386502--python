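# Methods

This note documents the statistical procedures, the synthetic-cohort
generator, the numerical choices, and the known limitations of
`metaborank`.

## Preprocessing

Raw intensities are strictly positive. The fixed pipeline is

1. **natural log** (the base only rescales coefficients, never ranks);
2. **batch median/MAD normalization** — per feature and batch, subtract
   the batch median and divide by the batch MAD scaled by 1.4826 so the
   MAD estimates the SD under normality. A zero batch MAD falls back to
   the feature's global MAD (logged); a zero global MAD marks the feature
   degenerate;
3. **global standardization** to mean 0 and unit (n−1) SD per feature.

Degenerate features are kept as zero columns rather than dropped so
feature indexing is identical across every ranking method; they are
scored missing by the univariate screen and carry zero weight everywhere
else. Scaling is applied globally (not per outcome group). The pipeline
is idempotent at the scaling stage to 1e-12.

## Univariate screen

Each feature is fit by maximum-likelihood logistic regression on
{intercept, feature, age (linear, centred), sex (single indicator)}.
Fits are Newton–Raphson, batched across features with a 1e-8 max-gradient
convergence criterion and a 1e-10 Hessian ridge to guard exactly singular
steps; results match `statsmodels.Logit` to 1e-6 (asserted in tests).
Wald two-sided p-values are used (the conventional choice for per-feature
GLM screens). |beta| > 15 on standardized features flags separation; the
Wald value is still reported. Non-converged or constant features are
scored missing and rank-imputed.

Bonferroni uses m = the number of features with a computed p-value (one
cannot correct for tests that were never performed); BH step-up uses the
literal `q_(i) = p_(i) m / i` arithmetic with downward monotonization.
Ranking is ascending lexicographic on (adjusted p, raw p, feature id); the
feature-id tie-break makes reruns bit-identical.

## Penalized models

LASSO (alpha = 1) and elastic net (alpha grid 0.1…1.0 by default; pure
ridge excluded because a ranking that never imputes would change the
selection semantics) minimize

    -(1/n) loglik(b0, b) + lambda * sum_j pf_j (alpha |b_j| + (1-alpha)/2 b_j^2)

Age and sex enter with penalty factor pf = 0 (unpenalized), mirroring the
univariate adjustment; this is switchable off (`covariates=False`). The
solver is a glmnet-style IRLS + coordinate-descent (numba-compiled) with:

* lambda path of 100 log-spaced points from the analytic lambda_max (max
  absolute score of the covariate-only null model, at which all penalized
  coefficients are exactly zero) down to lambda_max × 1e-3;
* warm starts along the path and active-set inner iterations;
* convergence on the glmnet energy scale, max_j wx2_j (Δb_j)^2 < 1e-7;
* IRLS weights floored at 1e-5.

The solver is written in-package because per-coefficient penalty factors
are not available in scikit-learn's logistic solvers; it is cross-checked
against `LogisticRegression(solver="saga")` on problems without
unpenalized covariates (agreement 1e-8…5e-4 depending on penalty).
Cross-validation is stratified by outcome, seeded, folds shared across
alpha values; the loss is binomial deviance by default
(misclassification available). Ties prefer the larger lambda (sparser
model), then the earlier alpha in the grid. Ranking is by descending
|coefficient| with exact zeros unselected (imputed).

## Shrinkage discriminant analysis (CAT scores)

t-scores are studentized two-group mean differences with pooled (n−2 df)
variances shrunk toward their median; the intensity is the analytic
Schäfer–Strimmer estimate clipped to [0, 1]. The correlation matrix of
pooled within-group residuals is shrunk toward the identity,
R* = λI + (1−λ)R, with λ = Σ Var̂(r_ij) / Σ r_ij², and

    cat = R*^(-1/2) t.

Two evaluation routes give the same answer: a dense eigendecomposition
(eigenvalues floored at 1e-12; the reference oracle, O(p³)) and a
low-rank route through the SVD of the standardized residual matrix
(O(n²p); used by `cat_scan`), which agree to better than 1e-8 for p ≤ 50
and to machine precision in practice. One property worth noting: under
*true* zero correlation the analytic λ tends to 1 (full shrinkage), since
Var̂(r)/r² → 1 — the estimator correctly recognizes that all observed
off-diagonals are noise. The two-group CAT is computed group-vs-group;
for two groups this ordering coincides (up to a constant) with the
per-group-vs-pooled-mean form.

After global standardization the pooled variances are nearly equal, so
the variance-shrinkage intensity is typically ~1 on preprocessed data;
it matters when `t_scores` is applied to unscaled matrices.

## Tree ensembles

**Random forest** (scikit-learn backend): tuned over mtry
({√p, p/10, p/3} by default) and nodesize ({5, 15, 50}) by OOB
misclassification; ties prefer smaller mtry then larger nodesize. Two
importance views: average minimal depth (features absent from a tree get
that tree's max depth + 1) and OOB permutation importance (per tree, the
OOB misclassification increase after permuting a feature's OOB values,
averaged over all trees; only features used by a tree are permuted, the
rest contribute exactly 0). The default ranking is descending permutation
importance with minimal depth as tie-break; ranking purely by minimal
depth and a minimal-depth selection gate (threshold = mean minimal depth)
are exposed as options because the choice between the two conventions is
genuinely open. Per-tree OOB membership reconstructs the forest's
bootstrap draws and is validated against the forest's own aggregated OOB
predictions.

**XGBoost**: logistic loss, grid over max_depth {2,4,6} × learning rate
{0.05, 0.1, 0.3} by default, stratified 5-fold CV classification error
with early stopping (20 rounds) choosing both the grid point and the
round count; single-threaded and seeded for bit-identical reruns.
Ranking is by fractional total gain; unused features are imputed. Note
that the reported CV error is a minimum over rounds and grid points and
is therefore slightly optimistic at small n.

## Rank aggregation

Missing ranks are imputed at exactly n_total (the total feature count,
mirroring a screen of N = 54,788 analytes where unselected features
receive rank N). Integrated = row sum, difference = row max − min,
variance = row sample variance (n−1). Bonferroni and FDR count as two
separate columns (k = 7 from six method families), since they are
tabulated separately throughout; this is switchable by passing any subset
of rankings. `focus_top` restricts reporting to the n best features by
integrated rank (default 500), boundary ties broken by feature id.

## Convergence diagnostics

For a method's top-50 (all scored features, with a warning, when fewer
than 50 are scored), the pairwise Pearson matrix of the preprocessed
abundances is summarized by two readings of "% highly correlated":
the share of unordered pairs with |R| ≥ 0.4 and the share of features
participating in at least one such pair. Both are reported; the
convergent/divergent label uses feature participation ≥ 0.5 (boundary
convergent). The 0.4 threshold is the package convention for "highly
correlated" and is configurable (reported ranges in the motivating
literature start at 0.3–0.4 depending on the method).

## Synthetic cohorts

`SyntheticConfig` defaults define the package's standard study
conditions: n = 500 samples; 20 blocks × 25 features (p = 500, a
tractable stand-in for a 54,788-analyte screen); within-block
equicorrelation ρ = 0.7 via a one-factor construction (an AR(1) option
exists); 5 signal blocks whose *first member only* is causal with one
log-odds per SD; age ~ N(52, 18²) truncated to [18, 95]; sex Bernoulli
(78% female); 4 batches with N(0, 0.3²) additive log-scale shifts; log
intensities centred at 10 before exponentiation. Age/sex marginals mirror
a large PAH registry cohort (mean age ≈ 52, ≈78% female) so synthetic
cohort tables are comparable to published ones. The one-causal-member
block design is exactly the structure that separates convergent from
divergent rankers: non-causal block members associate with the outcome
only through their correlation with the causal member.

What the generator does **not** emulate: missing intensities,
heteroscedastic measurement noise, heavy-tailed or skewed batch effects,
annotation/chemical identity, and realistic p/n ratios (p = 500 rather
than ~55k). Passing tests therefore demonstrate correct method behavior
under the assumed correlation/outcome structure, not performance on real
mass-spectrometry data.

## Multi-seed experiment settings

The acceptance experiments (20-replicate recovery, 20-seed convergence
contrast, 8-seed null study) run each method with deliberately modest
settings so multi-replicate loops are tractable on one CPU: 5 CV folds
and alpha grid {0.5, 1.0} with a 60-point lambda path for the penalized
models; mtry = √p = 22, nodesize 15, 150 trees for the forest; a single
(max_depth 3, lr 0.1) XGBoost point with early stopping. Recovery of all
planted signals was also verified under the heavier default grids; the
reduced settings do not change any qualitative conclusion.

## Null behavior of marginal rankings — a caveat

Under a global null (no feature–outcome association) with correlated
blocks, per-feature test statistics inherit the feature correlation
(within-block Wald z's correlate at ≈ ρ). Ranking by p therefore pulls
whole blocks into the top-50 even under the null: measured across null
cohorts, the Bonferroni/FDR top-50 pair-level frac_high is ≈ 0.19 versus
≈ 0.05 for uniformly drawn 50-feature sets. A null top-50 from a marginal
screen is *not* exchangeable with a random draw, and its intercorrelation
should not be read as evidence of a shared pathway on its own. The
decorrelating and sparse methods (SDA, LASSO, XGBoost) stay at the
random-draw baseline; the corresponding test in the acceptance suite
documents this asymmetry (and fails, intentionally and informatively, for
the marginal rankers).

## Cohort tables

Continuous variables: mean (SD) per group, Welch unequal-variance t with
Satterthwaite df between groups (this choice reproduces the printed
p-values of the motivating cohort table). Categorical: count (%) with
Pearson chi-square, no continuity correction. Pooled columns are
reconstructed from subgroup summaries alone — n-weighted means, the exact
combined-variance identity for SDs, combined counts for percentages — so
a printed table's internal arithmetic can be verified without raw data.

## Known limitations

* The elastic-net alpha grid excludes 0 (pure ridge); with ridge no
  feature is ever unselected and rank imputation loses meaning.
* Perfect-separation p-values are Wald values with a flag, not exact
  conditional tests.
* The minimal-depth selection gate uses the simple forest-average
  threshold rather than the full maximal-subtree distribution theory.
* Convergence labels depend on the |R| threshold and the
  pairs-vs-participation reading; both are reported to keep the choice
  visible.
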