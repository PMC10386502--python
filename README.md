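# metaborank

Multi-method metabolite prioritization for binary clinical outcomes, with
rank aggregation and convergence/divergence diagnostics.

## The problem

High-dimensional metabolomics screens (tens of thousands of analyte
intensities per plasma sample) are routinely mined for features associated
with a clinical contrast — here the motivating case is idiopathic versus
non-idiopathic pulmonary arterial hypertension (IPAH vs non-IPAH). The
answer depends heavily on the selection method: marginal screens with
multiple-testing correction tend to return *convergent* top lists —
mutually intercorrelated metabolites, plausibly one pathway or chemical
class — while sparsity- or decorrelation-based learners return *divergent*
lists spanning near-orthogonal features. `metaborank` implements seven
ranking columns from six method families, the rank-aggregation statistics
that quantify their agreement, and the top-k correlation diagnostic that
classifies each method's selections, so a study can run all of them in
parallel and compare.

## Methods implemented

Given a preprocessed abundance matrix X (samples x features, standardized)
and binary outcome y with age/sex covariates:

1. **bonferroni / fdr** — per-feature logistic regression
   `logit P(y=1) = b0 + b1 x_j + b2 age + b3 sex`, two-sided Wald p-values,
   adjusted by Bonferroni (`min(1, m p)`) or Benjamini–Hochberg step-up
   (`q_(i) = p_(i) m / i`, monotonized); ranked ascending with raw-p
   tie-break.
2. **lasso / elastic_net** — penalized logistic regression minimizing
   `-(1/n) loglik + lambda [alpha ||b||_1 + (1-alpha)/2 ||b||_2^2]` with
   age/sex unpenalized, (alpha, lambda) by stratified 10-fold CV; ranked by
   |coefficient|, exact zeros unselected.
3. **random_forest** — OOB-tuned classification forest; ranking by OOB
   permutation importance (accuracy-based) with average minimal depth as
   tie-break.
4. **sda** — shrinkage discriminant analysis: correlation-adjusted t-scores
   `cat = R*^(-1/2) t` with R* the Schäfer–Strimmer-shrunken pooled
   within-group correlation matrix and t variance-shrunken studentized mean
   differences; ranked by |cat|.
5. **xgboost** — CV-tuned logistic-loss gradient boosting; ranked by each
   feature's fraction of the total split gain.

Features a method does not score are imputed at rank N (the total feature
count), and three agreement statistics are computed across the feature x
method rank matrix: **integrated** (row sum), **difference** (max − min),
and **variance** (sample variance) ranks. For each method's top-50, the
pairwise Pearson correlation matrix of the selected features yields the
fraction of highly correlated pairs (|R| ≥ 0.4) and a convergent/divergent
label.

A block-structured synthetic-cohort generator (equicorrelated log-normal
intensity blocks, batch shifts, logistic outcome on one causal feature per
signal block plus age/sex) makes the whole pipeline testable without any
restricted-access data.

## Worked example

```python
import metaborank as mb

cfg = mb.SyntheticConfig(n_samples=500, n_blocks=20, block_size=25,
                         rho=0.7, n_signal_blocks=5, seed=1)
raw, meta = mb.generate_dataset(cfg)
Xs = mb.preprocess(raw, meta)           # log -> batch median/MAD -> scale
meta = meta.aligned_to(Xs)

scan = mb.univariate_scan(Xs, meta)
fdr = mb.rank_fdr(scan)
sda = mb.rank_by_abs_cat(mb.cat_scan(Xs, meta), Xs.feature_ids)

from metaborank.convergence import summarize
for r in (fdr, sda):
    s = summarize(Xs, r, k=50)
    print(r.method, round(s.frac_high_pairs, 3), s.label)
```

prints

```
fdr 0.227 convergent
sda 0.058 convergent
```

meaning 22.7% of the 1,225 pairs among the FDR top-50 are highly
correlated (|R| ≥ 0.4) versus 5.8% for the CAT/SDA top-50: the marginal
screen pulls in whole correlated blocks while the decorrelating score
spreads across blocks. (Both exceed the 50% feature-participation
threshold here because nearly every selected feature has at least one
correlated partner in this dense-block simulation.)

The same flow runs from a shell:

```bash
metaborank run-all --outdir run --seed 1
```

writing per-method ranking TSVs, the aggregate rank table, per-method
convergence summaries, and a cohort-characteristics table.

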