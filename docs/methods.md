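# Methods

`mucomet` implements a case-control analysis of untargeted LC-MS
metabolite feature tables: a fold-change/volcano screen, a Random Forest
validation scaffold with a Y-scrambled null arm, cohort characteristics
testing, and a synthetic-data generator that makes the whole chain
testable end to end. This note records the statistical model behind each
stage, the defaults and why they were chosen, and what the synthetic
data can and cannot establish.

## Synthetic data model

Control-group abundances are per-feature log-normal:
`X_ij = exp(mu_j + sigma_j Z_ij)` with `mu_j ~ Uniform(ln 1e4, ln 1e6)`
drawn once per feature and `sigma_j = sqrt(ln(1 + cv^2))` fixed by the
within-group coefficient of variation `cv`. A planted effect with log2
fold change `f` shifts the case-group location by `f ln 2` at unchanged
scale, so the ratio of case to control *means* is exactly `2^f`; the
arithmetic-mean fold-change statistic is unbiased for the planted value,
and `f = 0` leaves the two groups identically distributed.

Defaults emulate the targeted study design: 44 cases vs 69 controls,
300 features, and four planted effects — three beyond the volcano gate
(log2FC 1.63, 1.08, −1.52) and one "small but significant" feature
(log2FC 0.60) that must pass the t-test gate while failing the
fold-change gate. Demographic covariates (sex, age, body mass, height,
BMI, diabetes, hypertension) are drawn per group from the published
cohort marginals.

The study reports no within-group variance, so `cv` is a free
parameter. The default `cv = 0.6` is a typical mid-range biological CV
for untargeted LC-MS intensities; it makes a log2FC of 1.6 a ~2 SD
shift on the log scale — comfortably detectable at n = 44/69 — while a
log2FC of 0.6 remains a genuine borderline case. Features are
independent by default (the source analysis states no correlation
model); an optional block-equicorrelation knob (`correlation`,
`correlation_block_size`) exists for sensitivity checks and defaults
off. Missingness defaults off; when enabled, dropouts are recorded as
zeros (below-detection semantics) and absorbed by the log
pseudo-count.

What the generator does *not* emulate: feature-feature correlation
structure of real metabolomes, heavy-tailed or batch-structured noise,
retention-time drift, adducts/in-source fragments, or any dependence
between covariates and metabolite levels (the synthetic age imbalance
is decorative, not confounding). Tests passing on this generator
therefore establish the correctness and calibration of the *procedures*,
not the biological performance of the study's classifier on real
biopsies: with independent log-normal features and three planted effects
at these magnitudes, the real-arm AUC is near-perfect, far above the
moderate AUC a real mucosal metabolome supports.

## Preprocessing

Raw tables pass through `normalized -> logged -> scaled` states:

1. **Sample normalization** — each sample divided by its median
   positive intensity, re-multiplied by the grand median of those
   factors so values stay intensity-like. Sum normalization is available
   as a switch. Median normalization is exactly invariant to per-sample
   multiplicative effects up to one global factor.
2. **Log transform** — log10 with pseudo-count `half the smallest
   positive value` when zeros are present (0 otherwise); log2
   switchable. Monotone, so rank statistics are unaffected.
3. **Autoscaling** — per-feature mean 0 / SD 1 (sample SD, n−1);
   Pareto and centre-only variants available. Columns whose SD is at
   float-rounding level of their magnitude (≤ 1e−12 relative) are
   centred only and flagged `zero_variance` — dividing by such an SD
   would only amplify rounding noise. After division the columns are
   re-centred once so the mean-0 contract holds to 1e−9 exactly.

The upstream description of preprocessing names only
"normalization, log transformation, scaling" without parameters; these
defaults are the common defaults of metabolomics preprocessing tools,
and every step is explicit configuration (`PreprocessConfig`) rather
than a buried constant.

## Differential screen

Fold change is the ratio of arithmetic group means on the
**normalized, pre-log** table (the definition "ratio between the mean
abundances" refers to abundances, not log-abundances); the per-feature
p-value is a two-sided **Welch** t-test on the **logged** table
(variance-stabilised scale; Welch because the groups are unequal-sized
and variance homogeneity is not assumed). Both scales are configurable
since the source analysis states neither. Q-values are
Benjamini–Hochberg step-up over all features of the contrast, with no
pre-filtering. Volcano gates: |log2FC| ≥ 1 (fold change ≥ 2 or ≤ 0.5)
and p < 0.05 (−log10 = 1.30); `highlight` requires both. Features with
an undefined fold change (zero denominator-group mean) are excluded
from the volcano with a warning. The diarrhea- vs
constipation-predominant subtype contrast reuses the same machinery
with subtype labels, oriented IBS-D/IBS-C.

## Random Forest validation

Each of `n_iterations` (default 100) iterations draws a stratified
70/30 train/test split (per class, `round(0.7 · n_class)` to training;
44/69 gives 31 + 48 training samples). The four forest hyperparameters
— features per split, tree count, maximum depth, minimum leaf size —
are tuned by grid search maximising mean AUC over 2 stratified inner
folds of the training data ("two folds" is implemented as genuine
2-fold CV, both folds validated in turn). Ties prefer the more
parsimonious model (fewer trees, shallower, larger leaves, fewer
candidate features), then grid order. The winner is refit on the full
training set; the test AUC is the rank-based (Mann–Whitney) statistic
on predicted case probabilities, ties counted 1/2.

**Permutation importance**: each feature's test-set column is permuted
once per iteration (independent draws per feature), the model
re-scored, and 1 − AUC recorded; variability across single permutations
is absorbed by the outer iterations. All permuted copies are scored in
one batched prediction call for speed.

**Y-scrambled arm**: per iteration, the entire procedure (independent
grid search included) is repeated with *training* labels uniformly
permuted; test labels stay real. This is the standard Y-scrambling
contract and gives the scrambled arm its ~0.5 AUC reading.

**Summaries**: medians over iterations with percentile bootstrap 95%
CIs (default 1000 resamples of the median; the interval is widened to
contain the sample median in degenerate cases so `low ≤ median ≤ high`
always holds). The baseline is the unpermuted model's 1 − AUC
summarised the same way. A feature is **significant** when its 1-AUC CI
is disjoint from its arm's baseline CI. The ranking orders features by
real-arm median 1-AUC, descending.

**Default grid**: features-per-split {⌈√m⌉, ⌈m/3⌉}, trees {50, 100},
depth {unlimited, 8}, min-leaf {1, 5}. With ~80 training samples the
forest AUC plateaus well below 100 trees, and the grid is refit ~6,400
times per run (16 points × 2 folds × 2 arms × 100 iterations), so the
tree axis is kept small; every axis is overridable via `RFGrid`. At
these defaults a full 100-iteration validation of a 113 × 300 table
runs in roughly ten minutes on one CPU.

**RNG discipline**: one master `SeedSequence` spawns per-iteration
streams, each split into split/real-arm/scrambled-arm children, plus a
dedicated bootstrap stream — arms are independent yet the whole result
is bit-reproducible from `RFConfig.seed`.

A calibration subtlety, found while testing and worth stating: on a
single *fixed* effect-free dataset, the repeated-split median AUC does
not converge to 0.5 but to that dataset's conditional AUC, which for
small n scatters substantially around 0.5 (observed 0.32–0.63 at
n = 45). Null calibration is therefore a marginal property — across
datasets the medians centre on 0.5 — and the test suite checks it in
aggregate over several generated datasets rather than demanding each
dataset's CI cover 0.5. The scrambled arm, which re-randomises labels
every iteration, is much tighter around 0.5 on any single dataset.

## Cohort characteristics

Categorical variables: per-group counts with percentages and a
two-sided Fisher exact test using the probability-mass criterion (sum
of hypergeometric probabilities of margin-consistent tables no more
probable than the observed one) — the convention that reproduces the
published cohort-table p-values (sex 0.175, diabetes 0.783,
hypertension 0.169) from their cell counts; zero-margin tables return
p = 1. Continuous variables: mean (SD) and the two-sided Wilcoxon
rank-sum test — exact enumeration for combined n ≤ 20 without ties,
otherwise the normal approximation with tie and continuity corrections.
The published continuous p-values (e.g. age) depend on unpublished
per-subject values and are reproduced only structurally on synthetic
data. Display rounding: percent to 0 d.p., p to 3 d.p.

## Problem sizes in the test suite

Unit and property tests run on hand-sized tables. The stochastic
end-to-end checks use: 100 replicate tables at 44/69 × 50 features for
volcano recovery; 20 seeded pipeline runs at 44/69 × 25 features with a
reduced RF configuration (12 iterations, single-point grid) for
importance-ranking recovery; 6 null datasets at 45 × 30 features for
calibration; and one full-scale run (113 × 300, default config, 100
iterations) for the scrambled-arm null band. These sizes were chosen so
the planted signals are unambiguous at the study's sample size while a
complete test run stays desk-scale.

## Known limitations

- The forest learner is scikit-learn's `RandomForestClassifier`; any
  learner implementing `fit(X, y, params, seed)` / `predict_scores(X)`
  can be substituted, but results are only bit-reproducible for a fixed
  implementation.
- One permutation per feature per iteration makes single-iteration
  importances noisy by design; interpret only the across-iteration
  summaries.
- The percentile bootstrap of a median over 100 iterations is coarse
  (medians take ~discrete values); CIs are honest but granular.
- No covariate-adjusted differential models (the screen mirrors the
  unadjusted published analysis despite the cohort's age imbalance),
  no batch/drift correction, no imputation beyond the pseudo-count.
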