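# Methods

`omicboost` integrates heterogeneous omics blocks — RNA-seq counts, FTIR
absorbance spectra, image-derived phenotypes — measured on the same
biological samples, and links them by gradient-boosted cross-prediction
with Shapley-value interpretation.  This note records the models,
defaults, numerical choices and known limitations.

## Data model

All assays are carried as feature × sample matrices (`OmicsBlock`) with
NaN for missing entries; sample metadata is an ID plus nominal factor
columns (condition, time point, replicate).  Alignment restricts every
input to the common sample set, ordered as in the first block — a
deterministic, documented convention.  Accepted missing tokens on input
are the empty string, `NA` and `NaN` (case-insensitive), covering R and
spreadsheet exports.

## Count normalization

Scaling factors follow the median-of-log-ratios scheme:

    s_j = exp( median_{i ∈ G} [ ln x_ij − (1/n) Σ_k ln x_ik ] ),
    x̃_ij = x_ij / s_j

with G the genes with strictly positive counts in every sample — the only
set whose mean log-expression is finite under a natural log with no
pseudocount, which is deliberate: no pseudocounts are added.  Even-sized
medians average the two central values.  All genes are divided by s_j,
including those outside G.

One subtlety worth recording: multiplying one sample's counts by c
rescales its factor by c^((n−1)/n), not by c, because the scaled sample
also shifts every gene's reference mean by ln(c)/n.  Exact per-sample
scale invariance therefore holds only asymptotically in the sample count;
the test suite asserts the exact equivariance law rather than the naive
invariance.

The low-expression filter keeps a transcript when at least one sample
reaches the threshold (≥, so a count exactly at the threshold is kept);
the conventional threshold for TPM matrices is 50.  TPM/CPM inputs may
skip normalization entirely — both paths are supported.

## Spectral preprocessing

FTIR spectra are restricted to a wavenumber window (default
4000–400 cm⁻¹, inclusive bounds, order-insensitive), baseline-corrected,
and smoothed.  The baseline estimator is asymmetric least squares
(Eilers): minimise Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)² with w = p above the baseline
and 1−p below, iterated 10 times; defaults λ = 1e5, p = 0.01 are standard
for ATR-FTIR and parameter-light.  Savitzky–Golay smoothing defaults to
an 11-point window with cubic polynomials — conventional for 4 cm⁻¹
resolution — with edge handling by polynomial fits to the terminal
windows, so polynomial signals pass through unchanged.  On synthetic
spectra (Gaussian peaks on a smooth polynomial baseline) the chain
flattens peak-free spectra below 1% of their range and preserves apex
heights within 5%; broad peaks (width ≳ 50 cm⁻¹) are attenuated most, the
known cost of any asymmetric-least-squares baseline.

## Variance analysis

Per-block PCA treats samples as observations, centering features and by
default scaling each to unit variance (features within one assay often
live on heterogeneous scales); variance fractions come from squared
singular values and sum to one.  The integrated analysis first
standardises each block to a unit sum of squares — centred, divided by
its Frobenius norm — so every block contributes the same total deviation,
then concatenates blocks feature-wise and runs one PCA *without*
per-feature scaling; this is the only reading under which blocks get
comparable total deviations.  Whether the per-block analysis should scale
features to unit variance or unit SS is genuinely open; both are flags,
the default is documented.  Component signs follow the
largest-magnitude-loading-positive convention for reproducible outputs.
Missing entries are rejected rather than silently imputed — PCA has no
native missing-value contract; the error points to filtering or explicit
mean-completion.

Sources of variance are located by one-way ANOVA of component scores
against each metadata factor; factors with a single level or only
singleton groups are rejected (zero degrees of freedom).

## Trait-panel reduction

Correlated phenotype panels are reduced in three steps: (1) agglomerative
clustering of z-scored traits under the distance 1 − |Pearson r| with
average linkage — sign-blind because anti-correlated traits are equally
redundant; (2) the smallest cluster count k for which every cluster's
first principal component explains at least 50% of its member-trait
variance (singletons count as 1); (3) one representative per cluster, the
trait with the largest |PC1 loading|, ties broken lexicographically.
Distance, linkage and the representative rule are configurable choices;
z-scoring first is necessary because phenotype units are heterogeneous.

A structural boundary of the 50% criterion: merging two tight, balanced
groups of m traits with within-group correlation r leaves a cluster whose
PC1 share is (1 + (m−1)r)/2m, which approaches 0.5 from below as r → 1 —
and the merged cluster's two degenerate leading eigenvalues bias the
sample estimate upward.  Recovery of a planted group count is therefore
only reliable when no group dominates a candidate merge (balanced groups
of ≳6 traits) and the sample count is large; the recovery tests use
groups of 6–8 traits at n = 800.  Exact reproduction of any particular
historical trait list is out of scope: the distance, linkage and
representative rules behind such lists are under-determined.

## Cross-prediction

Any block (or prefix-labelled concatenation of blocks) predicts a
continuous trait or binary class with XGBoost.  Missing predictors route
through the learner's native missing-value handling — there is no
imputation step, by design.  Splitting is replicate-aware by default:
whole replicate groups are held out so correlated biological replicates
never straddle the train/test boundary, with three independent splits
(the headline metric is their mean held-out R²); random and
leave-one-group-out modes are available.  Test R² uses the test-set mean
for its total sum of squares and may be negative; negative values are
reported, not clipped.

Tuned knobs are the number of boosting rounds and tree depth (default
grid {50, 100, 200, 500} × {2, 3, 4, 6}, k-fold CV or LOOCV, ties toward
the smaller model).  The remaining hyperparameters are preset and
overridable: learning rate 0.1, gamma 0, subsample 0.8, column subsample
0.8, min child weight 1.  Everything runs single-threaded by default so
metrics are bit-reproducible for a fixed seed; multi-threading is a flag
(floating-point reduction order then varies).

## Shapley attribution, selection, constraints, interactions

Attributions are tree-path-dependent Shapley values computed by the
booster itself; local accuracy (base value + row sum = margin prediction)
is exact up to float32 rounding and asserted at 1e-4.  Global importance
is the mean |attribution| per feature.  A feature's direction is the sign
of the Pearson correlation between its values and its attributions, with
a |r| < 0.1 dead zone mapped to 0 (unknown); the threshold is
configurable.

Boruta-style selection appends a column-permuted shadow copy of every
feature, refits, and credits a real feature with a hit when its
importance exceeds the best shadow's; after 20 iterations a two-sided
binomial test against Binomial(n, ½) at α = 0.05 yields
confirmed/rejected/tentative.  The iteration count, α and max-shadow
criterion are package defaults.

Domain knowledge enters as a two-column table (`feature`,
`final_association` ∈ {−1, 0, +1}).  Tables can be derived from a model's
Shapley directions, randomized (every 0 replaced by a fair ±1 draw, once
per model fit), or merged — user values win conflicts because they encode
domain knowledge; conflicts are logged.  The merged vector is injected as
per-feature monotonic constraints, making the fitted response exactly
non-decreasing/non-increasing along each constrained coordinate (verified
on 50-point grids across 20 anchor samples).  On synthetic data whose
outcome is monotone in a few planted features, correctly-signed
constraints beat randomly-signed ones in mean held-out R² — the
directional analogue of reported gains from informed constraints.

Pairwise interactions come from the booster's Shapley interaction tensor
(samples × features × features, base value + full sum = prediction within
1e-3).  Pairs are ranked by mean |interaction|; known × model-selected
pairs are flagged.  Significance is deliberately a ranking plus an
optional max-statistic permutation null (y-permutation, 100 permutations)
rather than a formal test — interaction scores carry no causal claim.

## Synthetic data

The generator emulates a two-condition, time-resolved, replicated
multi-omics experiment: 48 samples in 8 replicate groups (condition
constant within group), 3 latent factors shared across blocks with
additive Gaussian replicate effects (SD 0.5) and a treatment shift (2.0)
on the first factor; a counts block generated on log scale then
exponentiated (positive, right-skewed, so the normalization path is
exercised on realistic data); block noise SDs 0.3–0.5.  The outcome is a
monotone link — signed sum of standardized planted-feature values plus a
cubic term (weight 0.3) — with noise at 0.3 signal SDs by default.
Planted features carry their own signal, independent of the shared
latents, so the remaining features are genuinely uninformative and
feature-recovery rates are well-defined.  The spectra generator draws
Gaussian peaks with ±10% per-sample height jitter on a polynomial
baseline over the descending 4000–400 cm⁻¹ grid.

What the generator does not emulate: real transcriptome covariance,
count-specific (negative-binomial) noise, real FTIR band positions or
water-vapour artefacts, batch effects beyond replicate shifts.  Passing
tests demonstrate the machinery is correct under the stated model, not
that any real dataset will reach the same recovery rates.

Experiment sizes for the heavier checks were chosen to keep the whole
suite in the minutes range on one core: feature recovery uses n = 60
samples with 500 noise features over 10 seeds with a conservative learner
(depth 2, 500 rounds, learning rate 0.05 — shallow, slow boosting is the
standard choice at this sample size, and outcome noise at 0.1 signal SDs
matches the other recovery-style checks); Boruta power and null each use
20 runs of 20 iterations.

## Known limitations

- Each planted feature in a k-feature outcome carries at most 1/√k of the
  outcome correlation; with 500 noise features at n = 60 this sits near
  the spurious-correlation ceiling, so recovery rates below 100% are
  expected, not a defect.
- The ALS baseline attenuates broad spectral features; band-shape
  quantification should use the stored baselines for inspection.
- No population-structure or kinship adjustment; predictions on
  stratified panels inherit that bias.
- Classification support is a secondary mode (binary logistic objective,
  accuracy/log-loss); no multi-class support.
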