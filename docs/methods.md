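# Methods

## The problem and the model

Untargeted LC-MS metabolomics of urine produces, per sample, intensities for
a very large set of spectral ions (retention time × m/z features). Marker
discovery for a binary contrast (case vs control) must cope with three
properties of such tables: heavy zero-inflation (an ion is simply not
detected in many samples), intensities spanning orders of magnitude, and far
more ions than samples. The package implements a screening-then-classify
workflow built around those properties, together with a synthetic-cohort
generator that reproduces them with known ground truth.

## Screening cascade

The cascade runs on the training split only and applies four filters in
order; each stage refines the previous one, so an ion's `passed_stage` is
monotone and the stage-k survivor set is always a subset of stage k−1.

1. **Detection.** Keep ion *i* iff `#{training samples with x > 0} > N/2`
   strictly, with case and control pooled. "More than half" is read as a
   strict majority of the pooled training set; per-group detection counts
   are still reported per ion, since they are what a reader of the candidate
   table wants to see.
2. **Fold change.** `R_i = mean(case) / mean(control)` over training
   samples, zeros included in the means (a config switch `include_zeros=False`
   averages detected samples only, for sensitivity analysis). Ions with zero
   control mean have an undefined ratio; they are excluded from this stage
   with a logged warning rather than treated as infinitely up-regulated.
   Log base 10 is used throughout; the ±1 SD rule below is scale-equivariant,
   so the base is a display choice. A three-parameter Gaussian
   `A·exp(−(x−μ)²/2σ²)` is least-squares-fitted to the histogram of log
   ratios (default 100 equal-width bins over the data range; the amplitude
   parameter only has meaning against histogram counts). Stage 2 keeps ions
   with `log R > 0` **and** `log R − μ̂ > sd_multiplier · σ̂` (default 1).
   If the curve fit fails to converge or the histogram is degenerate, the
   sample mean/SD of the log ratios are used and the fit is flagged
   `fallback=True`.
3. **Rank-sum.** Two-sided Mann-Whitney/Wilcoxon at `alpha = 0.05`, exact
   null distribution when `n₁+n₂ ≤ 12` with no ties, otherwise the normal
   approximation with tie and continuity corrections (scipy's
   implementation stands behind this primitive; an independent permutation
   oracle checks it in the tests). No multiple-testing correction is
   applied: the cascade deliberately uses the raw per-ion p < 0.05 as its
   third filter, relying on the compounding of all four stages — not on FDR
   control — to keep the false-positive count low. The null-cohort test
   quantifies exactly this compounding.
4. **AUC.** `AUC = (#{case > control pairs} + ½·ties)/(n₁n₂)`, case-high
   orientation, threshold `auc_min = 0.7`. On tie-free data this equals
   `U/(n₁n₂)` for the same U the rank-sum test uses; the tests assert the
   identity numerically.

Candidates (stage-4 survivors) are reported sorted by ascending p value.

## OPLS-DA

NIPALS-style: per orthogonal component, the weight `w ∝ Xᵀy` is computed on
the current (deflated) X, the loading's y-orthogonal part gives the
orthogonal weight, and X is deflated by the orthogonal score/loading pair;
after `n_orth` rounds a single predictive component is fitted to the
residual. Preprocessing is mean-centring + unit-variance scaling by default
(`pareto` and `none` are available); constant columns are dropped with a
warning before scaling. The class vector is encoded ±1 with case = +1, so
positive predictive scores lean case. R²X accumulates the modelled sum of
squares over all components (the tests verify exact sum-of-squares
bookkeeping); R²Y is the fit to y; Q² is computed by stratified 7-fold
cross-validation with a fixed seed, refitting the preprocessing inside each
fold. Only one predictive component is supported — the two-class y has rank
one, so further predictive components are not identified.

With many more ions than samples, R²Y ≈ 1 and a much smaller Q² is the
expected regime; Q² is the number to read.

## LLE

Standard locally linear embedding: k nearest neighbours by Euclidean
distance on per-ion standardized intensities, barycentric reconstruction
weights from the regularized local Gram matrix `C + reg·tr(C)/k · I`
(defaults k = 12, reg = 1e−3; with reg scaled by `k` the weights coincide
exactly with scikit-learn's convention, which the tests exploit as an
oracle), and coordinates from the bottom `d` nonconstant eigenvectors of
`(I−W)ᵀ(I−W)`. The embedding is returned as 2-D coordinates; any cluster
assignment is left to the caller, since the method is an embedding, not a
clustering.

## Decision tree

C4.5 conventions for continuous attributes: candidate thresholds are
midpoints between consecutive distinct sorted values with at least
`min_leaf` samples per side; a split must have information gain at least
the mean gain of all candidates (the gain-ratio guard) and the admissible
split with the highest gain ratio wins, ties toward the smaller threshold
and the lower feature index. Growth stops on purity, `min_leaf`, or no
admissible split; leaves predict the majority class with ties going to case
(favouring sensitivity). Pruning is bottom-up subtree replacement using the
upper confidence bound of the binomial leaf error at confidence 0.25, the
J48 formulation (normal-approximation upper limit on the error rate with
the e < 1 interpolation special-cases). Defaults `min_leaf = 2`,
`prune = True`, `prune_confidence = 0.25` mirror J48's.

Missing-value fractional routing is **not** implemented: screening
guarantees candidates are detected in most samples, and zeros are routed as
literal intensities. This is a documented limitation for data where
candidates are frequently undetected.

## Evaluation protocol

Stratified k-fold CV: per-group shuffle under the seed, then deal
round-robin, so 55 case / 50 control with k = 5 gives five folds of exactly
11 + 10. Marker selection is performed **once on the full training split**
and the candidate set is reused inside CV folds — this mirrors the
discovery protocol being reproduced, and optimistically biases the CV
estimate because the held-out fold influenced feature selection;
`nested=True` re-runs screening inside each fold for the statistically
preferable (honest) estimate, off by default for fidelity.

Per-fold metrics are aggregated as mean and SD. Both SD conventions are
computed because the two appear mixed in practice (a published fold table
this package models reports the accuracy SD under the population formula
and sensitivity/specificity under the sample formula); the default
convention is sample (ddof = 1). Display percentages are rounded half-up to
two decimals; exact fractions are kept internally, and reports always store
the integer confusion counts from which every metric recomputes exactly.
`solve_confusion_counts` inverts printed sensitivity/specificity
percentages back to the unique integer counts when they are unique, and
refuses otherwise.

A single seeded 5-fold partition is used (not re-drawn per repetition).

## Synthetic cohorts

Per ion: `log10 x ~ Normal(μᵢ, σᵢ)` with `μᵢ ~ U(3, 6)` (arbitrary
instrument-count units), `σᵢ ~ U(0.2, 0.5)`, and an independent per-ion
dropout probability `~ U(0, 0.6)` that zeroes observations (0 = not
detected, the same encoding the screening step 1 consumes; there is no
separate missing-value code). Marker ions shift the case-group mean by
`log10(fold)` with `fold ~ U(8, 12)` (≈10-fold, a strong planted effect) and
use a single low dropout probability (0.05) so planted signal remains
detectable. Default composition: 55 case + 50 control training, 32 + 15
test, 5000 ions, 6 markers. Ion labels draw retention times from
[0.5, 30] min and m/z from [50, 1000] purely for label realism.

What this emulates: zero-inflation, order-of-magnitude intensity spread,
p ≫ n, and a sparse strong up-regulated signal. What it does not: osmolality
normalization, chromatographic drift, isotope/adduct structure, batch and
QC-injection effects, correlated ions from shared metabolites, and any
realistic null correlation structure. Passing the recovery tests therefore
shows the cascade's filters and their compounding behave as designed — not
that the pipeline would achieve comparable operating characteristics on
real urine profiles.

Under these conditions the planted markers are always recovered (zero false
negatives across seeds), but the AUC filter's null tail (P(AUC ≥ 0.7) ≈
2·10⁻⁴ per ion at 55/50) admits roughly 0–2 chance survivors per 5000-ion
cohort, so the candidate list can slightly exceed the planted six; the
null-cohort check bounds this at far below `alpha · n_ions`.

## Numerical choices and degenerate inputs

- Intensities are written as positional decimals with ≤ 12 significant
  digits; read/write round trips are stable at that precision.
- The Gaussian histogram fit is initialised at (max count, sample mean,
  sample SD) and reports |σ|; non-convergence falls back to sample moments
  with a warning flag rather than failing the cascade.
- `rank_sum_test` and `auc` raise on an empty group; `detection_filter`
  raises on an empty training split; the generator raises a configuration
  error naming the offending field.
- LLE ties in the neighbour search break by sample index (stable sort);
  duplicate points are handled by the trace-scaled regularisation.
- Tree thresholds are serialised with full float repr so text and JSON
  round trips predict identically.
- All randomness (generator, splits, CV partitions, Q² folds) flows from
  explicit integer seeds; the full pipeline is byte-deterministic given its
  config.

## Problem sizes used by the test and acceptance runs

Unit and property tests use cohorts of 300–800 ions; recovery and
null-behaviour checks use the full default 5000-ion cohort over 5–10 seeds;
the permutation oracle uses 10⁵ permutations on 200 instances with group
sizes 15–40, the regime in which the pipeline actually applies the
asymptotic rank-sum test (at smaller groups the normal approximation itself
departs from the exact permutation distribution by more than the comparison
band, which is a property of the approximation, not of this
implementation). These sizes are the package's own defaults for a thorough
but quick verification run.
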