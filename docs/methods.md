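# Methods

## Model and assumptions

The forecaster treats each biomarker trajectory as piecewise linear over two
consecutive follow-up intervals of equal length Δt (0.5 or 1.0 years). Three
assumptions do the work:

1. **Class-typical progression.** Each class (progressor/stable) has a mean
   annual rate of change per marker — the base gradient δ_m^c — estimated as
   the class average of first-interval gradients on the training set.
2. **Persistent individual deviation.** A subject who deviates from the
   class-typical rate over the first interval deviates predictably over the
   second. The link is linear and multivariate: the second-interval
   deviation of marker m is a weighted sum over ALL markers' first-interval
   offsets, with weights μ[:, m] shared across subjects.
3. **Separable levels + rates.** The two observed visits (levels and annual
   change) carry enough class signal for a linear SVM to suggest the base
   group of an unseen subject.

Under these assumptions the forecast y_m(t+2Δt) = y_m(t+Δt) + (α_m + β_m)Δt
is exact: α supplies the class-typical rate, β the subject-specific
multimarker correction.

### Offset orientation

The first-interval offset is defined as base minus observed gradient,
OS_mi = δ_m^c − δ_mi. The second-interval ("future") offset that the linear
system predicts is oriented the opposite way — observed minus base. This is
deliberate: the forecast *adds* the weighted offset to the base gradient, so
the regression target must be exactly the correction that addition applies.
With this orientation the three stages (weight estimation, offset
computation, forecast) compose into an identity on data that follow the
model: a cohort generated with coupling matrix μ* yields fitted weights
equal to μ* and forecasts that reproduce the observed third visits to
machine precision (both facts are asserted in the test suite). Orienting
the future offset the same way as the first-interval offset would make the
pipeline apply its own learned correction with the wrong sign.

### Why least-squares recovery is exact despite estimated base gradients

Base gradients are estimated as class means, so each training subject's
offsets are the true latent deviations shifted by a per-class constant
(the class-mean sampling error). Because the offset rows are thereby
centred within each class, that constant shift is orthogonal to the
regressors and drops out of the normal equations: on noiseless cohorts the
weight matrix is recovered exactly at any sample size, not just
asymptotically. The tests check this centring identity explicitly.

## Pipeline

1. **Normalization** — every marker divided by its maximum absolute reading
   over all subjects and visits, mapping positive markers into (0, 1] while
   preserving within-subject shape. Default is the whole dataset before the
   train/test split (the classical, leakage-prone variant);
   `normalization="within_train"` derives scales from each training fold
   only.
2. **Ranking** — two-sample pooled-variance Student's t-test on baseline
   readings per marker (Welch behind `ttest="welch"`), ascending p-value,
   stable ties. Nested subsets grow one rank at a time. Ranking runs once
   globally by default; `rank_within_fold=True` re-ranks inside each
   training fold. Zero-pooled-variance markers get p = 1 (equal means) or
   p = 0 (unequal) by convention, logged as degenerate.
3. **Weights** — per outer training fold, an inner leave-one-out loop:
   leave one subject out, re-estimate base gradients on the retained
   subjects (`refit_base_per_fold=False` holds them fixed), build the offset
   system from all retained subjects, solve by minimum-norm least squares,
   and average the solutions element-wise. Folds that lose a class are
   skipped with a warning. The minimum-norm solution (LAPACK gelsd) replaces
   the literal normal-equations inverse so that rank-deficient systems —
   more markers than subjects, collinear markers — degrade gracefully.
4. **Forecasting** — base-group SVM (linear kernel, C = `svm_c`, default
   1.0, no class weighting) on features [level(t), level(t+Δt), annual
   change] per marker; α from the suggested class, β = μᵀ·OS_y, forecast as
   above. `base_classifier="oracle"` substitutes true labels, isolating
   forecast error from base-group misclassification.
5. **Classification & metrics** — linear SVM trained on training-fold
   observed trajectories, applied to forecast-completed test trajectories;
   decision-function scores (signed margin distances, oriented toward the
   progressor class) feed the rank-based AUC. Sensitivity is progressor
   recall, specificity stable recall. MAE is reported ×100 on the
   normalized scale. Ground-truth mode classifies observed third visits,
   so its MAE is zero by construction. Per-fold rows, fold-averaged rows
   (the headline) and a pooled-score AUC are all emitted; the best model is
   the subset size maximizing fold-averaged forecast AUC, ties going to the
   smaller subset.
6. **Cross-validation** — stratified 5-fold outer split, seeded. The split
   is stratified (not plain) because every fold must contain both classes
   for base gradients and both SVMs to exist.

μ is estimated pooled over both classes — the offset system stacks all
training subjects without class partition — and there is deliberately no
ridge/lasso regularization of the weights; the LOO average is the only
stabilizer.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| `dt` | years | 0.5 | 6-month follow-up spacing; 1.0 for annual visits |
| `folds` | — | 5 | outer CV; smallest count keeping ≥ 9 progressors per training fold at reference class sizes |
| `svm_c` | — | 1.0 | maximum-margin trade-off for both SVMs; features are already on the normalized scale |
| `max_subset` | markers | all | largest incremental subset evaluated |
| `subject_slope_sd` (generator) | rate/yr | 2 % of marker scale | between-subject heterogeneity of progression rates |
| `noise_sd` (generator) | reading units | 1.5 % of marker scale | test-retest measurement error |
| coupling matrix (generator) | — | 0.25 diag + 0.05 ring | moderate self- and neighbour-coupling of rate deviations |

## The synthetic cohort generator

`generate_cohort` draws, per subject: a uniform baseline per marker, a
subject-specific first-interval rate around the class slope, a noisy second
visit, and a second-interval rate equal to the class slope plus the
coupling-matrix image of the first-interval deviations (computed from the
noisy readings, exactly as the estimator will later see them), then a noisy
third visit. One seed sequence is spawned per subject in subject-id order,
so output is bit-identical across runs and vectorization changes.
`mci_cohort_spec` packages defaults resembling a 6-month MCI panel: 49
progressors / 70 stables, eight markers on scales log-spaced over two
decades, stables declining ~1.5 %/year and progressors ~5 %/year.

The generator emulates: two classes with class-specific linear slopes,
cross-marker coupling of rate deviations, additive observation noise,
heterogeneous positive scales, and exactly three complete equally spaced
visits. It does **not** emulate: baseline level differences between classes
(so the baseline t-test ranking is uninformative on these cohorts — it
exercises the machinery, not marker biology), missing visits, nonlinear or
floor/ceiling marker dynamics, covariates (age, sex, education), or
measurement error that correlates across markers. Passing tests therefore
demonstrate the estimator's correctness under its own assumptions, not
clinical performance on real cohorts.

## Numerical choices

* Normalization divides by the maximum **absolute** value, which coincides
  with divide-by-max for positive markers and keeps the operation idempotent
  and scale-equivariant if a synthetic marker goes negative.
* Degenerate inputs: all-zero markers raise a named error; single-class
  folds are errors at the outer level but skipped (with warnings) in the
  inner LOO loop, where they are a small-sample artefact.
* The t-test p-value conventions at zero pooled variance (above) avoid NaNs
  propagating into the ranking.
* Rank-deficient offset systems return the minimum-norm solution with a
  logged warning rather than failing — with hundreds of markers and tens of
  subjects, AᵀA is routinely singular.
* Floats round-trip at full precision through all artifacts (`%.17g` CSV,
  JSON repr), making reruns with the same seed byte-identical.
* AUC is undefined for one-class truth and reported as NaN, never imputed.

## Problem sizes

The test suite and `scripts/acceptance.py` use cohorts of 20–200 subjects
with 2–10 markers: large enough that weight recovery, separation and
forecast/benchmark orderings are stable to Monte-Carlo wobble at the stated
tolerances, small enough that the full suite runs in seconds. The
acceptance script's pipeline run uses the reference class sizes (49/70) with
the default eight-marker panel.

## Known limitations

* Two observed visits are a hard minimum and a hard maximum of history: no
  multi-step recursion, no uncertainty intervals on forecasts.
* Default whole-dataset normalization and global ranking leak information
  across the CV split; the leak-free variants are one flag away but change
  the headline numbers slightly.
* With C = 1 and strongly overlapping classes, the trajectory SVM's
  *threshold* can sit at the majority class (sensitivity near zero) even
  when its *ranking* is good (high AUC); raise `svm_c` if calibrated labels
  matter more than ranking.
* Class-imbalanced folds are handled by stratification, not by class
  weighting in the SVMs.
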