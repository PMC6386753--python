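# Methods

This note records the model implemented by `parcelstack`, the package's own
design and numerical choices, and the semantics of the synthetic cohort
generator. Defaults given here are the library defaults; every one of them is
overridable through the public APIs or the YAML run configuration.

## Problem and model

`parcelstack` classifies subjects into two groups (by convention `patient` vs
`control`) from resting-state fMRI, using a stacked ensemble over many
*feature sources*. A source is one (feature type, parcellation) pair:

* **Feature types** — three regional (ALFF, fALFF, ReHo) and three
  connectivity (full correlation, partial correlation, sparse precision).
* **Parcellations** — any mix of the three supported atlas dialects:
  integer label volumes, 4D probabilistic map stacks, and seed-coordinate
  tables expanded to spheres. The canonical registry of 14 published
  parcellations (17–444 ROIs) yields 6 × 14 = 84 sources.

One L2-regularized logistic regression is trained per source on
PCA-projected features (a *single-source model*, SSM); a second-level
logistic regression over the SSMs' predicted probabilities (*stacking*)
produces the final prediction.

## Preprocessing and feature extraction

All series first drop `n_discard` initial volumes and are linearly detrended.
Further preprocessing is routed per feature type:

| feature type | smoothing (4 mm FWHM) | band-pass 0.01–0.08 Hz |
|---|---|---|
| ALFF, fALFF | yes | no (band selection happens in the spectrum) |
| ReHo | no (smoothing destroys rank homogeneity) | yes |
| connectivity (all three) | yes | yes |

* **Band-pass** is an ideal frequency-domain filter: real FFT, zero all bins
  with frequency outside the closed band, inverse FFT. Bin inclusion is
  inclusive at both edges.
* **ALFF** is the sum of the single-sided amplitude spectrum
  (`2|X_k|/n`, endpoints unscaled) over bins inside 0.01–0.08 Hz, computed
  on the detrended *unfiltered* series. **fALFF** divides the same in-band
  sum by the sum over the full detectable spectrum excluding DC, so it lies
  in [0, 1].
* **ReHo** is Kendall's coefficient of concordance W over each voxel's
  27-voxel neighbourhood (face/edge/corner; 7- and 19-voxel variants are
  available), with the standard tie correction, computed on the band-passed
  *unsmoothed* series. Border voxels use their in-volume neighbours.
* Regional maps are z-scored across in-mask voxels (population SD) before
  ROI aggregation: label and sphere ROIs take the member-voxel mean, map
  ROIs a weighted mean.
* **ROI time series** for connectivity: member mean for labels/spheres,
  least-squares projection onto the map stack for maps; each ROI row is then
  z-scored. Estimators: Pearson correlation; partial correlation
  `−Θ_ij/√(Θ_ii Θ_jj)` from the pseudo-inverse of the Ledoit–Wolf covariance;
  sparse precision via the graphical lasso, with alpha either fixed or chosen
  by `GraphicalLassoCV` over a 10-point log grid in [1e-3, 1] (3-fold
  splits over timepoints).
* Connectivity matrices are vectorized as the strictly lower triangle in
  row-major order (length n(n−1)/2), with edge names `"rowROI|colROI"`.

## Confounds

Age, sex, total intracranial volume and mean framewise displacement are
removed by per-column OLS regression (design: intercept + the four
covariates). In cross-validated evaluation the regression is fitted on the
training fold only and applied to both folds (`confound_scope="train"`, the
leakage-safe default). Mean FD is the mean over frames of the summed absolute
backward differences of the six motion parameters, rotations converted to arc
length on a 50 mm sphere. Subjects exceeding 2.0 mm translation or 2.0°
rotation can be flagged for exclusion.

## Ensemble

**Single-source model.** Full-component PCA (`m = min(p, n_train)`
components, so the projection is a rotation and the model is invariant to it)
followed by L2 logistic regression. The inverse regularization strength C is
chosen from {0.001, 0.01, 0.1, 1, 10, 100, 1000} by internal repeated
stratified CV (default 10-fold × 5 shuffles) maximizing accuracy; ties break
toward the smallest C. The solver is lbfgs with `tol=1e-10` — the tight
tolerance is what makes the PCA-rotation-invariance contract hold to 1e-6 in
probability (liblinear's looser default does not).

**Stacking.** The second-level logistic regression is trained on the base
models' *in-sample* training probabilities (the design the original study
describes); a cross-fitted variant (`stack_cv=True`) is available. Per-type
substacks (e.g. all ALFF sources) reuse the fitted base models.

*Design deviation:* the level-1 probability columns are z-scored before the
stacking LR. Without this, the accuracy-scored internal CV with the
smallest-C tie-break legitimately picks a tiny C for weak or low-dimensional
sources, collapsing their probabilities into 0.5 ± 0.02 — a scale an L2
stacker cannot use even when the ranking information is present.
Standardizing the meta-features restores scale-invariant stacking while
keeping the architecture (LR over SSM probabilities) unchanged.

**Feature-selection modes.** Besides PCA, sources can use in-fold top-r%
univariate selection (ANOVA F, r ∈ {0.5, 1, 2, 5, 10, 20, 30}) or the mixed
mode "all regional + top-30% connectivity". Selection is always fitted inside
the training fold.

**Weight reliability.** Across outer folds, each feature's reliability is
mean(weight) / SE(weight); features at the 98th/99th percentile of |score|
can be reported. Zero-across-folds weights give NaN and are flagged;
constant nonzero weights give signed infinity.

## Evaluation

* Repeated stratified k-fold CV, default 5 × 10-fold = 50 train-test splits;
  `k = n` degenerates to leave-one-out.
* Per-fold confusion counts give accuracy, precision, sensitivity,
  specificity; an undefined ratio (zero denominator) is NaN, not 0.
* Summaries report mean and SE = SD(ddof=1)/√n_folds over fold values.
* Model comparison: paired two-sided t-test over per-fold accuracies of two
  reports sharing fold assignments.
* Permutation baseline: the *entire* learning procedure (including C
  selection and stacking) is re-run on each of n label shufflings.
* Severity sub-analysis: patients at or below the first quartile vs at or
  above the third quartile of a symptom score (linear-interpolation
  quantiles, inclusive comparisons), classified against controls with
  leave-one-out CV.

## Synthetic cohort generator

The generator (`parcelstack.synthetic`) emulates a single-site case-control
resting-state study at a scale where the full pipeline runs in minutes.

Per subject, each of 8 block ROIs (2×2×2 partition of a 16³ grid of 3 mm
voxels) carries a latent signal: a normalized sum of 3 sinusoids at random
in-band frequencies (frequencies drawn stratified across the band, so
distinct ROIs cannot alias onto persistent beat patterns at short t) mixed
across ROIs by the Cholesky factor of a group correlation matrix, plus AR(1)
noise mixed by the same factor. The latent signal is broadcast to member
voxels with i.i.d. white voxel noise (SD 1.0). Three atlases are emitted:
the true 8-block labels, 4 smoothed network maps grouping the blocks, and
8 seed spheres at block centres — one per dialect.

Planted group effects:

* `amplitude_shift` (default 1.5 in the planted preset) is expressed in
  units of the *between-subject SD of the measured ROI band-amplitude
  feature*. The required latent amplitude delta is found by a
  simulation-based calibration (secant iteration over a pipeline-faithful
  forward model including smoothing retention and map z-scoring), so "1.5
  SD" refers to the feature the classifier actually sees, not a latent knob.
  Applied to 10% of ROIs (ceiling).
* `coupling_shift` (default 0.25 in the planted preset) is an
  *observed-correlation* delta added to patients' inter-ROI correlation on
  10% of edges (ceiling). Positive-definiteness of the shifted matrix is
  verified before simulation. The default places the connectivity effect
  family at comparable single-source strength to the amplitude family, so
  that combining families — the property the stacked ensemble is for — is
  what drives performance.
* `effect_mode="subtypes"` makes each patient express only one effect family
  at full strength (clinical-heterogeneity emulation).
* `confound_group_strength` correlates age/sex/TIV/FD with group;
  `severity_effect` ties SANS/SAPS scores to effect expression.

What the generator does **not** emulate: hemodynamic response shape,
spatially autocorrelated physiological noise, motion artifacts, scanner
drift beyond a linear trend, site effects, or unbalanced missingness. It is
a test harness for the pipeline's statistical machinery, not a biophysical
simulator.

Presets: `ci_cohort_spec` (80+80 subjects, t=64), `null_cohort_spec` (no
planted effect), `planted_cohort_spec` (both effects at the defaults above);
the study-scale default `CohortSpec()` is 81+93 subjects at t=143, TR 2 s.

## Desk-scale problem sizes

The heavy label-recovery checks (acceptance criterion runs, and
`scripts/acceptance.py`) use deliberately scaled sizes, chosen as this
package's own trade-off between runtime and statistical resolution:

* outer CV 1 × 10-fold (the full 5 × 10 is exercised on study-scale label
  vectors in unit tests);
* internal C-selection CV 5-fold × 1 shuffle (full 10 × 5 in unit tests);
* graphical lasso at fixed alpha 0.05 instead of `GraphicalLassoCV`;
* permutation baseline: 20 shufflings at 1 × 5-fold outer CV with 3 × 1
  internal CV.

## Numerical choices

* All randomness flows from `numpy.random.default_rng` seeds;
  `SeedSequence.spawn` separates per-subject streams. Identical seeds give
  byte-identical cohorts and evaluations.
* Graphical lasso at fixed alpha runs on the Ledoit–Wolf shrunk covariance:
  the raw sample covariance of near-collinear ROI series makes the solver
  fail with non-SPD errors.
* Constant series/maps are handled explicitly (zeroed with a warning) rather
  than propagating NaN.
* Quantiles use numpy's default linear interpolation; map z-scoring uses the
  population SD.

## Limitations

* The stacking is in-sample by default, as in the original design; the
  optimistic bias this can carry is bounded here by the outer CV, and a
  cross-fitted option exists.
* The severity sub-analysis and confound model assume the metadata columns
  (`age`, `sex`, `tiv`, `mean_fd`, `sans`/`saps`) exist and are numeric.
* Binary classification only; exactly two classes are enforced throughout.
* The synthetic generator's effects are block-structured and stationary;
  results on it demonstrate machinery, not clinical performance.
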