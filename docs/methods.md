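# Methods

This package implements a baseline ¹⁸F-FDG PET/CT radiomics workflow for
predicting early progression (EP) in locally advanced pancreatic cancer
(LAPC): texture feature extraction from paired CT/PET tumor volumes,
semiquantitative PET metrics, table harmonization, minimum-redundancy
maximum-relevance (MRMR) feature selection, a two-level cost-sensitive
decision-tree cascade, and nested stratified cross-validation. Because no
patient imaging is distributed with it, the package includes a synthetic
cohort generator whose statistical structure is calibrated to the target
population; every empirical claim in the test suite is made on those
synthetic cohorts, at the problem sizes stated below.

## Image preprocessing and PET metrics

Volumes are NIfTI-1 triplets (CT, PET, binary tumor mask) per patient, CT
on a 12-bit intensity scale [0, 4095] and PET in SUV. The only geometric
preprocessing is an in-plane resize of rows/columns to the dataset median
grid (slice count never changes); for an even number of patients the
median resolves to the lower-middle value so the target is always an
observed size. Intensities are interpolated bilinearly, masks by nearest
neighbor and re-binarized; CT, PET and mask of a patient are resampled
identically so alignment is preserved. No inter-modality registration is
performed: CT and PET are assumed co-registered as acquired on a hybrid
scanner.

PET metrics inside the mask:

* **SUVmax** — maximum SUV over masked voxels.
* **MTV** (cm³) — volume of masked voxels with SUV ≥ 40% of SUVmax. The
  comparison is inclusive, making the single-voxel case well defined
  (MTV = one voxel volume). The threshold fraction is a parameter
  (default 0.40).
* **TLG** — SUVmean over the MTV voxel set × MTV. Computing SUVmean over
  the thresholded region (not the whole mask) is the standard pairing
  with a threshold-based MTV; it guarantees
  0.4·SUVmax·MTV ≤ TLG ≤ SUVmax·MTV.

## Texture features (242 per modality)

Three families per modality, 242 features each for CT and PET:

* **First-order (12)** — mean, median, population variance, skewness,
  excess kurtosis, minimum, maximum, range, energy (Σx²), Shannon entropy
  (base 2, 64-bin min–max histogram), 10th and 90th percentiles. For a
  constant region, skewness, kurtosis and entropy take their analytic
  limit 0.
* **GLCM (13 × 14 = 182)** — the 26 unit offsets of the 3×3×3
  neighborhood pool into 13 symmetric offset pairs (d and −d produce the
  same symmetric matrix). Co-occurrence is accumulated globally over the
  ROI: for each offset, every voxel pair with both ends inside the mask
  contributes a count; the matrix is symmetrized and normalized, and 14
  Haralick statistics are computed (ASM, contrast, correlation, variance,
  inverse difference moment, sum average, sum variance, sum entropy,
  entropy, difference variance, difference entropy, the two information
  measures of correlation, and the maximal correlation coefficient).
  Gray levels come from equal-width quantization of the ROI range into
  Ng = 32 levels (configurable); 32 keeps the matrices well populated for
  ROIs of a few hundred to a few thousand voxels. An offset with no valid
  pair yields missing values; statistics undefined at zero marginal
  variance (correlation, IMC1, MCC) are also emitted as missing and
  handled by imputation.
* **LBP-TOP (3 × 16 = 48)** — local binary patterns on the three
  orthogonal plane families of the volume stack (xy, xz, yz), treating
  the z axis as a third spatial axis. Per masked voxel and plane, a 4-bit
  code compares the four axis-aligned in-plane neighbors at distance 1 to
  the center (neighbor ≥ center sets the bit; bit order +row, +col,
  −row, −col). P = 4 axis-aligned neighbors avoid interpolation and give
  2⁴ = 16 codes per plane. Voxels whose neighbors leave the grid are
  skipped; each plane's 16-bin histogram is normalized to sum 1.

Feature names are a stable registry (`feature_names()`); ordering is
bit-exact across runs.

## Harmonization

Non-finite entries (NaN and ±inf) become missing; continuous columns are
filled with the feature-wise mean of observed values, discrete columns
(sex, tumor location, resectability) with the feature-wise median
(even count → lower-middle value). A fully missing column is filled with
0 and reported in a warning. Inside cross-validation the fill statistics
are fit on training rows only and applied to held-out rows — imputing
over the whole table before splitting would leak test-row information
into training; a `global_impute` switch reproduces the literal
whole-table behavior for comparison. Mean-filling preserves the column
mean and is idempotent. No feature scaling is applied: the downstream
learners are trees.

## Feature selection

MRMR greedy forward selection under the difference (MID) criterion:
at each step the feature maximizing I(f; y) − mean_{s∈S} I(f; s) joins
the selected set S. Mutual information is the plug-in estimate (base 2)
after 4-bin equal-frequency discretization of continuous features
(discrete features enter as-is); quartile binning is robust at cohort
sizes of tens of patients and makes the ranking invariant to strictly
monotone transforms. The greedy objective is rounded to 10 decimals
before the argmax so that mathematically tied features (e.g. permuted
contingency tables) resolve by column order rather than float-summation
noise. MID rather than the quotient form was chosen because it is the
original formulation and stays stable as redundancy approaches zero.

The retained count k is the elbow of the ranked score curve: both axes
are min–max normalized and k is the rank farthest (perpendicular
distance) from the chord joining the first and last points — the
standard deterministic surrogate for a visual scree inflection. A
numerically collinear curve falls back to k = min(10, m), bounding model
size at the cohort scale; a single score gives k = 1. The rule is
invariant to affine rescaling of the scores.

## Two-level decision-tree cascade

Two CART trees are grown on the same rows with different false-negative
costs, realized as a class weight c on the positive class inside the
impurity and leaf-frequency computations — the standard realization of
asymmetric misclassification cost in impurity-based trees. Depth is
capped (grid {2, 3, 4}; ~50 training rows per fold cannot support deep
trees) and costs are searched over c_low = 1, c_high ∈ {2, 3, 5} in the
inner CV.

Prediction routes each sample through the lenient (low-cost) tree first:
if its predicted-class leaf probability strictly exceeds the reliability
threshold τ (default 0.5), that prediction is accepted; otherwise the
conservative (high-cost) tree decides by comparing its positive-class
probability to an operating threshold θ. Since a binary tree's
predicted-class leaf probability is at least 0.5 by construction, at the
default τ only samples in exactly balanced leaves defer to stage 2; τ is
configurable for stricter reliability bars. θ is tuned on validation
data by maximizing Youden's J over midpoints of consecutive distinct
stage-2 scores (ties → smaller θ, favoring sensitivity, consistent with
the high-FN-cost intent). Limits: τ = 0 reduces the cascade to the
lenient tree, τ = 1 to the conservative tree at θ.

Models serialize to JSON (split feature, threshold, children, leaf
probabilities) with bit-exact prediction round-trip; prediction always
traverses the serialized node arrays.

## Nested cross-validation

Outer stratified 10-fold CV provides the test folds; an inner stratified
5-fold CV over each outer-training set performs imputation, MRMR +
scree, grid search and θ tuning without access to the outer test rows.
Stratification deals class-shuffled samples round-robin, so fold sizes
and per-fold class counts each differ by at most one (57 patients with
20 positives give ten folds of size 5–6 with exactly 2 positives each).
Degenerate inner splits are re-drawn with an incremented substream
(logged, at most 5 attempts).

Per outer fold, the grid point with the best mean inner validation
accuracy wins; the cascade is then retrained on the full outer-training
set with k fixed to the lower median of the inner scree k's, features
re-ranked on the outer-training rows, and θ frozen to the mean of the
inner tuned θ's — after retraining on train+validation no untouched
validation set remains, so θ cannot be re-tuned without leakage.
Predictions over all outer folds are pooled into one confusion matrix,
accuracy and rank-based (Mann–Whitney, ties = 1/2) AUC; per-fold
accuracies and a normal-approximation 95% CI half-width are also
reported, as is the per-fold feature-selection frequency table.

A leakage audit plants a sentinel feature informative only on one outer
fold's test rows and asserts it is never selected and never splits a
tree in that fold.

## Synthetic cohorts

The generator emulates the structure of a 57-patient LAPC PET/CT cohort
so the pipeline is testable end to end:

* **Labels** — exactly round(n × prevalence) positives (default
  prevalence 0.35); a deterministic count keeps small test cohorts
  non-degenerate.
* **Geometry** — default grid 32×32×24 voxels at 3 mm isotropic spacing;
  ellipsoidal tumors with semi-axes uniform on [4, 10] voxels (capped so
  the tumor plus a one-voxel margin fits interiorly, avoiding
  edge-effect ambiguity in the texture operators).
* **PET** — smooth background around SUV 1 plus a tumor with a Gaussian
  radial uptake profile, multiplied by (1 + relative-std × field) where
  the field is unit-variance Gaussian-filtered white noise. The tumor is
  scaled so its maximum equals a per-patient peak SUV drawn log-normal
  with cohort mean ≈ 6.7, clipped to [1.1, 21.1]. With this profile and
  geometry the cohort-mean 40%-threshold MTV lands near the 20.6 cc
  calibration target.
* **Class signal** — placed in *heterogeneity*, not uptake level: EP
  tumors have texture correlation length 1 + 0.6·texture_effect voxels
  and relative std 0.15·(1 + 0.5·texture_effect). CT (12-bit scale,
  soft-tissue background near 1050) carries an analogous, independently
  drawn texture. The clinical signal is a shift of clinical_effect in
  log CA 19-9 (log-normal, cohort median ≈ 1044 U/mL, clipped to
  [1, 3848], σ_log = 0.9). At effect 0 the label enters no computation,
  so the null model holds by construction.
* **Covariates** — age uniform on [40, 79], ~54% female, ~93% head
  location, ~28% borderline-resectable, matching the target cohort's
  marginals.
* **Presets** — the documented *strong* preset (texture_effect = 2.0,
  clinical_effect = 1.5) represents clearly separable classes and is the
  reference condition for signal-recovery checks; the *null* preset sets
  both effects to 0.
* **Reproducibility** — one global seed expands to per-patient
  substreams via `SeedSequence(seed, spawn_key=(i+1,))` (substream 0 is
  cohort-level label assignment), so cohorts are identical across runs
  and patients are stable under partial regeneration.

What the generator does **not** emulate: scanner physics, attenuation
correction and reconstruction artifacts, respiratory motion, irregular
or infiltrative tumor shapes, inter-observer segmentation variability,
and any uptake-level class difference. Passing tests therefore
demonstrate correctness and calibration of the *machinery* — not
clinical performance on real LAPC data, whose headline numbers depend on
undeposited patient imaging.

## Problem sizes and observed behavior

Statistical checks run at desk scale: calibration and signal-recovery
experiments use cohorts of n = 120 (42 positives) over 10 seeds, the
marginal-calibration cohort n = 200, the distribution-calibration check
50 cohorts of n = 30, and the effect-monotonicity check n = 60 over 3
seeds per effect level. At these sizes the full suite runs in a few
minutes on one CPU. On strong-preset cohorts the nested CV recovers the
class signal well above chance, and on null cohorts the seed-averaged
pooled AUC is consistent with no signal; the nested-CV AUC under the
null is more variable than the raw Mann–Whitney permutation null (the
trees are trained on what are effectively permuted labels, which adds
model-selection variance and a mild pessimistic drift), which is why
calibration is asserted on the seed average rather than per seed.

## Numerical conventions

* Even-count medians (grid sizes, discrete imputation, inner-k
  consensus) resolve to the lower-middle value: deterministic and always
  an observed value.
* Quantization maps the ROI minimum to level 0 and maximum to Ng − 1;
  constant regions map to level 0.
* 0·log 0 = 0 throughout entropy computations.
* The MCC is computed on the support of the marginal (levels with
  nonzero probability); fewer than two support levels yield a missing
  value.
* Tree traversal sends `x[feature] <= threshold` left, matching the
  serialized representation exactly.
* All stochastic components accept explicit seeds; reported quantities
  are deterministic given (data, seed).

## Known limitations

* Haralick sum-variance uses the sum-average centering (the common
  correction of the classic formulation).
* The scree elbow on curves with one dominant drop selects the first
  rank *after* the drop (the farthest-from-chord point), which can admit
  one weak feature beyond the visually obvious cut.
* With τ = 0.5 and shallow trees, stage 2 engages only for samples in
  exactly balanced stage-1 leaves; on well-separated data the cascade
  often behaves as the lenient tree alone.
* CI half-widths use the normal approximation over 10 fold accuracies,
  which is crude at fold sizes of 5–6.
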