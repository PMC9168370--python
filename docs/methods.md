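# Methods

`radstab` re-creates, on synthetic data, a complete radiomics
model-development workflow for predicting short-term treatment response of
liver tumors from arterial-phase CT: image standardization, handcrafted
feature extraction, perturbation-based robustness screening, a multi-stage
feature-selection cascade, a high-throughput selector x classifier
benchmark, and survival follow-through. This note records the models,
parameter choices, numerical conventions and known limitations.

## Synthetic phantom cohort

Real patient imaging for this problem class is rarely shareable, so the
package generates a phantom cohort with the statistical structure the
downstream analysis assumes.

Each subject is a 3-D Hounsfield-unit raster containing one tumor:

* **Shape** — an ellipsoid (largest semi-axis = diameter/2, the two other
  axis ratios drawn from U(0.80, 1.0)) whose radius is modulated by a
  random low-order spherical-harmonic field (degrees 1–3, amplitude 10% of
  the radius), so shape features vary across subjects.
* **Texture** — a Gaussian random field realised by Gaussian-smoothing
  white noise; the smoothing scale is the field's correlation length.
  The tumor interior and the liver-like background carry separate fields.
* **Noise** — additive white Gaussian noise emulating CT quantum noise
  (default SD 10 HU). All values are clipped to [-1024, 1400] HU.

Cohort-level defaults emulate the target population: 103 subjects with a
72/31 disease-control/progression split (the split count is exact by
construction), maximum tumor diameters log-normal with median 59.68 mm
truncated to [10.40, 153.33] mm, background 60 HU, tumor enhancement
+45 HU for responders.

The two outcome classes differ in two image properties, both scaled by a
single `effect` parameter: the tumor mean HU shift (class 0 enhances
12 HU x effect less) and the texture correlation length (class 0 is
coarser by 1.0 voxel x effect). With `effect = 0` the label is independent
of image content. The paper-scale intensity/texture statistics of real
tumors are unknown, so these separations are free parameters; the defaults
were chosen once so that a realistic workload exists (near-chance AUC at
effect 0, strong but imperfect separability around effect 1) and are part
of the package's study conditions, not estimates of any real cohort.

Survival times are exponential with the hazard multiplied by a
configurable ratio (default 2.49) for progressors, median control survival
18 months, under administrative censoring whose window is solved by
bisection to hit a requested censor rate (default 0.30). Every random
stage derives a named sub-seed from the global seed via SHA-256, so
regeneration is bit-identical and adding a stage never shifts another
stage's stream.

## Preprocessing chain

Fixed order: resegmentation (mask voxels outside (-1000, 400) HU are
dropped) -> adaptive windowing (center = in-mask mean; width =
max(2 x (p99 - p1), 1); volume clipped) -> Gaussian denoising (sigma 0.5
voxels, reflect boundary) -> linear 0–255 rescale + 256-bin histogram
equalization -> selection of the 3 consecutive axial slices with maximal
total tumor area (ties toward the smaller index; masks thinner than 3
slices are padded by duplicating boundary slices) -> a square crop centred
on the union-mask bounding box, zero-padded at borders.

Design choices that were genuinely open: intensity operations run on the
whole volume *before* slice selection so the three slices share one
transform; the window statistics come from in-mask mean/percentiles; the
crop size is interpreted in pixels at 1 px = 1 mm base spacing;
equalization uses 256 bins on the already-rescaled volume.

## Perturbations

Three deterministic perturbation kinds feed the robustness analysis:

* **S (slice thickness)** — z-axis slab averaging to 1, 2, 3 and 5 mm
  (mean for intensities, >= 50% vote for the mask), applied to the raw
  volume before preprocessing. Slab averaging is simple and monotone; no
  sinc reconstruction is attempted.
* **R (rotation)** — in-plane rotation of the processed tiles by -30, -15,
  +15, +30 degrees (bilinear image / nearest-neighbour mask, canvas
  preserved), applied after slice selection since it is a 2-D operation.
* **Seg (segmentation)** — iterative unit-ball dilation/erosion of the raw
  mask, stopping at the iterate whose volume ratio is closest to 1.2 / 0.8;
  the achieved ratio is recorded. Erosion that would empty the mask
  returns the last nonempty iterate with a warning.

## Feature catalogue (851)

107 features on the original image — 18 first-order, 14 shape, 24 GLCM,
16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM — plus the 93 non-shape features
recomputed on each of 8 wavelet sub-bands (744). Shape is computed once.

Conventions:

* Gray levels are discretized to 32 equal-width bins over the pooled
  in-mask range of the stack (per filtered image). Binning over the
  in-mask range makes all texture features invariant to global intensity
  shifts.
* Texture matrices are built in 2-D per slice (a 3-slice stack is too thin
  for 13-direction 3-D statistics): GLCM/GLRLM over the 4 in-plane
  directions at distance 1 (GLCM symmetric), features averaged direction
  first, then slice; GLSZM/GLDM/NGTDM use 8-connectivity per slice.
* Shape is 3-D on the thin stack with true anisotropic spacing: mesh
  volume/surface from marching cubes, diameters from the convex hull,
  axis lengths 4*sqrt(eigenvalue) from a PCA of physical coordinates.
* Degenerate ROIs: a single gray level gives entropy-type features 0 and
  correlation-type features 1; a single voxel gives axes 0 and sphericity
  1 (logged).
* The wavelet filtration is undecimated (stationary), implemented as
  separable low/high-pass convolutions along each axis, so all 8 sub-bands
  (LLL…HHH, letters in z-y-x order) stay aligned with the original mask.
  Default basis Coiflet-1; stacks thinner than the filter fall back to
  Haar — with 3-slice stacks this is the usual path.
* Each matrix family was validated against brute-force enumeration oracles
  (exhaustive pair/run/zone/dependence counting in plain loops) on toy
  images; these oracles live in the test suite.

External ("deep") features enter through a bank contract: any numeric
matrix keyed by subject. The built-in provider is a deterministic
random-convolution bank (seeded filters, valid convolution, ReLU, global
max pooling, mean over slices) at CNN-embedding dimensionalities
(512/1536/2048); it reproduces the *shape* of a transfer-learning feature
source, not any pretrained network's activations. Precomputed CSVs are
accepted through the same interface.

## Robustness screening

Per feature and perturbation kind, a subjects x raters panel (raters =
original + each level; thickness 5, rotation 5, segmentation 3) is scored
with the two-way random-effects, single-rater, absolute-agreement
intraclass correlation ICC(2,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E +
(k/n)(MS_C - MS_E)), clipped to [-1, 1]; an all-equal panel scores 1 by
convention. A feature is robust iff its minimum ICC over the three kinds
is >= 0.85 (configurable; ">= " rather than ">" was chosen and is
exposed). All levels of a kind are pooled into one panel rather than
averaging pairwise ICCs. Standardization (zero mean, unit variance)
happens after filtering, inside each CV training fold.

## Selection cascade

1. Drop features with zero median absolute deviation.
2. Keep the top 20% by absolute Welch t statistic (ceil(0.2 p)).
3. Rank with one of 13 filter selectors. Score-based: ReliefF (k = 10
   nearest hits/misses, range-normalized), Fisher score, Gini impurity
   reduction over threshold splits, chi-square on a 10-equal-frequency-bin
   x class table, |Welch t|. Greedy forward MI selectors use the standard
   conditional-likelihood criteria (MIM, MIFS, MRMR, JMI, CIFE, CMIM,
   ICAP, DISR; formulas in `selection.greedy_mi_select`); mutual
   information is the plug-in estimator on 10 equal-frequency bins; every
   criterion's first pick is argmax I(f;Y); ties break toward the earlier
   catalogue column. The pre-wrapper candidate budget is 30 by default.
4. Recursive feature addition: walk the ranking, keep a feature iff mean
   stratified k-fold CV AUC improves by > 1e-4. If nothing beats chance
   the single top-ranked feature is kept so downstream fitting is defined.

Inside the benchmark the RFA wrapper uses one fixed inexpensive inner
classifier (logistic regression) shared across all 12 outer classifiers;
this lets one (source, selector, fold) cascade be cached across the
classifier axis and keeps the 1,092-model grid tractable. The inner
classifier, fold count and tolerance are configurable.

## Benchmark

Models are named `<Extractor>_<Selector>_<Classifier>`. Per outer
stratified CV fold (10 by default; reduced automatically when the minority
class is smaller): standardize (fit on train), SMOTE the training half to
class parity (synthetic rows x + U(0,1)(x_nn - x) from k = 5 nearest
minority neighbours), run the cascade on the balanced training data, fit
the classifier, score the held-out fold. AUC uses the Mann-Whitney rank
formulation with midranks; model stability is RSD = (sample SD of fold
AUCs / mean) x 100; accuracy/sensitivity/specificity/precision/F1 are
pooled over out-of-fold predictions at probability threshold 0.5.
Classifiers are scikit-learn/XGBoost at library defaults with pinned
seeds (a `tiny` switch shrinks ensembles and iteration caps for reduced
cohorts). A failed fold marks the record but the grid continues. The
per-group optimum is the maximal mean AUC with lower RSD as tie-break.

## Survival

The group variable is the chosen model's *out-of-fold* predicted label —
the leakage-free dichotomization. Kaplan-Meier curves use the
product-limit estimator; the two-group log-rank statistic is chi-square
with 1 df; the univariate Cox model maximises the Breslow partial
likelihood by Newton iteration (score < 1e-8) with Wald 95% CI. The Cox
score test at beta = 0 equals the log-rank statistic on tie-free data,
which the tests assert. Subjects lacking survival data or an out-of-fold
prediction are dropped.

## Problem sizes and what the tests show

The test suite and the acceptance script run scaled-down study conditions
chosen as this package's own defaults for a single-CPU workstation:
phantoms with 16–36 mm tumors on ~1 mm grids, 32–48 pixel crops, cohorts
of 16–103 subjects, stand-in banks of 256–512 features, and reduced
selector budgets (K = 4–10) with 3-fold inner RFA. Calibration suites use
1,000 log-rank replicates (n = 100), 200 Cox replicates (n = 300) and 20
permuted-label benchmark repeats (n = 100). The full-scale settings
(224-pixel crops, 2048-dim banks, K = 30, 10-fold RFA) are the defaults
of the corresponding dataclasses.

Passing tests show the machinery is correct and calibrated on data whose
generative model is known. They do not show that real CT radiomics
features are robust or predictive: the phantoms have no anatomy, no
contrast-phase dynamics, no scanner/reconstruction variability and no
inter-observer segmentation noise, and the robust-feature percentage on
small phantoms is far below what full-size tumors yield, because a 5 mm
slab is a much larger relative perturbation for a 24 mm tumor than for a
60 mm one.

## Known limitations

* 2-D texture with direction-first averaging is one of several defensible
  IBSI-compatible aggregation schemes; values are not interchangeable with
  other schemes.
* The random-convolution bank is a stand-in that exercises the external
  feature contract; conclusions about real CNN features do not transfer.
* The plug-in MI estimator is biased upward at small n; rankings, not MI
  values, are consumed downstream.
* SMOTE before per-fold selection follows the balance-during-CV design;
  selection sees synthetic rows, which slightly smooths selector scores.
* The Cox implementation handles a single binary covariate only (that is
  all the workflow needs).
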