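# Methods

This note documents the models, conventions and design choices behind
`glioprep`, in the order data flows through the pipeline.

## Synthetic cohorts

The generator emulates the two experimental settings the analysis needs:
a *paired* (test–retest / two-scanner) cohort and a *graded*
(two-class, multi-site) cohort. It is a study-condition definition, not
a tuning surface: the defaults in `CohortConfig` are the conditions all
downstream results refer to.

**Anatomy.** An ellipsoidal brain (semi-axes ≈ 0.42 of each grid
dimension, ±5 % per-case jitter) on a 64³ grid at 1 mm isotropic
spacing — the smallest grid on which texture matrices and white-matter
mode detection are meaningful at desk-scale runtime. Three nested
compartments give a T1-like contrast: central CSF (mean 30), cortical
GM rim (mean 80) and WM bulk (mean 120), each with Gaussian intra-tissue
spread of sd 4. WM is by construction the largest compartment so the
brain histogram has a detectable WM mode. Units are arbitrary MR
intensities.

**Tumour.** A sphere fully inside the brain, with volume fraction drawn
from a truncated normal (mean 0.075, sd 0.037, bounds [0.02, 0.16]) —
tumours occupy on average 7.5 % of the brain, small enough that tumour
voxels are *not* excluded from brain-mask normalization statistics.
Tumour intensities are a stationary correlated Gaussian random field
(white noise smoothed with a Gaussian kernel, rescaled): its mean shift
above WM, variance and correlation length are the grade effect sizes
(defaults: low grade +15 / sd 6 / 2.5 voxels, high grade +30 / sd 12 /
1.2 voxels, with per-case jitter of the mean (sd 8) and of the sd
(±20 %) so the classes overlap realistically).

**Scanner effect.** `out = gain · I^gamma · bias(x) + offset + noise`,
with `bias` a low-order separable-polynomial field renormalized to mean
1 over the brain. With gamma = 1, bias amplitude 0 and noise 0 the map
is exactly affine — the regime in which FBN discretization is provably
transparent. Paired-cohort defaults are affine: gain U[0.6, 1.8],
offset U[−20, 20], noise sd 2.4 (2 % of the WM mean). Graded-cohort
defaults are wider (gain U[0.5, 2.0], offset U[−30, 30]) and the gain is
*anti-correlated* with grade (high-grade gains scaled by 0.75, low-grade
by 1.25): raw intensity statistics then actively mislead a grade
classifier, which is exactly the failure mode intensity normalization
exists to fix. The magnitude of real inter-field-strength differences
is not well quantified in the literature; these ranges are a one-time
choice of a plausibly severe multi-site spread.

**Determinism.** Every generator is a pure function of (config, seed).
Per-case seeds are spawned from the master seed via
`numpy.random.SeedSequence(master, spawn_key=...)` and recorded in each
case's metadata and manifest.

**What the phantoms do not model.** No realistic anatomy (no atlas
deformation, no cortical folding), no Rician/k-space noise physics, no
partial-volume mixing, no segmentation error (masks are shared exactly
within a pair). Passing tests therefore demonstrate the *mechanisms*
(affine invariances, agreement statistics, confound removal), not
clinical effect sizes; absolute accuracies on phantoms are higher than
anything achievable on patients.

## Intensity normalization

All statistics come from brain-mask voxels (tumour included); the fitted
transform is applied to every voxel.

* **Z-Score** subtracts the brain mean and divides by the brain standard
  deviation. Population (divide-by-N) convention throughout the
  repository — the scale factor is irrelevant downstream but must be
  fixed for exact tests.
* **WhiteStripe** does the same with the mean/sd of the white stripe.
  Mode detection: brain histogram with a Freedman–Diaconis-like bin
  width (clipped to 32–2048 bins), Gaussian smoothing (sigma 2 bins),
  prominent local maxima via peak finding (prominence ≥ 5 % of the
  smoothed maximum); the *last* (highest-intensity) prominent mode is
  taken for T1-like contrast, the largest for T2-like. The ±5 % band is
  interpreted on the intensity axis: stripe = voxels with
  I ∈ [0.95 μ_mode, 1.05 μ_mode] for a positive mode; for a non-positive
  mode (e.g. re-normalizing an already standardized image) a symmetric
  band of half-width 0.05 × (p99 − p1 of brain intensities) is used.
  A quantile-window band would make the method exactly idempotent, but
  the intensity-axis reading is the conventional one and is kept; the
  consequence is that a second application re-centres the stripe at 0
  without being a strict identity.
* **Nyúl** learns a standard histogram by computing the landmark
  percentiles (default C_L = [1, 10, …, 90, 99], linear-interpolation
  percentile convention, fixed repository-wide) over brain voxels of
  each training image, mapping each image's [first, last] landmark
  interval affinely onto the standard scale (default (0, 100) — any
  increasing interval works; it is recorded in the model), and averaging
  across images. The transform is the monotone piecewise-linear map
  sending an image's landmarks exactly onto the standard ones, extended
  beyond the outer landmarks with the end segments' slopes.

## Grey-level discretization

FBS: `level = ⌊X/w_b⌋ − ⌊X_min/w_b⌋ + 1` (levels start at 1, count grows
with the ROI range). FBN: `level = ⌊N_g (X − X_min)/(X_max − X_min)⌋ + 1`
capped at N_g, with the maximum mapped to N_g. Floors are evaluated with
a relative epsilon guard (1e−12) so values landing on a bin boundary up
to floating round-off discretize reproducibly; this is what makes the
FBN affine-invariance exact in practice, not just approximate.

To compare FBS across conditions whose intensity ranges differ, the bin
width for a nominal count N_g is `mean_Range / N_g`, where `mean_Range`
is the mean tumour-ROI intensity range over the cohort of one
(sequence × normalization) condition, computed *after* normalization —
per-condition computation is required for the nominal bin counts to be
comparable across normalization methods.

First-order Entropy and Uniformity are the only first-order features
that need binning; they reuse the experiment's active discretization
spec. The summary robustness comparison of first-order features uses
FBS at 32 bins, because under FBN these two features are affine-invariant
and would not discriminate between normalization methods.

## Features

The 91-feature set is 18 first-order + 22 GLCM + 16 GLRLM + 16 GLSZM +
5 NGTDM + 14 GLDM, IBSI-style definitions. Conventions:

* direction-dependent matrices (GLCM symmetric, GLRLM) are built per
  direction — 3D, Chebyshev distance 1, 13 unique directions — and the
  features averaged over directions (directions without a valid voxel
  pair are skipped);
* GLDM uses alpha = 0 and distance 1; the dependence of a centre voxel
  is the raw count k ∈ 0..26 of in-mask neighbours within alpha levels,
  and the feature formulas use the column index j = k + 1 so
  small-dependence emphases stay finite;
* GLSZM zones are 26-connected components of equal level;
* NGTDM centre voxels without any in-mask neighbour are excluded;
* kurtosis is Pearson (non-excess); skewness/kurtosis of a constant ROI
  fall back to 0; NGTDM coarseness with a zero denominator returns the
  sentinel 1e6; logs are base 2 with 0·log 0 := 0. Every emitted vector
  is finite by construction.

Texture is computed on the tumour bounding box only (boolean-mask
ordering is preserved under C-order cropping), which keeps a 243-case ×
3-normalization extraction under a minute.

## Robustness statistics

JSD uses base-2 logarithms (range [0, 1]) on histograms over a shared
support: 256 equal-width bins spanning the union of the two brain-mask
intensity ranges of a pair. ICC is the two-way random-effects,
absolute-agreement, single-measurement form ICC(2,1) — the standard
test–retest choice — computed from the mean-squares decomposition; zero
total variance returns 1 by convention. CCC is Lin's concordance with
population moments. A feature is robust iff *both* exceed 0.8 strictly.

## Classification harness

Five families at library defaults (random forest, Gaussian naïve Bayes,
logistic regression with max_iter = 1000, SVC, MLP), each seeded;
stratified 5-fold CV with shuffled, seeded fold assignment (memberships
are recorded in the result). Column-wise feature z-scoring is fitted on
training rows only; the per-fold scaler parameters are exposed so the
no-leakage property is directly testable. ROC-AUC uses the Mann–Whitney
rank formulation (ties ½); balanced accuracy is (sensitivity +
specificity)/2. The 95 % CI is a percentile bootstrap (1000 resamples)
of the mean of the pooled 25 fold × model scores — pooled scores are the
resampling unit. ANOVA uses type-II sums of squares (robust to the
unbalanced designs that arise here), with Tukey HSD post-hoc tests for
factors significant at 0.05.

Feature-set models: 1 = first-order only, 2 = texture only, 3 = both,
4 = the robust subset from a paired-cohort robustness report (model 4 is
skipped with a recorded warning when the robust set is empty).

## Numerical and degenerate-input choices

* Constant image inside the brain mask: Z-Score raises (no NaN output).
* Empty white stripe or undetectable mode: explicit error naming the
  failure.
* Tied image landmarks (non-increasing percentiles): Nyúl raises.
* Constant ROI: FBN raises (zero denominator); FBS yields a single
  level; first-order falls back as above.
* ICC needs n ≥ 3 subjects; CCC of two identical constant columns is 1.

## Orchestration and reproducibility

`run_all` writes a config hash (sha256 of the canonical config JSON) and
the master seed into every artifact; CSV floats use a fixed `%.12g`
format and JSON keys are sorted, so re-running an identical config
byte-reproduces every output. Timing/progress goes to the logger, never
into result files.

## Problem sizes

Defaults follow the study design: 20 paired subjects and 108 + 135
graded cases on 64³ grids. The full default condition grid
(4 methods × 2 modes × 8 bin counts × 4 models) is supported but large;
the test-suite and the acceptance script exercise representative slices
(32 bins, FBS/FBN, models 1–2) that demonstrate every mechanism at
desk-scale runtime.

## Known limitations

* The phantom's tissue simplicity makes WhiteStripe's mode detection
  easier than on real FLAIR images; the contrast heuristic (`t1` vs
  `t2`) is exposed but only the T1-like path is exercised by default.
* Nyúl's standard histogram is learned from the analysis cohort itself
  (no held-out training set), matching common practice when no external
  standard exists.
* Bootstrap CIs treat the 25 fold × model scores as exchangeable; fold
  overlap means they are not independent, so the CIs are descriptive
  rather than strictly inferential — the comparisons across conditions
  rely on the ANOVA, not on CI overlap.
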