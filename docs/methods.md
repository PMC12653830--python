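# Methods

This note documents the models, conventions and numerical choices behind
`dceqc`, and what its synthetic benchmarks do and do not demonstrate.

## Problem and model

The task is a binary, no-reference quality decision per patient on the
first post-contrast phase of a breast DCE-MRI series: class 0 = high
quality, class 1 = low quality (noisy, blurry, low-contrast, or carrying
severe artifacts).  The decision is learned from hand-labelled examples as
a standard radiomics pipeline: handcrafted texture/intensity features from
two ROIs, sparse feature selection, and a conventional classifier under
patient-level cross-validation.  No anatomy segmentation is needed — the
two ROIs are the whole image and an automatically located background
(air) region, on the rationale that noise and many artifacts are most
visible where there is no signal, while blur is only visible where there
is.

## Slice sampling

* **12-slice scenario**: the through-plane index range is split into
  integer thirds `[0, Z//3)`, `[Z//3, 2Z//3)`, `[2Z//3, Z)`; 3, 6 and 3
  linearly spaced indices (inclusive of the third boundaries, rounded to
  nearest) are drawn per third.  Rounding collisions shift to the nearest
  unused index inside the same third first, then anywhere, so exactly 12
  distinct slices always result.  For `Z < 18` the middle third holds
  fewer than 6 integers and the 3/6/3 split is geometrically impossible;
  the sampler then spills into the adjacent thirds (at `Z = 12` it simply
  returns every slice).
* **Middle-slice scenario**: index `⌊Z/2⌋` (floor convention for even Z —
  deterministic and conventional).

The through-plane axis is inferred from the NIfTI header as the axis with
the largest voxel spacing, with an explicit override for unusual headers.

## Intensity normalization and discretization

Each analysed slice is z-scored (population SD) using whole-slice
statistics; whole-volume statistics are available via
`ExtractionConfig(normalize_per="volume")`.  The same affine map applies to
every pixel, so ROI restrictions see consistently scaled data.

Gray levels for the texture matrices use IBSI fixed-bin-size
discretization referenced to the ROI minimum, `level = ⌊(x − min)/w⌋ + 1`.
The default width `w = 54` is the mean ROI intensity range divided by a
fixed bin number of 64 and is defined on the *raw* intensity scale — on
z-scored data (range of a few units) it would collapse everything into one
bin.  The package therefore discretizes the raw-intensity filtered images
for texture, computes first-order moments on the z-scored filtered images,
and reuses the texture gray levels for first-order entropy/uniformity
(IBSI computes those on discretized intensities).  Setting
`texture_on_normalized=True` together with a sub-unit bin width switches
the texture source to the z-scored bank; `bin_width=1` on integer data is
the "no discretization" regime.

## Filter bank

Nine filtered images per slice: original; one-level 2D `coif1` DWT
subbands LL/LH/HL/HH, nearest-upsampled back to the input raster so a
single mask fits all filtered images (LH responds to variation along
rows); Laplacian-of-Gaussian at σ ∈ {2, 3, 4, 5} pixels with reflective
boundaries.  The truncated discrete LoG kernel retains a small DC gain
(~1.7e-4 at truncation 4σ); it is measured once per σ and subtracted so
constant regions respond exactly zero.  σ is interpreted in pixels; mm
would require voxel spacing and is deliberately out of scope for 2D
slice analysis.

## Feature bank (821 per ROI)

Per filtered image: 18 first-order, 22 GLCM, 14 GLDM, 16 GLRLM, 16 GLSZM,
5 NGTDM = 91; × 9 images = 819; + BRISQUE-style score + total variation =
821.  Combined mode appends the background vector with suffix `_bg`
(1642).  Conventions, all asserted by tests:

* **GLCM**: symmetric, distance 1, four in-plane directions, features
  computed per direction then averaged.  The 22-feature set excludes the
  two redundant IBSI features (sum average duplicates joint average under
  symmetry; dissimilarity duplicates difference average).  Degenerate
  single-level regions take analytic limits: contrast/entropies 0,
  correlation defined as 1, IMC1 := 0 when the marginal entropy vanishes.
* **GLRLM**: runs of equal level along the four directions; out-of-mask
  pixels break runs; features averaged over directions.
* **GLSZM**: 8-connected zones, single matrix; stored sparsely as
  (level, size, count) triplets since zone sizes reach the pixel count.
* **GLDM**: dependence size = 1 + number of in-mask Chebyshev-distance-1
  neighbours whose level differs by ≤ α (default α = 0).
* **NGTDM**: neighbourhood mean over in-mask 8-neighbours; coarseness
  capped at 1e6 on homogeneous regions.
* **First-order**: population moments; kurtosis is the plain fourth
  standardized moment (3 for a Gaussian); skewness/kurtosis of constant
  samples are 0; robust MAD is the mean absolute deviation of the
  10–90 percentile subsample about its own mean.

Pixels outside a mask never contribute to any matrix.  The background ROI
is the pooled union of the two selected corner squares (the alternative —
averaging two separate extractions — was rejected to keep one matrix per
region and more pixels per statistic).

## Background localization

Corner squares of ⌊H/8⌋ × ⌊W/8⌋; SNR = mean/(population SD + 1e-6); among
the four non-diagonal pairs the pair with minimum total SNR wins, ties
broken in the fixed order (TL,TR) < (BL,BR) < (TL,BL) < (TR,BR).  The
minimum-total-SNR formalization reflects that anatomy-free corners have
low mean and relatively high noise SD; a uniform bright anatomy patch has
a huge SNR and is avoided.  The non-diagonal constraint keeps the region
on one image edge, robust to axial vs sagittal orientation.

## No-reference metrics

* **Total variation**: anisotropic sum of absolute neighbour differences,
  normalized by pixel count by default (raw available).  Computed on the
  z-scored slice, and on the stitched pair of corner squares for the
  background ROI.
* **BRISQUE-style NSS score**: the standard 36-feature construction —
  MSCN coefficients (7×7 Gaussian window, σ = 7/6, stabilizer 1 on a
  [0,255] rescale), generalized-Gaussian fit to the MSCN field and AGGD
  moment-matched fits to the four pairwise products, at two dyadic
  scales.  The scalar score is an *NSS divergence*: the RMS standardized
  distance of those 36 features from a reference distribution fitted at
  run time to 24 clean phantom slices (fixed internal seed, cached per
  process).  Higher = further from clean statistics = worse.  The score
  is finite on constant images and increases under blur (σ ≥ 2) and heavy
  noise, which is the behaviour the pipeline consumes; it is *not*
  numerically interchangeable with scores from a natural-image-trained
  regressor, and the feature-selection stage is free to discard it (as
  the underlying study also observed for NR metrics on breast MRI).
  Images narrower than 8 pixels are rejected; the background strip
  (stitched corner squares) satisfies this at all supported corner
  fractions.

## Feature selection

Three steps, fitted strictly on training folds: (1) drop features with
variance ≤ 0.05 on the raw training values (subsumes constant-feature
removal); (2) one-way ANOVA between the two classes, keep p < 0.05
(a top-k alternative is exposed); (3) L1 logistic regression, liblinear,
C = 0.5, on standardized features; keep |coefficient| > 1e-8.  The solver
seed is fixed and recorded.  Note that coordinate-descent L1 splits weight
across exactly collinear features rather than dropping one — the pair's
*total* influence is conserved, which the tests assert instead of
single-survivor behaviour.  On the synthetic cohorts the pipeline retains
roughly 15–20 features per fold.

## Cross-validation, metrics, soft voting

Folds are stratified at patient level (all slices of a patient share a
fold); fold assignment, selection, scaling and classifier fitting never
see held-out rows, a property enforced by a mutation test.  Class 1 (low
quality) is the positive class.  Metrics are computed at patient level:
per-slice class-1 probabilities are averaged per patient (soft voting) and
thresholded at 0.5, with a tie resolving to high quality; AUC uses the
averaged probabilities.  Summaries report mean ± population SD across
folds.  The best fold (for explanation) is the highest accuracy, ties
broken by AUC then lowest fold id.  Classifier hyperparameters beyond
those stated above are scikit-learn defaults, frozen in the run report;
SVM probabilities come from Platt calibration on the training fold.

## Shapley explanation

Permutation-sampling Shapley values with the coalition value
`v(S) = mean_b f(x_S, b_{S̄})` over a seeded ≤ 100-row training-fold
background.  Each sampled permutation is paired with its reverse
(antithetic sampling), and every permutation walk telescopes exactly to
`f(x) − base`, so local accuracy holds to floating point for any number of
permutations; more permutations only sharpen the per-feature split.
Explanations default to the best fold's test samples.

## Synthetic phantom generator

Each phantom emulates the gross structure the ROI logic relies on: a
bright ellipse (anatomy, ~1000 intensity units with 4% internal texture)
whose extent shrinks toward the stack ends, a chest-wall band (~550) along
the bottom edge — which can flood the *bottom* corners, exactly the
situation the SNR rule must handle — and air noise (σ ≈ 12–25).
Degradations are applied in the order blur → zebra (multiplicative
sinusoidal stripes) → ghost (shifted attenuated copy) → noise (Gaussian
default, Rician option, clipped at 0).  The label follows a severity score
`noise/100 + blur/3 + zebra/0.4 + ghost/0.4` thresholded at 0.8, and the
class-conditional severity distributions leave a guard band around the
threshold (low: severity ≲ 0.3; high: ≳ 1.4), so synthetic classes are
separable *by construction*.

What this does and does not show: near-perfect synthetic metrics validate
the plumbing — sampling, ROI logic, feature definitions, leakage-free CV,
voting, attribution — not clinical performance.  Real breast DCE-MRI
quality boundaries are far subtler (borderline cases, inter-reader
disagreement, protocol heterogeneity, Rician/structured noise, coil
shading), and classifier accuracy on real cohorts must be established on
expert-labelled data.

## Problem sizes and defaults

Phantoms default to 64 × 64 × 18 voxels — large enough for the σ = 5 LoG
kernel and 8 × 8 corner squares while keeping the full 110-patients-per-
class benchmark (the sample size the study design targets) comfortably
fast on a single CPU.  The end-to-end benchmarks use 10-fold CV with the
SVM-RBF classifier on combined whole+background features, in both slice
scenarios.

## Known limitations

* 2D extraction only; no shape features (no anatomy mask exists).
* DICOM reading, registration and bias-field correction are upstream
  concerns.
* The NSS score's reference model is phantom-derived; absolute score
  values are not comparable with published BRISQUE numbers.
* The k-space physics of real artifacts (coil sensitivity, susceptibility,
  motion) is only caricatured by the phantom degradations.
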