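# Methods

## Problem and scope

`osteotex` estimates integer chronological age (years, nominal range 9–17)
from the texture of rectangular regions of interest in coronal wrist MRI of
adolescents. Two ROI kinds are modelled: a *bone* region sampling the
trabecular pattern of the distal radius, and a *growth* region spanning the
bright cartilaginous growth plate. The package covers scan I/O, ROI
resolution, intensity normalization, a 307-feature texture descriptor, a
cross-validated regression pipeline, and a synthetic cohort generator that
stands in for clinical data, which cannot be distributed. Manual steps that
precede this pipeline in practice — ROI placement, motion-artifact
screening — are out of scope: ROIs are inputs.

## Images and ROIs

Scans are single-frame grayscale slices: 12-bit DICOM (the original
acquisition representation) or 8-bit PNG exports normalized to 0–255.
Coordinates are 0-based, row-major; ROI rectangles are half-open. An ROI may
be specified in pixels or millimetres; metric ROIs are resolved against the
scan's pixel spacing (mm/px, read from DICOM metadata or supplied for PNG,
which carries none) and rounded half-away-from-zero with a 1-pixel floor, so
equal physical extents are compared across scans whose spacing varies
(0.2539–0.3516 mm in the emulated acquisition). Rounding half away from zero
is used everywhere a real value becomes a gray level or a pixel count; it is
platform-stable, unlike banker's rounding of exact halves.

DICOM rescale slope/intercept are applied (then rounded) when present;
otherwise stored values are used untouched. 12-bit data written to PNG uses
a 16-bit container verbatim, and the effective bit depth is declared by the
manifest rather than inferred from the container.

## ±3σ normalization

With μ and σ the mean and *population* standard deviation of the region,
intensities are mapped linearly so that μ−3σ → 0 and μ+3σ → L, then clamped
to [0, L] and rounded. L defaults to the full input range (255 or 4095); a
`ceiling` parameter allows clamping 12-bit data onto 255 instead. For a
Gaussian-like histogram ≈ 0.3% of pixels clamp, and the operation
standardizes location and scale: any affine intensity change aI + b (a > 0)
leaves the output unchanged up to ±1 gray level of rounding. A constant
region (σ = 0) maps to the mid-gray constant round(L/2); this degenerate
case is covered by tests. The population σ (rather than the n−1 sample
form) was chosen because the region is treated as the complete pixel
population being rescaled; at typical ROI sizes (≈10³ pixels) the difference
is far below one gray level.

## Texture descriptor

All families operate on the normalized region. Directions are the offsets
(0,d), (d,d), (d,0), (d,−d) in (row, col) coordinates, labelled 0°, 45°,
90°, 135°. Entropies use the natural logarithm with 0·log 0 ≡ 0.

* **Histogram (9).** Mean, population variance, skewness, *excess* kurtosis
  (0 for degenerate distributions), and percentiles 1, 10, 50, 90, 99
  (linear interpolation). The excess form of kurtosis was fixed once and is
  asserted by tests; the variant without −3 differs only by a constant and
  is immaterial to rank-based selection downstream.
* **Co-occurrence (220).** Intensities are uniformly re-binned to G = 64
  levels (configurable); for each direction and distance d ∈ {1..5} the
  pair-count matrix is symmetrized and normalized to sum 1. Eleven
  statistics per matrix: angular second moment, contrast, correlation, sum
  of squares, inverse difference moment, sum average, sum variance, sum
  entropy, entropy, difference variance, difference entropy. Means and
  variances inside correlation/sum-of-squares use the marginal gray-level
  distribution (the two marginals coincide for a symmetric matrix);
  sum variance is centred on the sum average; difference variance is the
  variance of the |i−j| distribution. A degenerate marginal yields
  correlation 0. G = 64 keeps the matrices dense enough at ROI sizes of
  10³ pixels while preserving gray-level discrimination.
* **Run-length (20).** Maximal runs of equal quantized level along each
  direction (the same G); the five Galloway statistics: short- and long-run
  emphasis, gray-level and run-length nonuniformity, and run percentage
  (runs per pixel).
* **Gradient (5).** Absolute response of a 3×3 Laplacian-type high-pass
  mask on the region interior (boundary excluded, so no padding convention
  enters); mean, variance, skewness, kurtosis of the magnitude map and the
  fraction of nonzero magnitudes. Invariant to constant offsets by
  construction.
* **Autoregressive (5).** Each interior pixel is predicted as a weighted
  sum of its left, upper-left, upper and upper-right neighbors; the weights
  θ₁..θ₄ are fitted by least squares (minimum-norm solution when the design
  is rank-deficient, e.g. constant regions) and the fifth feature is the
  population standard deviation of the residuals. No intercept is used —
  the model is a pure weighted sum — so the weights absorb the region's
  mean level; tests verify parameter recovery on simulated zero-mean AR
  fields and residual orthogonality on arbitrary regions.
* **Haar (16).** The region is cropped (top-left anchored) to dimensions
  divisible by 2⁴ and decomposed 4 dyadic scales deep with the periodized
  orthogonal Haar transform; each feature is the mean squared coefficient
  of one subband (LL, LH, HL, HH) at one scale. Periodization keeps the
  transform exactly orthogonal (Parseval holds to machine precision), at
  the cost of wrap-around coupling between opposite edges — acceptable for
  texture patches, which are approximately stationary.
* **Gabor (24).** Complex Gabor kernels with wavelength λ = s and Gaussian
  σ = s/2 for envelope sizes s ∈ {4, 6, 8, 12, 16, 24} pixels and the four
  direction angles (modulation axis aligned with the matrix-family
  offsets); kernels are truncated at 3σ and normalized by envelope mass.
  The region mean is subtracted before filtering, making the bank exactly
  DC-free. The feature is the mean response magnitude over the region
  (reflect boundary handling, FFT convolution).
* **HOG (8).** Central-difference gradients on the interior; orientations
  on [0°, 360°) in 8 equal bins, magnitude-weighted, normalized to sum 1
  (all-zero for gradient-free regions).

The schema — names and order — is fixed; extraction is deterministic and
bit-identical on repeated calls, and every value is finite for every valid
input including constant regions. The strictest size precondition among the
families (the 24-pixel Gabor envelope) sets the minimum usable ROI.

## Regression pipeline

`TextureAgeModel.fit()` runs leave-one-out cross-validation with one fold
per image (or per patient when `group_folds=True`, for cohorts where
patients contribute up to three images). Per fold, on training rows only:

1. **Selection.** Features ranked by |Spearman ρ| against age; the top
   k = 15 kept. Constant features get ρ = 0; ties break by schema order, so
   selection is deterministic. Rank correlation is used because feature/age
   relations are monotone but not linear, and |ρ| because sign is
   irrelevant to a nonlinear regressor.
2. **PCA.** The 15 features are standardized by training-fold mean and
   standard deviation and projected onto the first 3 principal components
   (deterministic full SVD; an effective training rank below 3 raises an
   error). 3 components for ≈50 training samples keeps roughly 15 samples
   per regressor input.
3. **Perceptron.** Component scores, standardized by training-fold scale,
   feed a two-hidden-layer perceptron (10 + 10 rectified-linear units,
   linear output) trained with L-BFGS (weight-decay α = 10⁻⁴, tolerance
   10⁻⁸, iteration cap 4000). Full-batch L-BFGS makes the fit
   deterministic given the seeded weight initialization; each fold's seed
   derives arithmetically from the single top-level seed, so reruns are
   bit-identical and a fold's model is independent of its held-out row.
4. **Prediction clamp.** Fold predictions are clipped to the training
   fold's observed age range. Age is a bounded label; outside the observed
   support the rectified-linear network extrapolates linearly and can
   produce physically impossible ages (e.g. > 20 years) exactly for the
   extreme-age samples that leave-one-out isolates.

Pooled held-out predictions give MSE, RMSE = √MSE, MAE, and
R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² with ȳ the overall mean of true ages — one
coefficient per dataset. Note that under this pooled definition R² of a
label-shuffled control is typically strongly *negative*, not near zero.

## Synthetic cohorts

`generate_cohort` emulates the statistics the pipeline consumes, not the
anatomy: 512×512 12-bit masters at the three pixel spacings, a smooth
marrow background, a trabecular patch of correlated Gaussian noise, a
horizontal growth band with a soft (≈1 px logistic) edge, white acquisition
noise (σ = 45 twelve-bit units), T1 and T2 contrast variants (T2 inverts
the band/marrow contrast), and an 8-bit export by per-image min-max
scaling. Default cohort shape: 30 patients, 55 images (1–3 per patient),
integer ages drawn from a distribution with mean ≈ 12.4 and median 12 on
9–17.

Because ±3σ normalization removes intensity location and scale, a purely
photometric age effect would be invisible downstream; the age signal is
therefore carried by *structure*:

* growth-band width w(age) = 20 − 1.8·effect·(age−9) px (+ patient jitter,
  σ = 0.5 px): the band's area fraction inside the 32-row growth ROI falls
  from ≈0.6 to ≈0.18 across the age range, reshaping the intensity
  distribution (upper percentiles, skewness);
* band brightness 3400 − 95·effect·(age−9) (+ jitter σ = 20): younger
  plates are brighter as well as wider;
* trabecular correlation length 2.5 − 0.2·effect·(age−9) px (+ jitter
  σ = 0.05) with contrast tied to it: younger bone is coarser, which moves
  co-occurrence correlation/IDM across distances 1–5, Haar scale energies
  and AR weights.

`effect_strength` ∈ [0, 1] scales all three slopes; at 0 every parameter is
age-independent and feature/age associations sit at their null rates (the
test asserts the fraction of features beating a per-feature permutation
95% bound stays ≤ 0.12 — the null expectation is 5%, and inter-feature
correlation inflates the variance of that fraction, hence the slack).
Patient-level parameters are shared across a patient's images; pixel noise
is independent per image. Everything derives from one seed; pixel outputs
are integer, so cohorts are bit-reproducible across platforms.

What the generator does **not** emulate: anatomy (bone contours, carpal
bones), MR physics (coil profiles, bias fields, chemical shift), motion
artifacts, inter-scanner variation, and any irregularity of the real
age→texture relation. Passing recovery tests therefore demonstrate that the
pipeline can extract a planted monotone structural effect at realistic
sample sizes and noise levels — not that real wrist MRI carries an effect
of that size.

## Evaluation at study scale

The acceptance script and tests run the full chain on the default cohort
(55 bone images; 30 growth images, one per patient, 12-bit T1). Typical
results at full effect strength: pooled LOO R² ≈ 0.88–0.90 for the bone
region with MAE ≈ 0.45–0.64 years; shuffled-label controls give R² well
below 0; R² increases monotonically in effect strength over {0, 0.5, 1}.
The growth-region analysis (n = 30) is markedly less stable across seeds —
with 30 samples a handful of hard folds dominates the pooled metrics —
which mirrors the general experience that half-sized cohorts give noisier
cross-validated estimates.

## Known limitations

* The 11 co-occurrence statistics admit textbook variants (centering of
  sum variance, marginal vs joint means); the choices above are fixed,
  internally consistent, and pinned by brute-force-oracle tests.
* Leave-one-out is honest but high-variance at n = 30–55; pooled R² can
  swing by ±0.1 across generator seeds at identical settings.
* Metric ROIs rounded to the nearest pixel change the pixel count by a few
  percent across the spacing range; features are not re-weighted for this.
* The perceptron is a fixed topology with no hyperparameter search, by
  design; the package measures the pipeline, it does not tune it.
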