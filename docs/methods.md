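# Methods

This note records the models implemented in `scqp`, the assumptions behind
them, the parameter and numerical choices that were genuinely open, and
what the synthetic benchmarks do and do not demonstrate.

## The G/V quantifier

For channels on [0, 1] the package quantifies analyte level with
`signal = 1 − G/V`, `V = max(R, G, B)`.  Two properties carry the design:

1. **Illumination invariance.**  If a pixel's linear channels are scaled by
   a common factor t (shading, exposure, distance), G/V is unchanged; and
   since gamma encoding maps the ratio to `(G/V)^(1/γ)`, the invariance
   survives the camera's power-law response.  Raw channels, grayscale and
   HSV value all lack this property.
2. **Relation to saturation.**  `1 − G/V = S` exactly when G is the minimum
   channel (the hexcone definition `S = 1 − min/max`), which holds for
   red-family analytes over their full range; unlike S, the ratio stays
   informative when another channel becomes the minimum at low
   concentration.

Conventions are pinned for testability: hue in degrees (0 for achromatic
pixels, with an explicit flag), S and V as percentages, grayscale with
BT.601 weights 0.299/0.587/0.114, CIELAB under sRGB primaries, D65 white
and the 2° observer.  Camera-specific profiles are out of scope.

## Evenness equalization

The correction assumes the image is a product of reflectance and a smooth
illumination field and operates only on the HSV value matrix `I` (range
[0, 1]).  A multiscale Gaussian surround

    L = mean_σ (K_σ * I),   σ ∈ {20, 72, 250} px, equal weights

estimates the illumination; the calibrated value matrix is

    N = clip(I + k·(L̄ − L), 0, 1),   k = 1 − μ,   μ ∈ [0, 1].

μ = 1 gives the identity, μ = 0 full flattening (`I − L + L̄`); the degree
of calibration is monotone in μ by construction.  The k(μ) form and the
equal scale weights were open design choices; `k = 1 − μ` is the simplest
map satisfying the stated endpoint behavior, and equal weights are the
standard multiscale-retinex convention.  Kernels are truncated at 3σ and
renormalized to unit sum; boundaries are handled by reflection (zero
padding would darken edges).  For kernel radii above 48 px the separable
spatial filter is replaced by FFT convolution on a symmetric-padded image —
numerically identical (≤ 1e-15) and far cheaper at σ = 250, whose 1501-px
support is meant for megapixel-scale photographs.  Images smaller than the
smallest kernel support are rejected.

The output image rescales each pixel's RGB triple by `N/I` rather than
re-encoding through HSV: the result has value exactly N, and hue and
saturation are preserved identically in exact arithmetic (a common positive
factor changes neither the hue angle nor 1 − min/max).  In floating point
the saturation of the output can differ by one ulp, which is what the tests
assert.  Pixels with V = 0 carry no chromatic information and become
neutral gray at the calibrated value.

## Distance calibration

Channel linearization uses the display-gamma model `D = 255·(G/255)^γ` with
γ = 2.2 by default (admissible range 2.0–2.2, configurable).  Distance is
corrected in linear-light space by the exponential model

    C_D2 = D2 · τ^(ΔDistance / 5),   τ = 1.1,

i.e. the amendment factor per 5 cm step, followed by re-encoding; the
residual against a reference-distance image is reported as mean |D1 − C_D2|.
The simulator attenuates with the same exponential family, so the closure
is exact by construction in the noise-free, unquantized limit; real optics
follow an approximately inverse-square law over larger ranges, so τ should
be recalibrated per setup (as its role as an empirical amendment factor
implies).  Sensor saturation (linear values clipped at full scale) is not
invertible by any calibration; closure benchmarks keep scenes inside the
dynamic range.

## Chip segmentation and signal extraction

Grid detection: grayscale → Sobel gradient → Otsu threshold → morphological
closing → hole filling → connected components; the 36 groove interiors are
the largest consistently sized interior regions, assigned to rows and
columns by sorting centroid coordinates into six equal-occupancy runs
(exact for a grid; validity requires inter-run gaps to exceed within-run
spread).  Boxes are the inner 60% of the detected cell, centered on each
region centroid, which tolerates small chip rotations (~2°).  Failures
raise an error carrying the candidate count.

Artifact filtering uses the value channel in two stages: (1) robust outlier
rejection — pixels more than 6 robust sigmas (1.4826·MAD, floored at 0.02)
from the box median are dropped, which removes shadow bands and saturated
glare clusters of any size up to half the box; (2) a symmetric 5% rank trim
of the survivors, which keeps the rejected fraction near the nominal 10%
even for uniform boxes where value thresholds tie.  A fixed percentile trim
alone cannot exclude a 10% glare cluster, which is why the robust stage
exists.  Grooves keeping fewer than 25 pixels, or rejecting ≥ 80%, are
unusable.

Calibration fits concentration on the G/V signal by ordinary least squares
(≥ 3 distinct standards required); quantification flags signals outside the
calibrated range as extrapolation.  The benchmark figure of merit is the
mean absolute concentration error divided by the mean true concentration
(the ladder includes 0 µg/mL, where a per-sample relative error is
undefined).

## Training machinery

All estimators follow the scikit-learn protocol and are seeded; fits are
bit-reproducible given (data, parameters, seed).

* **Lasso-loss linear / polynomial regression** minimizes
  `0.5·mean((Xw + b − y)²) + α‖w‖₁` (α = 0.1 for the concentration models)
  by minibatch SGD with a 1/t-decayed learning rate.  The L1 term is
  handled by a proximal soft-threshold step rather than a plain
  subgradient, so exact zeros and the 1-D closed form
  `w = S(cov(x, y), α)` are reachable.  Defaults: lr 0.01, decay 0.01,
  500 epochs, batch 16; full-batch mode (`batch_size=None`) gives
  deterministic, monotone descent and is used wherever closed-form
  agreement at 1e-4…1e-6 is required.  The polynomial variant maps
  features to [x, x²].
* **Linear ε-insensitive SVR** minimizes
  `0.5‖w‖² + C·Σ max(0, |r| − ε)` (C = 1.5, ε = 1).  The regularizer makes
  the objective 1-strongly convex in w, so steps follow `1/(t0 + t)` and
  the returned w averages the tail half of the iterates.  The
  unregularized intercept has no curvature to exploit and converges too
  slowly on that schedule; it is instead minimized exactly once per epoch
  (the slack sum is piecewise linear in b; the flat minimizing interval is
  found by direct evaluation over the `r ± ε` breakpoints and its midpoint
  taken).  This reaches libsvm-level objectives within ~1e-3.
* **CART regression** uses variance-reduction splits over midpoints of
  sorted unique values, depth ≤ 3, ties broken to the lowest feature index
  then lowest threshold, leaf prediction the mean.  Predictions are
  invariant to strictly monotone per-feature rescaling.
* **Fully connected network** 5 → 64 → 32 → 16 → 5 → 1 with ReLU hidden
  units, squared-error loss, plain SGD, and early stopping when validation
  loss (20% split) has not improved for 15 epochs; the best-validation
  weights are restored.  The target is internally centered and scaled for
  conditioning.
* **Logistic classification** minimizes cross-entropy by SGD with
  probabilities clipped to (1e-12, 1 − 1e-12).
* **K-fold cross-validation** (K = 10) uses a seeded shuffled partition
  with fold sizes differing by at most one; standardization parameters are
  learned on training folds only and applied to validation folds.

SGD hyperparameters were not externally constrained; the defaults above are
declared once and configurable.  Tests requiring tight convergence use the
full-batch mode with more epochs — a statement about the optimizer, not
about the data.

## Oximetry correction system

The melanin index is the standard narrow-band reflectance definition
`M = 100·log₁₀(1/R₆₅₅)`; the baseline skin tone of a subject averages the
six inner-arm spectrophotometer replicates (outer-arm sites are recorded
but excluded as sun-exposed).  The melanin–lightness relation is fitted as
a 4-parameter logistic in 1/L* with an OLS linear approximation alongside;
over the mid-range tones the cohorts span, the linear fit reaches R² ≈ 0.97.

Three linked linear models form the correction chain, all trained with the
Lasso-loss SGD regressor on standardized features:

1. **Oximeter correction:** gold-standard SpO₂ (A) on
   `[F, L*, a*, b*, M]`; its prediction (clipped to [0, 100]) becomes the
   reference for the camera-side models.
2. **Color correction:** four models mapping `[L_s*, a_s*, b_s*, G_s, B_s,
   ISO-or-V]` to `L*, a*, b*, M`, so later use needs no spectrophotometer.
3. **App SpO₂ model** on lip color features plus corrected tone against the
   corrected-oximeter reference; the **pCO₂ model** shares its structure.
   Both use noise-based training: exactly `round(0.2·n_train)` seeded rows
   receive additive Gaussian feature noise with σ = 10% of each feature's
   spread (unit after standardization); the injection mask is recorded.
   The noise distribution was an open choice; Gaussian at 10% is a
   conventional augmentation scale.  Predictions clip to [0, 100]% and
   [10, 100] mmHg.

The correction models use α = 1e-4 — a token L1 that keeps the Lasso-loss
structure without materially shrinking weights; the α = 0.1 setting belongs
to the chip concentration models, whose engineered features are
deliberately redundant.  Their optimizer runs full-batch for 20000 steps
(lr 0.1, decay 1e-4) because the standardized tone features are strongly
collinear (smallest covariance eigenvalue ≈ 0.02) and individual weights
converge slowly in that subspace.

Classification: hypoxemia is `SpO₂ ≤ 95%`; the three-band label splits at
95 and 97.  Bland–Altman statistics use the convention (method under test −
reference), with limits of agreement `bias ± 1.96·sd` (sd with ddof = 1).

## The simulator and what the benchmarks show

The camera model multiplies a reflectance scene by an illumination field, a
`τ^(−Δd/5)` distance factor, an auto-exposure gain and white-balance gains,
adds Gaussian sensor noise, clips, gamma-encodes and (optionally)
quantizes to 8 bits.  Design choices:

* Distance attenuation uses the calibration's own exponential family so
  closure is exact; this intentionally departs from inverse-square optics.
* Auto-exposure targets mean luminance 0.5 (gain clipped to [0.5, 2]) but
  never pushes the brightest pixel into saturation — cameras meter to
  protect highlights, and a blown-out well carries no color signal.
* Closure benchmarks use unquantized float renders: 8-bit rounding adds a
  ±0.5-unit floor that no calibration can undo and is not the property
  under test.
* The dye map is Beer–Lambert per channel (`base·10^(−k·conc)`) with a
  green-dominant extinction (k = 0.0002/0.0025/0.0006 per µg/mL), chosen so
  the 0–100 µg/mL ladder stays within the regime where the signal is
  nearly linear in concentration (linear R² ≈ 0.999), matching how such
  assays are designed to be read linearly.
* Cohorts: Fitzpatrick II–VI with per-stratum L* means 67/59/50/40/30
  (sd 2.5); M from a logistic link in 1/L* (range 10–75) plus measurement
  noise (sd 1.5); reflectance `10^(−M/100)`; SpO₂ a two-component mixture
  (low/cyanotic ~N(85, 4), normal ~N(97.5, 1.2)); oximeter reading
  `F = A − 0.08·(M − M_ref) + noise` (melanin-proportional
  underestimation); imaged tone an affine distortion of standard tone plus
  an ISO-dependent shift and noise; lip features linear in A; pCO₂ linear
  in three standardized latent features.  Default n = 97 samples.  All
  randomness flows through one seeded generator; generation is
  bit-reproducible.

Benchmark configurations that differ from the defaults, and why:

* The evenness benchmark scene is a 1600×1600 flat-reflectance linear ramp:
  at this size the σ = 250 surround tracks the ramp except near borders
  and μ = 0 removes ≈ 88% of the V spread.  The surround scales are pixel
  units; on small thumbnails the large scale degenerates toward a global
  mean and full flattening is impossible.
* The weight-recovery experiment sets the oximeter relation noise to zero
  (the relation being recovered is then exact) while keeping covariate
  noises at defaults — with all noise off, M is an exact function of L* and
  individual weights are unidentifiable.  It also sets the bias reference
  M_ref below the cohort minimum so the [0, 100] clip never binds inside
  the generating relation.
* Distance-closure scenes are dimmed ×0.8 when negative Δd (camera closer
  than reference) would otherwise push linear values into saturation.

What passing these benchmarks shows: the algebra and the implementations
are correct, the calibrations invert the corruptions they model, and the
correction system removes the bias structure it assumes.  What they do not
show: performance on real photographs (lens flare, demosaicing,
tone-mapping pipelines, non-planar lips), real skin optics (the
melanin–tone link here is a one-dimensional sigmoid), or clinical accuracy
— those require patient data outside this package's scope.

## Problem sizes and determinism

The shipped benchmarks use 10⁴ random colors, 360-px chip renders
(4 imaging conditions × 36 grooves), a 1600² evenness scene, 640² for the
five-point μ sweep, cohorts of 97–200 subjects (1000 for the residual
independence check), and 50-point oracle sets for SVR.  The full test suite
runs in about a minute on one CPU; `scripts/acceptance.py` in about 20 s.
Every stochastic step takes an explicit seed, and fixed seeds reproduce
fits and cohorts bit-for-bit.

## Known limitations

* The evenness correction assumes multiplicative, smooth illumination; it
  cannot correct colored (channel-dependent) lighting, which is what the
  white-balance stabilizer and the G/V ratio address instead.
* τ and γ are device/setup-dependent empirical constants; defaults match
  the calibrated values used throughout but should be refitted per camera.
* The grid detector expects one chip roughly filling the frame on a
  contrasting background; perspective distortion and multi-chip images are
  out of scope.
* The correction system is linear by declaration; interaction terms exist
  only if added to the feature set.
* 8-bit quantization bounds any pipeline's accuracy at roughly the 0.2%
  channel level; the package works in float internally and quantizes only
  at image I/O.
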