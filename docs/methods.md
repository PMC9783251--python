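# Methods

## Pipeline

`perfcolor` evaluates pseudo-coloring of myocardial perfusion SPECT slices
in three stages run in a fixed order: adaptive Wiener denoising of the gray
image, pixel-wise color mapping, and full-reference quality scoring of the
colored image against the denoised gray reference.  Denoising precedes both
sides of every comparison, so the metrics measure what the color map does to
the image, not what the noise does.

## Intensity conventions

A grayscale image carries a *declared* value range — `raw_8bit` `[0, 255]`,
`unit` `[0, 1]`, or `signed` `[−1, 1]` — and all range remapping is affine
on the declared container bounds, never on the observed per-image extremes.
Observed-extreme scaling would give the same tissue different colors in
different images, and would make the quality indices depend on unrelated
image content.  Four of the maps operate on unit intensities; the jet map
follows the convention `t = 2I/255 − 1` on `[−1, 1]`.

## Color maps

Each map is a triple of scalar transfer functions evaluated per pixel and
clamped to `[0, 1]` per channel.  Numerical specifics worth knowing:

* **Warm (WCM).**  The color is `B · (r(t)sin(ωt+φ), r(t)cos(ωt+φ), √3 t)ᵀ`
  with `B = (1/(2√3))·[[1+√3, 1−√3, 2], [1−√3, 1+√3, 2], [−2, −2, 2]]`, an
  orthonormal basis whose third column is the gray axis `(1,1,1)/√3`.  The
  chroma radius `r(t) = (√3/2)·min(t, 1−t)` is triangular.  Consequences,
  both asserted in tests: the pre-clamp channel mean equals `t` exactly
  (luminance is carried by the gray-axis coordinate alone), and the chroma
  magnitude `‖RGB − (t,t,t)‖` equals `r(t)`.  The rotation parameters
  default to `ω = −π, φ = 5π/4`, which orders the hues dark blue → magenta
  → orange → light yellow; both are exposed on `WCMParams` because other
  phase choices are equally self-consistent.
* **Hot (HCM).**  Channels are clamped ramps `clip(2.7027·t)`,
  `clip(2.7027·t − 1)`, `clip(3.8461·t − 2.8461)`.  The clamp form (rather
  than hard branches at `t = 0.37/0.74`) is deliberate: the printed slope
  constants are 4-decimal roundings of 1/0.37 and 1/0.26, so hard branches
  would be discontinuous by ~1e−6..1e−5 at the breakpoints; the ramps agree
  with the branch values away from the breakpoints and are continuous and
  monotone.
* **Zahedi (ZCM).**  Piecewise-linear; the blue channel has a
  genuine jump of 0.2 at `t = 14/15` (it sits at 1/5 on `[2/5, 14/15]` and
  restarts from 0 on the ramp `60t − 56`).  The jump is preserved as
  defined and asserted — exactly one discontinuity, magnitude 0.2.
* **Jet (JCM).**  `R = f(1.5 − 2|t−1|)`, `G = f(1.5 − 2|t|)`,
  `B = f(1.5 − 2|t+1|)` with `f` the unit clamp.  The absolute values are
  what produce the triangular blue → green → red profile; without them the
  three channels would be monotone and the map could not start at blue and
  end at red.
* Evaluation is vectorized; for 8-bit integer input an optional 256-entry
  lookup table gives the identical result (asserted at all levels).

## Denoising

Local moments use a uniform filter with symmetric (reflect) boundary
padding — zero padding would darken the borders of a 64×64 raster.  The
local variance is computed after centering on the global mean, which makes
it exact (zero) on constant images instead of ~1e−16.  The Wiener gain is
`max(σ² − ν², 0)/σ²`, defined as 0 where `σ² = 0` (there the pixel equals
its local mean, so the choice is a removable singularity).  Output pixels
therefore always lie between the input pixel and its local mean; output is
clipped to `[0, 1]`.  When `ν²` is not given it is the mean of all local
variances.  On structured images this estimate includes signal variance
and therefore over-smooths when the true noise is small; at realistic SPECT
count levels (noise power well above the structure floor in flat regions)
the filter reduces error-to-truth, and the tests assert exactly that
regime.

## Quality indices

* **MSE** divides by `3MN` (all channels); **PSNR** uses `Imax = 1` on
  unit-range data.  That peak choice is forced by internal consistency:
  `10·log₁₀(1/0.3234) = 4.9026` dB reproduces the published per-image
  MSE↔PSNR pairs for the sine, Zahedi and jet maps to the printed
  precision.  `PSNR(MSE=0)` is `+inf` by convention.
* **NCD** converts both images to CIELAB (sRGB primaries, D65 white, via
  scikit-image), the gray image after channel replication.  The default
  form is the ratio of summed squared L/a/b differences to the summed
  squared L/a/b magnitude of the colored image; a `classic` option uses
  per-pixel Euclidean roots instead (`Σ‖ΔLab‖ / Σ‖Lab‖`).  Both are
  provided because published NCD values cannot discriminate between the
  two readings without the original images; they differ numerically but
  share the properties tested (zero at identity, tiling invariance,
  nonnegativity).
* **SSIM** uses an 8×8 uniform sliding window (stride 1, no Gaussian
  weighting), population (divide-by-n) moments, constants
  `c₁ = (0.01·L)², c₂ = (0.03·L)²` with `L = 1`, computed per channel and
  averaged.  All of window size, constants and dynamic range are
  configurable on `SSIMParams`.  Only windows fully inside the image
  contribute, matching a naive double-loop oracle to 1e−10.  Note that
  against a channel-replicated gray reference the per-channel average is
  invariant to permuting the test image's channels — a symmetry, not a
  defect — so permutation sensitivity only appears between two chromatic
  images.
* **ANOVA** is the classical one-way F test across maps, computed from
  explicit sums of squares with `(k−1, N−k)` degrees of freedom; degenerate
  inputs get sentinels (`F = 0, p = 1` for identical groups; `F = inf,
  p = 0` for perfect separation with zero within-group variance).

## Synthetic phantoms

The generator emulates a short-axis left-ventricular slice: a unit
annulus (inner radius 9 px, outer 16 px on a 64×64 matrix), an optional
defect sector with fractional uptake reduction, Gaussian blur of σ = 1.5 px
standing in for collimator/reconstruction resolution, renormalized to
peak 1.  Noise is Poisson counting noise with an expected peak of 100
counts/pixel — the order observed on filtered-back-projection cardiac
SPECT — and the noisy counts are renormalized by the *expected* peak count
and clipped to `[0, 1]`.  Normalizing by the observed noisy maximum was
rejected: it multiplies the whole image by a random factor (~20–30% at
these count levels), which dominates any error-to-truth comparison with a
scale bias and even makes denoising appear harmful.

What the phantoms do **not** model: attenuation, scatter, the projection /
filtered-back-projection chain, anatomical variability, and the
signal-dependence structure of reconstructed noise (real FBP noise is
correlated; ours is pixel-independent Poisson).  Passing tests on phantoms
therefore validate the pipeline's algebra and ordering behavior, not
clinical absolute values; published corpus-level means are not reproducible
without the patient images, and the corpus tests assert report structure,
the row-wise PSNR↔MSE identity, and ANOVA significance rather than absolute
numbers.

## Problem sizes and determinism

Tests and the acceptance script use 64×64 images, corpora of 4–30
phantoms, and a 256×256 raster for the noise-power calibration check —
sizes at which every property asserted is already stable.  All randomness
flows through explicit seeds (`numpy.random.default_rng`); a pipeline rerun
with the same configuration and seed produces byte-identical CSV reports,
and the configuration is serialized into each report's header.

## Known limitations

* The warm map's rotation parameters are a convention; any `(ω, φ)` pair
  preserves the gray-axis and equal-step properties, so comparisons
  involving WCM chroma depend on that choice.
* The noise-variance estimator is biased upward by image structure; a
  flat-region or wavelet-based estimator would denoise better at high
  count levels but is out of scope.
* NCD in either form is scale-normalized by the colored image, so it is not
  symmetric and not a metric.
* DICOM input is not implemented; PNG/TIFF/`.npy` readers cover the
  supported acquisition-independent path.
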