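# Methods

## Problem setting

A simulation CT slice with anatomy outside the scanner FOV is modelled as a
complete ground-truth slice with two full-height lateral strips of columns
set to zero. The reference geometry removes 36 + 36 of 128 columns
(56.25% of the pixels). The task is to synthesize plausible tissue in the
missing strips so that (a) the image resembles the ground truth, measured
by region-restricted SSIM/RMSE/PSNR, and (b) a radiotherapy plan
recalculated on the completed slice reproduces the ground-truth dose,
measured by gamma analysis.

## Synthetic thorax phantoms

Real FOV-truncation cases are dominated by the thorax/abdomen of large
patients, and the lung is the hardest site for completion because of its
large density contrast. The generator therefore builds the minimal anatomy
that exercises that difficulty: an elliptical soft-tissue body, two
elliptical low-density lungs, one high-density spine disk, on an air
background.

Defaults (128 × 128 grid, 3 mm pixels — a 384 mm field):

| parameter | default | rationale |
| --- | --- | --- |
| body semiaxes | 170 × 110 mm, jitter ±20/±15 mm | adult thorax; widest jittered body still inside the grid, but wider than the truncated FOV |
| lung semiaxes / offsets | 45 × 70 mm at ±60 mm lateral | lungs reach into the truncated strips so completion must reconstruct low-density tissue |
| spine radius / offset | 15 mm, 75 mm posterior | a high-density landmark inside the kept region |
| gray levels | air 0, lung 30, tissue 100, bone 220 | 8-bit scale with water-like soft tissue at 100 |
| noise | additive Gaussian σ = 4, clipped to [0, 255] | mild CT-like noise; keeps outline extraction non-trivial but reliable |

One integer seed drives both geometry jitter and noise; dataset item *i* is
seeded independently from (seed, *i*) so any item can be regenerated alone.
The returned ground-truth outline is exactly the non-air support before
noise.

What the phantoms do **not** emulate: Hounsfield-accurate densities,
parenchymal texture, tumours, couches, metal, 3-D continuity. Passing the
phantom-scale tests shows the machinery is correct and that the method
ordering holds under controlled conditions; it does not certify clinical
image quality, which requires training on real CT at full scale.

## Preprocessing

Resampling uses anti-aliased bilinear interpolation for downscaling and
plain bilinear for upscaling, then re-quantizes to the slice's intensity
unit; pixel spacing rescales by the size ratio. Note that an
upscale-then-downscale round trip smears step edges by about 1/8 of the
intensity jump — an inherent property of mass-preserving kernel pairs, not
a code defect; the bulk of the image round-trips exactly.

DICOM input is converted to HU via RescaleSlope/Intercept and windowed
linearly to 8 bits. The default window [-1000, +600] HU places water
(0 HU) at gray 159; the window is a single configuration value and the
water gray code used by the fill methods is derived from it. On the
synthetic scale water sits at the phantom's tissue gray (100).

## Completion network

The generator is a 17-layer fully convolutional network: a 5×5 stem, two
stride-2 encoders (×4 downscale), a bottleneck whose four dilated 3×3
convolutions (dilation 2, 4, 8, 16) expand the receptive field to cover the
whole strip width without further downsampling, two transposed-convolution
decoders (kernel 4, stride 2) restoring the input size, and a sigmoid
output in [0, 1]. ReLU follows every other layer; there is no batch
normalization and no fully connected layer, so one set of weights serves
any input size. The input is the masked image concatenated with the binary
hole mask as a second channel.

Two discriminators score realism: a global branch (six 5×5 stride-2
convolutions + FC→1024) sees the whole slice; a local branch (five such
convolutions + FC→1024) sees the generated region. Because the holes here
are two full-height side strips rather than square patches, the local
branch consumes one full-height crop per strip — width
max(left, right, grid/4) — and the two strip features are averaged before
concatenation with the global feature; a final FC + sigmoid yields one
probability-of-real score. `base_channels` rescales every channel count
uniformly (floor 1), so the identical topology trains at CPU-friendly
widths.

The engine underneath is a compact numpy implementation (NHWC float32):
convolutions are evaluated as one BLAS matrix product per kernel tap,
which handles stride and dilation uniformly and keeps backward passes
exact; transposed convolution is the adjoint of the same operation. All
layers pass numeric finite-difference gradient checks.

## Training

Each joint iteration updates the discriminators first (separating real
slices from completed ones), then the generator with total loss

    L_G = MSE(raw, truth | missing region)  +  α · (−log D(completed)),

α = 4·10⁻⁴ and batch size 2. "Completed" images are composites: known
pixels copied from the input, missing pixels from the generator.
Discriminator loss is the min–max form −[log D(real) + log(1 − D(fake))],
with scores clamped to [1e-7, 1 − 1e-7] so saturated discriminators yield
finite losses. Training is phased — reconstruction-only (Tc), then
discriminator-only (Td), then joint — defaulting to 20% / 5% / 75% of
epochs; a pure-joint schedule (0, 0, 100%) is also supported. The optimizer
is Adam (default moments) at 1e-3, a robust choice for the tiny
configurations this package trains.

With a fixed seed and a single-threaded deterministic BLAS, reruns are
bitwise identical; otherwise reproducible in distribution only. On tiny
configurations the discriminators typically win early (their loss → 0 and
the adversarial gradient saturates); the small α keeps the L2 term
dominant, so this does not destabilize the reconstruction.

Problem sizes: the in-suite training run uses a 64 × 64 grid (6 mm pixels,
the same 384 mm field), quarter-width channels, 64 training + 8 held-out
phantoms, 60 epochs, 18 + 18-column truncation (the same 56.25% missing
fraction). That is the size at which the run demonstrates its two
contract properties — falling reconstruction loss and a ≥ 0.2 held-out
masked-region SSIM gain over the zero-filled baseline (measured gain ≈
+0.49) — while the whole test suite stays fast enough to run routinely.

## Body outline, water fill, hybrid fusion

The outline is extracted by thresholding at `tissue_threshold`,
morphological closing with a 2-pixel disk (the smallest radius that
bridges noise gaps on the fixtures), interior hole filling, and keeping
the largest connected component — yielding a single filled region. On
noiseless phantoms this equals the ground-truth outline exactly; under the
default noise its Jaccard overlap with the truth exceeds 0.98 across 100
seeds.

`tissue_threshold` defaults to the midpoint of air and lung gray (15), so
lung parenchyma counts as tissue: the hybrid step must not overwrite
generated lung with water. The fill rules on the missing region are:

* **PBO fill**: inside the outline → `water_gray`; outside → `air_gray`.
* **Hybrid**: generated tissue outside the outline is eliminated (set to
  air — leaving network values outside the body would contradict the known
  body surface); sub-threshold (air-like) pixels inside the outline are
  replaced with water; everything else keeps the network value.

Both operations are idempotent, never touch known pixels, and agree when
the network generates nothing.

## Toy arc dose and gamma analysis

The dose engine exists so the gamma comparison can be exercised; it is
deliberately simple. Attenuation is linear in gray value with water
(gray 100 on the phantom scale) at μ = 0.005/mm. For each of n equispaced
gantry angles (default 36) a parallel beam collimated to the target width
(default 20 mm diameter at 200 cGy) is traced through the slice; the local
deposit is μ × the arriving fluence exp(−Σ μℓ), and beams are summed. The
reference plan is normalized so the target-centre dose equals the
prescription; recalculating on a completed image **reuses the reference
plan's normalization factor** — the same plan applied to different
anatomy — so attenuation errors in the completed tissue show up as dose
differences. Scatter, divergence, spectral hardening and aperture
optimization are ignored.

Gamma uses global normalization: dose difference as % of the maximum
reference dose, thresholds likewise reference-based, with sub-threshold
pixels excluded from both numerator and denominator of the pass rate. The
evaluated dose is bilinearly interpolated on a fine sub-grid
(step = dta/10) and the minimum generalized distance is searched within a
radius of 3·dta — standard engineering defaults. The implementation is
vectorized over search offsets with an exact early-exit (offsets sorted by
spatial penalty); it matches an exhaustive loop-based evaluation to 1e-6
on small grids. The default report is the six-cell table {1%/1 mm,
2%/2 mm} × {1%, 10%, 50% threshold}.

At phantom scale the resulting ranking of completion methods by mean pass
rate at 1%/1 mm (10% threshold) is hybrid ≥ DL-only ≥ PBO-only: the water
fill misrepresents lung density in the strips, the network occasionally
hallucinates tissue outside the true body, and the hybrid corrects
exactly that failure mode.

## Degenerate inputs and numerical conventions

* Empty missing region: reconstruction loss defined as 0; the
  generation-only metrics report is flagged empty rather than raising.
* MSE = 0: PSNR reported as +inf with a flag, not an exception.
* SSIM is not clamped; anti-correlated inputs can yield negative values.
  Windowed SSIM uses an 11 × 11 Gaussian (σ = 1.5) window; the map is
  averaged over window centres inside the evaluation region (windows may
  straddle the region boundary), and regions smaller than the window fall
  back to global mode with a warning.
* Coordinates are row-major, 0-based, pixel centres at integer indices;
  spacing converts indices to mm.
* Per-stage seeds derive from the master seed by stable hashing of the
  stage name; all seeds stay below 2³¹.

## Known limitations

The numpy engine is single-device and unsuited to full-scale (128 × 128,
full-width, thousands-of-epochs) adversarial training; the architecture is
faithful but the published training scale is out of reach without a GPU
framework. The dose engine is not a clinical algorithm and its absolute
dose distributions should not be interpreted physically — only the
*comparison* between plans on truth vs completed images is meaningful. The
phantom generator's simplicity means image-quality numbers on phantoms are
optimistic relative to clinical CT.
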