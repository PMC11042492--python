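# Methods

## Problem setting

Specular reflections (SR) are saturated highlight artifacts in white-light
endoscopy video: light bouncing directly into the camera blows out the
sensor, erasing the underlying tissue appearance.  Because the highlight
moves with the camera/light geometry while the tissue does not, a patch
hidden in one frame is usually visible a few frames away — which is what
makes *video* restoration fundamentally stronger than single-frame
inpainting.  The package implements a three-stage system (enhance →
detect → restore), the masked-region quality metrics needed to score such
restorations, and a synthetic benchmark protocol, so the whole chain is
testable without any clinical data.

## Stage 1 — saturation-weighted enhancement

Each RGB channel is multiplied pointwise by `1 − S`, where `S` is HSV
saturation (`S = (max − min)/max`, `S = 0` when the maximum channel is 0).
Chromatic tissue is darkened; achromatic highlights (including pure white,
`S = 0`) are fixed points.  The effect is a wider gap between highlight
and tissue populations in the value-channel histogram, which makes the
fixed threshold in stage 2 far more selective.  Arithmetic is float with
round-half-away-from-zero back to 8 bits, so results are bit-reproducible;
the enhanced frame is channelwise never brighter than the input.

## Stage 2 — hybrid detection

Two detectors with complementary failure modes are fused by pixelwise
union:

* **Light U-net** — a compact encoder–decoder with 4 resolution levels
  and 8 initial filters (channels 8/16/32/64, doubling per level).  Each
  level applies two 3×3 convolutions with batch normalization and ReLU;
  2×2 max-pooling descends, 2×2 stride-2 transposed convolutions (with
  batch norm) ascend, skip connections concatenate encoder features
  before each decoder block, and a final 1×1 convolution with sigmoid
  yields a probability map (binarized at 0.5 by default).  This
  resolution of the architecture has **exactly 121,641 trainable
  parameters** (120,825 convolution weights+biases, 816 batch-norm affine
  parameters), which the tests pin both against the constant and against
  a closed-form count over layer shapes.  The network is implemented
  directly in NumPy (im2col convolutions, explicit backward passes,
  verified against finite differences); at this size it trains a
  scaled-down synthetic task in minutes on one CPU.
* **Value-channel thresholding** — `V > 194` (strict) on the *enhanced*
  frame.  Compact networks under-detect large saturated regions;
  thresholding catches them trivially.

Training uses an equal-weight sum of soft-Dice loss (computed over the
batch, which stabilizes batches with empty masks) and mean binary
cross-entropy; Adam with learning rate 0.01, β₁ = 0.9, β₂ = 0.999; a
reduce-on-plateau schedule (patience 10, factor 0.1) on the monitored
validation loss; batch size 8; at most 120 epochs (longer training
overfits).  The weights with the best validation loss are returned.
Dataset utilities provide the four-quadrant 288×384 crop augmentation
with random horizontal/vertical flips and a shuffled 80/10/10
train/validation/test split.

The fused mask is finally dilated once with a 5×5 elliptical structuring
element (pixels whose center lies in the ellipse inscribed in the 5×5
square).  Dilation deliberately trades Dice for sensitivity: the
restoration stage needs the degraded rim around each highlight covered,
not a pixel-perfect outline.  The undilated variant remains available as
a config toggle.

Why union and not intersection: the two detectors are combined precisely
because each catches what the other misses; an intersection would keep
only what both agree on and discard exactly those complementary
detections.  The quantitative ablation direction (the combination's
sensitivity exceeding either component's) is only achievable with the
union.

## Stage 3 — flow-guided restoration

The reference engine is a classical flow-propagation chain:

1. **Flow estimation.** Dense forward and backward optical flow for every
   adjacent pair via iterative Lucas–Kanade (window radius 7, 8 warp
   iterations) on grayscale frames.  Saturated regions carry no matchable
   structure and would inject large fake gradients, so before estimation
   each pair is *neutralized*: masked pixels get a diffusion prefill, and
   the target frame's masked region is overwritten with the source's so
   the estimator sees zero temporal signal there.
2. **Flow completion.** Displacements under the pair mask **dilated by
   the estimator window (radius + 2)** are replaced by the discrete
   harmonic (Laplace) extension of the surrounding flow, solved with a
   sparse direct solver.  Harmonic interpolation reproduces affine flow
   fields exactly, which is the right prior for smooth camera motion over
   a hole; the dilation removes the rim the estimator window could still
   have contaminated.
3. **Pixel propagation.** Every masked pixel chains completed flows
   backward and forward in time, one frame per step, until the landing
   position falls outside the donor frame's mask (bilinearly sampled mask
   value ≤ 10⁻³).  The nearest donor in time wins; on a tie the earlier
   frame is preferred (deterministic).  Chains leaving the field of view
   die.  Sampling positions within 0.05 px of the integer grid are
   snapped onto it, so essentially-integer displacements copy donor
   values exactly instead of blurring them through interpolation — this
   is what makes recovery on static or integer-translation sequences
   bit-exact.
4. **Residual fill.** Pixels no chain can reach are filled by the same
   harmonic solver applied per channel within their own frame.

Contract for every engine: output dimensions equal input dimensions, and
pixels outside the masks are bit-identical to the input.

**Baselines.** `diffusion-inpaint` applies step 4 alone per frame (the
single-frame stand-in).  `homography-replace` estimates a per-pair
projective transform from single-scale ORB keypoint matches outside the
masks (RANSAC, residual 1 px, with a plausibility guard rejecting
contorted fits — adjacent frames are near-affine) and copies raw donor
pixels into the mask with **no photometric adjustment**; it exists to
reproduce the lighting-inconsistency failure mode that motivates
flow-guided restoration.  `identity` returns the corrupted input (the
unrestored baseline), and `external-command` shells out to any
drop-in engine via a `{frames}/{masks}/{out}` template, which is where
heavyweight learned video-completion models would plug in; they are not
re-implemented here.

## Metrics

* Dice, IoU and sensitivity from pixel confusion counts.  Conventions:
  both masks empty → all three are 1; reference empty but prediction not
  → sensitivity is undefined and reported as NaN.
* **mPSNR**: squared error gated by the binary mask weight, averaged over
  the `S` mask pixels and `C` channels —
  `mMSE = (1/C)(1/S) Σ (I−K)² w`, `mPSNR = 10 log₁₀(MAX²/mMSE)`.  The
  alternative reading `20 log(MAX/mMSE)` is dimensionally inconsistent
  with PSNR; the adopted form reduces *exactly* to textbook PSNR when the
  mask covers the frame (asserted to 10⁻⁹).  A perfect restoration
  returns an infinite sentinel; aggregation excludes infinities from
  means and reports their count.
* **mSSIM**: connected components of the mask (8-connected by default)
  are boxed; each box side is grown symmetrically to at least 8 px
  (border deficits pushed to the opposite side) so a 7×7 SSIM window
  fits; SSIM per box uses a uniform 7×7 window, K₁ = 0.01 / K₂ = 0.03,
  data range = MAX, mean over RGB channels; box scores are averaged with
  weights proportional to the mask pixel count inside each (expanded)
  box, normalized to sum to one.
* Full-frame PSNR/SSIM are included for contrast; on the benchmark they
  barely separate engines, which is the reason the masked variants exist.

## Synthetic fixtures

`fixtures` generates everything the tests and benchmark need:

* **Tissue sequences** — a panoramic canvas of a tissue-toned base color
  (default RGB (168, 82, 72)) with low-frequency shading, mid-frequency
  texture and slight chromatic variation, overlaid with vessel-like
  random cubic Bézier curves darkened by 30–50% (soft-edged so flow and
  keypoints can lock onto them).  Motion models: `static`; `translation`
  (horizontal pan of `round(t·magnitude)` px, so integer magnitudes give
  exact integer shifts before noise); `homography` (pan composed with a
  slowly accumulating small projective drift).  Per-frame Gaussian sensor
  noise (default σ = 2) is added last.  Every generator is a pure
  function of its config and seed.
* **SR artifacts** — irregular elliptical blobs in three size classes
  (small/medium/large, radii 2–16 px), redrawn per frame.  Core pixels
  become achromatic at `core_intensity` (≥ 195, so every synthetic core
  exceeds the 194 threshold — the thresholding stage is a guaranteed
  sensitivity floor on fixtures); a halo of configurable width blends
  surrounding pixels toward the core color, raising value and lowering
  saturation with distance.  The ground-truth mask marks cores only.
* **Mask library** — 200 random highlight-shaped masks at 288×384,
  sampled without replacement and nearest-neighbor-resized for overlay
  trials; an explicit exclusion mask clips sampled masks away from
  pre-existing highlights.

What the fixtures do **not** emulate: real tissue reflectance and
pathology, depth-dependent lighting, motion blur, rolling shutter, or the
annotation noise of human-labeled masks.  Passing tests therefore show
that the algorithms satisfy their contracts under controlled geometry and
noise — not that clinical detection scores would match.

## Benchmark protocol

One trial is a 100-frame window: frames 1–50 are clean warm-up (donor
content for temporal engines), frames 51–100 each receive one of 50 masks
sampled without replacement from the library, painted as a saturated
overlay confined to the mask.  The restorer sees the full corrupted
window; mPSNR/mSSIM/PSNR/SSIM are scored on assessment frames against the
clean ground truth.  A benchmark runs 13 trials per engine on temporally
disjoint windows with independent mask draws; every engine sees identical
corrupted inputs per trial.  Engines are compared by two-tailed
two-sample t-tests on the 13 per-trial metric means (pooled variance by
default, Welch by flag; two zero-variance samples with equal means return
t = 0, p = 1).

Problem sizes: benchmark frames are 96×128 (the protocol's frame counts,
warm-up split, mask counts and trial count are fixed; spatial resolution
is not a protocol parameter, and the classical engines are
resolution-agnostic).  The scaled-down training sanity run uses fifty
64×64 synthetic pairs.

## Numerical choices and degenerate inputs

* Harmonic fills use a 5-point Laplacian with Dirichlet boundaries and
  Neumann behavior at image borders; a full-frame mask raises (no
  boundary data).
* All-black frames produce empty masks at every detection stage; empty
  masks make every restorer the identity.
* Empty-mask mPSNR/mSSIM raise rather than return a sentinel.
* U-net inputs are reflect-padded to multiples of `2^(depth−1)` for
  inference and cropped back.
* Max-pool backward routes gradients to a single argmax winner, so tied
  activations never duplicate gradient mass.

## Known limitations

* Iterative Lucas–Kanade flow is local; on large untextured regions the
  flow is ill-determined, and long chains (tens of frames) accumulate
  drift — visible as a few intensity units of error in propagated fills
  on moving sequences.
* The homography baseline needs enough matchable texture outside the
  masks; when matching fails it logs a warning and falls back to
  diffusion fill.
* Training the NumPy network is practical at fixture scale; it is not a
  GPU training framework and does not try to be.
* The benchmark's significance claims concern the synthetic conditions
  above; they transfer to real endoscopy only in direction, not in
  magnitude.
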