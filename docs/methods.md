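# Methods

## The pipeline

`octavg` implements the standard en-face OCT-angiography averaging analysis:
five sequential acquisitions of the same retinal slab are aligned to the
first acquisition, averaged pixel-wise, and the averaged image is compared
with the first single acquisition to quantify what averaging adds (pixel
*gain*) and removes (pixel *loss*).  Alongside, the repeatability of
automatic vessel-density (VD) measurements across the five acquisitions is
summarised with intraclass correlation coefficients.

### Registration

Alignment runs in two stages, mirroring the classic StackReg → bUnwarpJ
chain used in en-face averaging work, but as native computation:

1. **Similarity stage.**  Per non-reference frame, a
   translation + rotation + uniform-scale transform (no shear) minimising
   the mean squared intensity difference to the reference over a 3-level
   Gaussian pyramid.  Initialisation combines phase correlation (for
   translation) with a coarse-level rotation sweep over ±9° in 1.5° steps;
   beyond about ±3° the capillary texture decorrelates and a
   translation-only start strands a local optimiser, so the sweep sets the
   capture range.  Refinement is Powell's method with fixed iteration caps;
   the whole stage is deterministic.  A frame whose optimised transform
   does not beat the identity on MSE keeps the identity, so registration
   can never worsen a frame.  Sanity bounds (|scale−1| ≤ 0.2, |θ| ≤ 20°,
   shift ≤ 0.45 of the raster) convert divergence into a
   `RegistrationError` naming the frame.

2. **Elastic stage.**  The residual smooth warp (ocular curvature, scan
   distortion) is estimated from iterative Lucas–Kanade optical flow
   between the reference and the linearly aligned frame, then projected
   onto a cubic B-spline control grid (default spacing 32 px) by
   confidence-weighted penalised least squares.  The confidence weight is
   the *smaller* eigenvalue of the local structure tensor — high only where
   texture constrains both flow components; along a straight vessel edge
   the tangential component is unconstrained (aperture problem) and plain
   gradient magnitude would give garbage high confidence.  Rows whose
   median inter-frame difference is grossly elevated (a motion-stripe
   artifact present in only one frame) are excluded, as is a margin where
   the flow window straddles the raster edge or invalid border fill.  The
   penalty is a discrete bending energy (second differences of the control
   grid, weight `lam`, default 0.1) plus a mild first-difference term and a
   ridge so unsupported border nodes decay to zero instead of extrapolating
   as ramps; as `lam → ∞` the whole field shrinks monotonically to zero.
   One reweighting pass discards flow estimates far (> 3 robust SDs) from
   the first fitted surface — low-texture pockets can produce wildly wrong
   local flow.  A fitted field exceeding the displacement bound (default
   15 px) raises `RegistrationError`; a field that does not reduce the MSE
   is replaced by the zero field.

The final registered frame is resampled **once** from the original
acquisition through the composed mapping `T(p + D(p))` with bilinear
interpolation; pixels mapping outside the source raster are flagged
invalid and set to 0.  The reference frame is returned bit-exact.  On
synthetic stacks with known geometry the composed alignment error is
typically 0.1–0.3 px (mean over the joint validity mask).

### Averaging

Plain per-pixel arithmetic mean over all frames, accumulated in floating
point with a single final rounding (half away from zero) to 8 bits.
Invalid-filled zeros participate by default, mirroring a plain
average-intensity Z-projection; `exclude_invalid=True` averages only
frames with real data per pixel.  The stack's joint validity mask is
carried on the result so downstream counting can ignore border fill.

### Gain/loss analysis

With A the averaged and S the first single image (the registration
reference, hence already in the same frame):
`gain = max(A − S, 0)`, `loss = max(S − A, 0)`, binarized at the
vessel/background grey-level limit of the slab — 40 for the superficial
plexus and full-retina slab, 60 for the deep complex, whose background is
brighter.  The boundary value itself counts as foreground.  Masks are
scored on a 3 × 3 grid of 172 × 172-px boxes (the native 516 × 516 raster);
a box is flagged when it holds at least `min_pixels` (default 50)
suprathreshold pixels — a small connected-area floor standing in for an
expert's presence/absence judgement, so isolated noise pixels cannot flip
a box.  Counts are restricted to the averaging validity mask.

Ground-truth-based surrogate grading (synthetic data only):

* **Gain**: suprathreshold gain pixels intersected with the true vessel
  mask — separates capillary gain (an intermittently perfused segment
  restored by averaging) from background-noise gain.
* **Loss of detection**: suprathreshold loss pixels on *consistently
  perfused* vessel support where the averaged image has additionally
  fallen below the detection grey level.  Resampling slightly attenuates
  thin vessels, producing suprathreshold S−A values on vessels that are
  still plainly visible; an expert would not call that a loss of
  detection, and neither does the surrogate.

### Vessel density

`VD = vessel pixels / total pixels` after automatic histogram
thresholding (Otsu default; IsoData offered because ImageJ's default
auto-threshold is an IsoData variant and the source chain does not name
the method).  The returned threshold is the smallest intensity classified
as vessel, so binarization is uniformly `pixels >= threshold`.  VD is
reported both as a fraction and as pixels per grading box.  Constant
images raise a degenerate-histogram error.

### Repeatability statistics

ICC(2,1) — two-way random effects, absolute agreement, single measurement
— from the ANOVA mean squares, with the F-distribution 95% CI
(Satterthwaite degrees of freedom).  Acquisitions are exchangeable
"raters"; absolute agreement is the question being asked of repeated VD
measurements.  Supporting tests: Spearman rank correlation, Welch's
t-test by default for unpaired comparisons (paired t for paired), raw
p-values with no multiplicity adjustment, and inter-grader agreement as
Pearson r on the 0/1 grades plus the exact agreement fraction (r is
reported absent when a grader is constant).  Stratified summaries report
both mean and median ICC.

## The synthetic angiogram generator

No real OCTA exports are available for testing, so `synthetic` renders
acquisition stacks with known ground truth:

* **Geometry** — branching trunk trees (recursive midpoint-displacement
  branches tapering from 4 px to 1 px) plus a random capillary mesh of
  short strokes drawn until the target pixel fraction is met.  Stroke
  length is proportional to the raster side (capillary segment length is
  fixed in retinal mm), so phantoms are geometrically self-similar across
  image sizes.  The DVC style uses a denser, finer (1-px) mesh and no
  trunks.
* **Per-acquisition effects** — rigid jitter (translation/rotation/scale;
  acquisition 1 always carries identity geometry so recovery is assessable
  against absolute ground truth), a smooth elastic warp (sum of six
  Gaussian bumps, amplitude ≈ `elastic_amp`, length scale
  `elastic_scale`), additive Gaussian noise, bright full-width motion
  stripes (Poisson-count rows, drawn after the geometric warp because
  scan-line artifacts live in the acquired frame), per-segment perfusion
  dropout (`dropout_rate`), a multiplicative signal factor, and a focus /
  motion blur of the clean signal (`blur_jitter_sd`) applied before noise.
  Intensities are clamped to [0, 255] once, after all effects.
* **Oedema eyes** — dark cystoid ellipses multiplying local intensity by
  0.2–0.5, globally attenuated vessel signal (intensity 150 vs 180,
  intraretinal fluid), larger jitter, more stripes, stronger blur jitter
  and more dropout: the fixation-instability bundle.
* **Determinism** — every quantity is drawn from a fixed per-acquisition
  substream of the master seed, so any single acquisition is reproducible
  in isolation.
* **Quality index** — a Signal-Strength-Index surrogate in [0, 100]: the
  spread between the 95th and 25th intensity percentiles relative to full
  scale, discounted by a robust noise estimate (scaled MAD of the
  high-pass residual over background pixels).  The 95th rather than a more
  extreme percentile keeps stripe rows from inflating the score; the
  background restriction keeps vessel texture from inflating the noise
  estimate.

### Default study conditions

516-px rasters (172-px grading boxes); vessels at 180 over background 20
so the 40/60 difference thresholds are meaningful; noise SD 15; jitter
SDs 4 px / 2° / 1% scale; elastic amplitude 4 px at scale 64 px; dropout
0.15; healthy-SVP preset noise 10, healthy-DVC noise 18.  Cohorts built
with `cohort_specs` additionally draw each eye's true capillary density
from a normal spread (SD 0.04) around the preset — real eyes differ in
vessel density, and without between-eye variance the ICC analysis is
degenerate by construction.

### What the phantom does and does not show

Passing tests demonstrate that the *pipeline* behaves correctly on images
with known truth: sub-pixel registration recovery, the 1/√N noise law,
exact difference-map algebra, restoration of intermittently perfused
capillaries without erasure of persistent vessels, and an ICC analysis
that recovers designed repeatability differences.  They do not certify
performance on real OCTA data: the phantom has no projection artifacts,
no physically realistic speckle statistics, no vendor segmentation errors,
and its noise model is Gaussian.  One known qualitative gap: the positive
SSI–VD correlation reported for the device's proprietary VD algorithm is
not reproduced, because fully adaptive Otsu binarization is invariant to
global signal scaling (a property this package asserts and tests) and
focus blur *widens* the supra-threshold support of thin bright lines.
The quality index and VD therefore decouple in the phantom;
`repeatability_report` still computes the correlation for real data.

## Problem sizes used in the automated analyses

Registration-recovery suites run 20 stacks at side 258 (the recovery
tolerances are absolute, in pixels and degrees); the gain/loss cohort runs
20 eyes at the native 516 raster with the default box grid; ICC-ordering
cohorts run 4 strata × 10 eyes (the study's own per-group size) at side
172 over 20 seeds, with VD measured on non-averaged images (no
registration needed, matching how the repeatability analysis is defined);
ICC parameter recovery uses 200 replicates of 50 × 5 matrices at true
ρ ∈ {0.3, 0.6, 0.9}.  `scripts/acceptance.py` runs a 6-eye full-raster
averaging cohort and a 4 × 10-eye repeatability cohort.

## Numerical choices and degenerate inputs

* Rounding of averaged pixels: half away from zero, documented and tested.
* Binarize convention: foreground = value ≥ threshold everywhere.
* Auto-threshold returns the first vessel bin, so the ≥ convention
  recovers a noiseless two-level phantom's mask exactly.
* Crop policy: removing a corner logo removes the full horizontal band of
  rows at that corner's vertical extreme, keeping the raster rectangular;
  synthetic images carry no logo (default side 0).
* Constant images: quality index 0; auto-thresholding raises; Spearman and
  ICC raise on zero variance; paired t on identical samples returns
  (t = 0, p = 1), on an exact shift (±∞, 0).
* Images are 8-bit throughout; deeper rasters are linearly rescaled so
  their maximum maps to 255 at load; RGB is converted to luminance.
* JPEG is accepted on input; all pipeline outputs are PNG.
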