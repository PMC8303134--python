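# Methods

## Angle geometry

All coordinates are raster-frame: x rightward, y downward, 0-based,
sub-pixel. Five landmarks define three lines:

* baseline: proximal check point → tri-radiate cartilage point (the distal
  check point and the tri-radiate point coincide);
* bony roof line: lower edge of the ilium → acetabular bone edge;
* cartilage roof line: bone edge → labrum tip.

α and β are the unsigned minimal angles between the baseline and the two
roof lines, computed as arccos of the absolute normalized dot product and
therefore confined to [0, 90]°. The check angle is *signed*: the angle of
the (proximal → distal) wing direction from the image vertical, positive
when the distal end tilts toward +x, range (−90, 90] with an exactly
horizontal wing mapped to +90. The reference axis is the image vertical
because the standard plane is acquired vertically oriented; the
appropriateness gate uses |check| ≤ 5° (boundary inclusive), so the sign
convention does not affect gating. The Graf call is dichotomous: normal iff
α ≥ 60°, boundary inclusive, following the type-I definition (subtype
classification from β is out of scope). Angles are reported to 3 decimals.

## Phantom generator

`PhantomSpec` fixes the target angles (0 < α, β < 90; |check| ≤ 30), image
size (≥ 64 px), bone/soft-tissue gray levels, speckle scale, a global
brightness factor in [0.75, 1.00] (the brightness-variation range used for
training augmentation), and a seed. Landmark layout is the closed-form
inverse of the geometry: unit vectors u (along the baseline, distal),
n (lateral), w = cos α·(−u) + sin α·n and z = cos β·(−u) + sin β·n are the
roof directions, so the recomputed angles equal the requested ones to
~1e−13°. The lower-ilium point is offset a few pixels laterally off the
baseline along n; since the roof line leaves it parallel to w, this leaves
α untouched while keeping the rasterized structures pairwise separated by
an echo-dropout gap of ~3 px, which is what lets a connected-component
detector see three distinct structures. Structure shapes: the ilium is a
thick band centered on the baseline segment; the acetabular roof a thinner
band from the lower-ilium point to the bone edge; the labrum an ellipse
whose distal major-axis tip is the labrum landmark.

Rendering: background at `soft_intensity`, structures at `bone_intensity`,
the whole scene scaled by the brightness factor, multiplied by mean-one
log-normal speckle exp(N(−σ²/2, σ²)) and perturbed by additive Gaussian
noise with SD 4σ gray levels — a standard first-order speckle surrogate,
not a wave-propagation model. With σ = 0 and brightness 1 the rendering is
exact (every mask pixel equals `bone_intensity`), which gives the
zero-noise oracles their bit-level ground truth. Default σ = 0.25 was
chosen once as visibly grainy but not structure-destroying; the default
image is 256×256, large enough that 1 px of landmark error costs well
under a degree.

Cohorts sample per-image true angles from truncated normals defaulting to
the screening population summary (α 64.117 ± 7.12°, β 40.679 ± 8.71°,
check 0 ± 4°), then add independent per-rater Gaussian reading noise to
every angle. The per-rater SD defaults to 4.5/√2 ≈ 3.18° so the AI−human
*difference* SD is ≈ 4.5°, the inter-observer variability that population
shows; a `detect_failure_rate` flags a random fraction of readings per
rater undetectable. What the phantoms do **not** emulate: anatomical shape
variation, probe pressure and orientation effects, attenuation and
shadowing, femoral-head structures, or any correlation between image
quality and detectability — so passing tests demonstrate the pipeline's
correctness and calibration, not clinical-grade detection difficulty.

## Classical detector

Stage 1 thresholds the image and assigns connected components to
structures; stage 2 extracts the five keypoints. The threshold is
max(intensity quantile, Otsu): the quantile (default 0.85) encodes the
expected small bright-bone fraction, while the Otsu floor prevents the
quantile from promoting 15% of a speckled background to foreground and
makes the operator idempotent on its own binary white-on-black output
(smoothing — a σ = 1 Gaussian — is skipped for binary inputs, which carry
no speckle). Components under 40 px are treated as speckle. Assignment is
geometric: the longest component whose principal axis lies within 50° of
vertical is the ilium; the remaining component nearest the ilium's distal
axis endpoint is the acetabular roof; of the rest, the component nearest
the roof's lateral (bony-rim) endpoint is the labrum. Per-structure
confidence is the Michelson contrast (m − b)/(m + b) of component mean m
against background mean b, which cancels the global brightness factor.

Keypoints: band endpoints are centroids of the pixels whose principal-axis
projection lies within 1.5 px of the extreme (the sub-pixel refinement);
the roof endpoint nearer the ilium axis line is the lower-ilium point, the
farther one the bone edge; the labrum tip is the extreme-projection
centroid along the bone-edge → labrum-centroid direction, which recovers
the ellipse's distal tip accurately at every β (the naive
"farthest-from-baseline pixel" picks a tangent point and can err by >2°).
An image is detectable iff all three structures segment with confidence
≥ 0.5 and all five keypoints extract; failures are encoded in the result,
never raised. On noise-free phantoms spanning α 40–80° the detector's
landmark error is ≤ ~1.6 px and angle errors stay below 2° (mean ~0.3°);
detectability is 100% at the default speckle and degrades monotonically as
speckle grows.

## Trainable detector

The two-stage training protocol is implemented with deliberately small
fully-convolutional networks written directly in numpy (im2col + manual
backprop): a 5×5-conv → ReLU(16) → 1×1-conv sigmoid pixel classifier maps
the image to the white-on-black structure composite, and a 9×9-conv →
ReLU(16) → 1×1-conv linear head regresses five keypoint heatmaps
(Gaussian targets, σ = 2.5 px) from the *predicted* stage-1 output, so the
secondary training consumes the first training's resulting images as the
protocol prescribes. Optimization follows the protocol's settings —
SGD, learning rate 0.01, weight decay 1e−4, batch size 10, validation
every `validation_interval` steps with best-checkpoint selection, and
augmentation sampled per step within the stated ranges (shift ±5%, scale
80–100%, rotation ±15°, brightness 75–100%, optional additive Gaussian
noise). Momentum 0.9, class-balanced cross-entropy for stage 1 and
peak-weighted (1 + 50·target) MSE for stage 2 are this implementation's
choices where the protocol is silent; without them the imbalanced
pixel-classification problem (~7% foreground) barely moves in a few
hundred steps. Keypoints are decoded by per-channel argmax with 3×3
positive-mass centroid refinement; per-structure masks for the
`DetectionResult` contract are recovered from the thresholded stage-1
output with the classical assignment rules, making the two detectors
drop-in interchangeable. Training is exactly reproducible from the config
seed. The full-scale configuration (40,000 steps, validation every 1,000)
is representable but the packaged demonstrations run toy scale
(200–500 steps, 64×64 phantoms, cohorts of 16–40), where trained held-out
landmark error reliably falls to roughly half the untrained baseline;
no clinical performance is claimed for this stage.

## Gating and tables

Triage is a strict partition: *fail detection* if either rater is
undetectable; else *appropriate* iff both raters pass the |check| ≤ 5°
gate; else *inappropriate check angle*. The detectability table counts
per-rater and joint detectability with percentages of cohort size to one
decimal; the check table cross-tabulates the two raters' gates over the
commonly-detectable subset (undetectable input is a validation error) and
reports AI-gate percentages within each human-gate column. Boundary
reading: "within ±5°" is inclusive, so |check| = 5.0 gates OK.

## Agreement statistics

Percent agreement 100(a+d)/n; positive percent agreement 2a/(2a+b+c);
Cohen's κ = (p_o − p_e)/(1 − p_e) with the marginal-product chance term and
a large-sample CI from SE = √(p_o(1−p_o)/n)/(1−p_e). The ICC is the
two-way random-effects, absolute-agreement, single-measurement form
ICC(A,1) = (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n), chosen because
two raters independently measure the same images and a systematic offset
between them should count against agreement; its 95% CI follows McGraw &
Wong's Satterthwaite-df F construction (the implementation agrees with
pingouin's ICC(A,1) row to machine precision). Interpretation uses the
Cicchetti bands: <0.40 poor, 0.40–0.59 fair, 0.60–0.74 good, ≥0.75
excellent — note 0.743 reads *good* and 0.764 *excellent*. Paired
summaries use ai − human differences: MAD is the mean absolute difference
(mean-based, not median), the SD uses ddof = 1, the <5° fraction is strict
("less than"), and 60° concordance classifies each side with the inclusive
boundary. Degenerate inputs (empty tables, constant measurements, <3
pairs) raise validation errors rather than returning NaN.

## Synthetic reference cohort

The clinical per-image measurements behind the published screening tables
are unavailable, so `grafscreen.datasets.synthetic_reference_cohort`
constructs a 921-image paired-reading cohort whose *categorical* structure
is exact by construction — detectability margins 542/555/512 and
check-angle table (320, 49, 49, 94) — while the continuous angles are
simulated from a shared-subject-effect model tuned to the published
population summary (difference SD ≈ 4.5°). Statistics derived from the
categorical structure (percent agreement 80.9%, κ 0.525, positive
agreement 0.87, column percentages 86.7/65.7, appropriate fraction 34.7%)
are therefore exact recomputations; continuous-agreement numbers (ICC,
MAD, <5° fraction, concordance) are properties of the simulation and only
land *near* the published clinical values. Everything is deterministic
given the seed.

## Numerical and design notes

* Degenerate lines (coincident points) raise errors; arccos arguments are
  clipped to [0, 1]; the horizontal-wing check angle maps to +90 by
  convention.
* Component ties in the detector resolve by the stated geometric rules in
  order (elongation, then proximity); there is no randomization anywhere in
  the classical path.
* The κ confidence interval uses the simple asymptotic SE; exact or
  bootstrap intervals are out of scope.
* DICOM conversion window-levels with WindowCenter/Width when present,
  else maps the nominal stored-bit range (so 8-bit data pass through
  bit-identically), and writes a sidecar restricted to technical tags with
  a conservative PHI keyword blocklist. Annotation XML uses the CVAT
  "images 1.1" dialect with 0-based sub-pixel coordinates, round-tripping
  to 1e−3 px.
* Test problem sizes (100-phantom sweeps, 50-image cohorts, 2000-pair ICC
  recovery, 120–500-step training runs) were chosen as the smallest scales
  at which the checked properties are stable.

## Known limitations

Phantom realism is geometric, not acoustic; detector thresholds are tuned
to the phantom contrast regime and would need re-tuning for clinical
images; the trainable stage is a protocol demonstration, not a clinical
model; and the reference cohort's continuous angle values are simulation,
so ICC/MAD-type numbers computed from it characterize the simulator, not
any clinical population.
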