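# Methods

`fazkit` measures the area of the foveal avascular zone (FAZ) on 3×3 mm
en-face OCTA angiograms with two semiautomated methods, corrects the areas
for ocular magnification, and compares the methods statistically. This
note records the models, the numerical choices, and what the synthetic
test bed does and does not establish.

## The script (morphological) pipeline

The deterministic path is an ImageJ-macro-style pipeline, run stage by
stage on 8-bit images throughout:

1. **8-bit conversion.** 16-bit exports are min–max scaled over their
   occupied range (device display-range state is not recorded in exports,
   so occupied-range scaling is the reproducible choice); a constant
   image maps to 0. Color inputs use the Rec. 601 luminance weights.
2. **Crop** of the rectangle (x=127, y=127, 512×512) — the foveal field
   of the export. Sources must be at least 639×639.
3. **Downscale to 270×270.** Resampling is separable: axes being reduced
   are *area-averaged* (each output pixel integrates its exact source
   footprint — the "average when downsizing" behaviour), axes being
   enlarged are bilinearly interpolated with pixel-center alignment.
   Every stage rounds half-up back to 8-bit.
4. **Otsu binarization**, vessels ("white") as foreground: the threshold
   maximizes between-class variance of the 256-bin histogram; pixels
   strictly above it are foreground. Ties take the lowest threshold; a
   constant image is flagged degenerate (no FAZ is defined).
5. **Skeletonization** (Zhang–Suen iterative thinning, via
   scikit-image). Exact pixel parity with other thinning-table
   implementations is *not* promised; the subsequent 8-dilate/4-erode
   makes the measured area insensitive to 1-px skeleton differences,
   which the suite asserts (<2% area change under an extra thinning
   pass).
6. **Dilate ×8, erode ×4** with the full 3×3 structuring element
   (maximum/minimum filter; windows are clipped at the image border, so
   the border neither grows nor erodes the mask). The net 4-px closing
   margin at the working scale (≈7.6 px at the 512 scale) is what closes
   the perifoveal capillary ring across gaps left by weak terminal-loop
   flow signal.
7. **Upscale back to 512×512** (bilinear), then **wand flood-fill** from
   (255, 255) at tolerance 0. The flood is 4-connected by default: an
   8-connected flood can leak through diagonal single-pixel gaps in the
   dilated vessel wall (a config switch restores 8-connectivity). With
   tolerance 0 on the upscaled gray image, boundary gradient pixels are
   excluded from the region; a config switch instead thresholds at 128
   before the wand.
8. **Seed rescue.** If (255, 255) lands on a vessel-valued pixel
   (≥128), the nearest pixel below 128 within 10 px (Euclidean, ties by
   scan order) re-seeds the wand and a warning is recorded; if none
   exists the scan fails with a seed-failure error rather than returning
   a bogus region.

The pipeline is a pure function: identical inputs give bit-identical
masks.

## The texture-classifier pipeline

The trainable path emulates an interactive trainable-segmentation workflow.
Each pixel of the 512×512 crop is described by 21 features: raw intensity
plus mean, median, population variance, and Shannon entropy (base 2, of
the 256-bin window histogram) over square windows of radius
r ∈ {1, 2, 4, 8, 16}, with edge replication so every window has full
(2r+1)² support. The dyadic radius ladder follows the default scale ladders of
interactive trainable-segmentation tools; it is config-exposed. Features are computed
exactly — integer integral images for means/variances, per-intensity
integral histograms for medians/entropies — and the suite checks them
against a naive per-window loop at 1e-9.

The classifier is a 100-tree random forest with a fixed seed (the
conventional default for interactive pixel classification). It is trained from a few labelled
polylines — strokes over vascular mesh and strokes inside the avascular
zone — rasterized with Bresenham's algorithm; a pixel carrying both labels
is an error. Training is deterministic given the seed. The resubstitution
accuracy must be ≥0.95; the *out-of-bag* accuracy drives the sanity
warning, because a full-depth forest reproduces even permuted training
labels perfectly, so resubstitution cannot detect inconsistent
annotations.

A saved model embeds its feature recipe, frame size, seed, and training
provenance; loading verifies the recipe and application never mutates the
model (asserted by fingerprint). The FAZ is extracted from the avascular
probability map (p ≥ 0.5) as the largest 4-connected avascular component
intersecting a 10-px disc around the image center — taking the largest
nearby component rather than literally the component under the center
pixel makes the extraction robust to speckle-sized avascular fragments
sitting exactly on the seed. Interior holes under 50 px
(capillary-dropout speckle) are filled; the threshold is config-exposed.

## Magnification correction

The nominal scale is 3 mm / 510 px ≈ 5.88 µm/px. For an eye of axial
length AL, the corrected scale multiplies the nominal scale by
AL / 23.95 mm (the plain axial-length ratio; 23.95 mm is the reference
eye assumed by the device). Areas use the squared corrected scale, so
area scales exactly as (AL/23.95)². Axial lengths outside (15, 40) mm are
rejected as data errors. The full Littmann–Bennett q-ratio
(q = 0.01306·(AL − 1.82)) is available behind a config flag for
sensitivity analyses; the plain ratio is the operational default. The
printed 510-px span (versus the 512-px acquisition grid) is kept as the
default and is configurable.

## Statistics

*Agreement* (per plexus, visits pooled, scans paired by subject/eye/visit):
Pearson r with the Fisher-z interval tanh(atanh r ± z₀.₉₇₅/√(n−3)) and p
from the exact t reference distribution (n−2 df); Bland–Altman bias
(mean of script − classifier differences) with 95% limits of agreement
bias ± 1.96·sd (sample sd, the conventional normal-quantile multiplier),
flagging pairs outside the limits.

*Longitudinal* (per plexus × method): classic repeated-measures ANOVA —
the additive subject + visit fixed-effects decomposition on complete
cases (eyes with all four visits; incomplete eyes are dropped and
counted). F for visit has df1 = k−1, df2 = (n−1)(k−1). All six visit
pairs are then compared with Tukey's studentized-range adjustment,
q = |mᵢ − mⱼ| / √(MS_error/n), with the adjusted p from the
studentized-range distribution (SciPy's implementation of the double
integral). For k = 2 this reduces exactly to the two-sided paired t-test
(q² = 2t²), which the suite checks numerically. A subject-random-intercept
mixed model would be the natural extension but is out of scope for the
core; with complete balanced data the F test is the same.

Calibration is verified by simulation: Fisher-z 95% CI coverage within
[93%, 97%] under bivariate normality (n=50, ρ=0.8), and Tukey familywise
type-I error within [3%, 7%] under the repeated-measures null.

## The synthetic test bed

Clinical OCTA exports carry no ground truth, so all recovery claims rest
on a generator whose FAZ is known exactly.

A synthetic angiogram is built in a 768×768 source frame (so the crop
stage runs as in production): a star-convex boundary
r(θ) = r₀(1 + a·s(θ)) with s a low-order random-phase harmonic sum
(normalized so a is the peak radial perturbation; default 0.15), with r₀
solved so the rasterized interior hits the requested area (±2%; default
0.49 mm², the baseline superficial-plexus mean) under the
magnification-corrected scale. Vessels are biased random walks: a
background capillary mesh (density scaled to ≈30–35% binarized vessel
fraction, the range reported for en-face OCTA vessel density) plus ring
capillaries seeded on an annulus and biased inward, one per ≈7 px of
boundary circumference, terminating at the boundary. The interior is
strictly vessel-free — that interior *is* the ground truth.

Two physically motivated degradations matter most:

* **Flow-signal falloff** (default 12 px): terminal capillary loops carry
  slow flow, so their decorrelation signal ramps up smoothly over a band
  just outside the anatomic boundary. This is why binarized angiograms
  show a dark zone slightly larger than the true avascular area — and it
  is precisely what the macro's net dilate–erode margin was designed to
  compensate. Roughly half the band survives Otsu binarization, which the
  ≈7.6-px net closing margin of the script pipeline then cancels; the
  default falloff width follows from that forward calculation, not from
  fitting to any test outcome.
* **Speckle**: multiplicative log-normal noise (σ = 0.3) after a 1-px
  Gaussian blur, then 8-bit quantization.

Cohorts draw one eye per subject: axial length ~ N(23.79, 1.7²) mm
truncated to (21, 26) mm (high myopes excluded), a per-plexus between-eye
effect, per-visit means following the default trajectories
(SVP 0.49→0.45→0.41→0.41; IVP 0.15→0.14→0.14→0.17;
DVP 0.41→0.39→0.37→0.38 mm²), and within-eye visit noise
(sd 0.06 mm², consistent with published FAZ test–retest repeatability).
Between-eye sds (0.20/0.10/0.18 mm²) are set so the total cross-sectional
spread matches the trajectory-table sds. True areas are floored at
0.02 mm². All randomness flows from the single spec seed; identical
seeds give identical bytes.

The training strokes used in tests are generated from the truth mask the
way a clinician would draw them: a freehand ring tracing the boundary
2 px inside plus chords through the zone (avascular), and rings at
+18 px (just past the falloff band) and +45 px plus a far chord
(vascular). Teaching the boundary — not just region interiors — is what
makes a classifier trained on a single image transfer across FAZ sizes.

**What the synthetic results do not show.** The generator does not model
projection artifacts, motion lines, media-opacity signal loss,
plexus-specific mesh morphology, or real decorrelation speckle
statistics. Passing recovery tests therefore demonstrates that the
implementations are faithful and self-consistent and that the two methods
track the same truth on images with realistic geometry and noise — not
that either method is clinically accurate on patient data.

## Problem sizes in the shipped suite

The suite uses 50 synthetic images for script-path recovery, a 12-image
held-out subset for the classifier path (whose feature stack dominates
runtime at ≈3 s/image), 1000/2000 replicates for CI-coverage/familywise
calibration, and 200 replicates of 30-eye cohorts for longitudinal power.
`scripts/acceptance.py` uses 30 images, a 10-image classifier subset, and
500/1000/100 replicates. These sizes keep a full run in the low minutes
while leaving the Monte-Carlo bounds comfortably away from their
acceptance edges.

## Known limitations

* The script pipeline's absolute areas inherit the macro's geometric
  bias: the measured region is bounded by the *binarized* inner vessel
  edge shifted by the net morphological margin, so its accuracy on real
  eyes depends on how far the flow-signal dropout extends — a quantity
  the generator parameterizes but patient data would have to calibrate.
* The classifier is trained per-device/per-protocol by design (single
  training image); no cross-device generalization is attempted.
* Repeated-measures inference assumes compound symmetry (no sphericity
  correction is applied) and complete cases.
* The wand tolerance-0 convention excludes boundary gradient pixels;
  areas are therefore systematically a ring thinner than a threshold-128
  wand would give (both conventions are available).
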