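# Methods

`veinviz` is an offline re-implementation of the computational core of a
mobile near-infrared (NIR) vein-visualization system: a synthetic
forearm-phantom renderer with ground truth, the capture-settings and
image-enhancement pipeline, vein segmentation with a marker-hit
criterion, and the descriptive statistics used to evaluate such a
device in an educational/clinical venipuncture study. This note
documents the models, the parameters that matter, and the design
choices that were genuinely open.

## Optical phantom model

Veins carry deoxygenated hemoglobin, which absorbs strongly at
740–760 nm, so under NIR illumination they appear as dark curvilinear
structures against brighter tissue. The renderer uses a single-scatter
Beer–Lambert surrogate rather than photon-transport simulation:

* **Absorption.** Each vein is a tube of radius *r* projected onto the
  image plane (footprint width 2*r*). Its absorption amplitude is
  `A_max · exp(−(d + a)/δ)` where *d* is vessel depth, *a* the adipose
  thickness, and δ the extinction scale.
* **Scatter blur.** The footprint is convolved with a Gaussian of
  width `σ(d) = σ0 + k·(d + a)`: deeper vessels are imaged through
  more diffusing tissue and look blurrier as well as fainter.
* **Illumination.** Four LEDs at the corners of a 50 × 35 mm rectangle
  (σ_L = 30 mm radial Gaussian falloff each, summed and clipped at 1)
  approximate the radial distribution of the LED accessory. The true
  angular emission profile of the diodes is not published; the
  Gaussian falloff is a stand-in.
* **Frame.** `I = clip01(I0 · L · R_bg · (1 − ΣA_v) + n)` with
  zero-mean Gaussian sensor noise *n* (sd `noise_sigma`, seeded).
  Optional hair occlusion draws 1-px anti-aliased dark arcs
  (transmission 0.2) until a target coverage fraction is reached,
  mirroring a known field failure mode (hairy antecubital skin).

This surrogate was chosen because it is cheap, fully closed-form
(hence testable against dense numerical convolution), and reproduces
the two qualitative behaviours the pipeline must face: a finite
depth-visibility limit and contrast loss with adipose thickness.
Reflectance imaging is assumed (not transillumination). Arterial
(oxygenated) blood is not rendered.

Default calibration (all config-overridable): `I0 = 1.0`,
`R_bg = 0.6`, `A_max = 0.85`, `δ = 2.5 mm`, `σ0 = 0.3 mm`, `k = 0.35`,
`noise_sigma = 0.01`, `pixel_pitch = 0.1 mm/px`, frames 256 × 384 px
(25.6 × 38.4 mm field). These values place the default
depth-visibility limit (below) near the 4.8 ± 0.7 mm figure obtained
when the hardware prototype was validated against ultrasound; they are
a calibration, not an independent measurement.

Coordinates are row-major pixels with origin top-left; physical
position of pixel (r, c) is (r, c) × `pixel_pitch` mm. Footprints are
computed in continuous mm (exact point-to-segment distance per
polyline segment) and sampled at pixel centers. Adipose is a scalar
depth offset, not a separate scattering layer; BMI classes map to
adipose presets only in the fixtures generator, never in the optics.

## Capture settings

Gain, exposure and contrast act pointwise:
`out = clip01((in·e·g − 0.5)·c + 0.5)` (implemented in the factored
form `in·(e·g·c) + 0.5(1 − c)` so identity settings are bit-exact).
Exposure is modelled multiplicatively — indistinguishable from gain on
static frames — and contrast pivots at mid-gray, the standard linear
convention. The five named profiles (Low light, Medium light, Very
bright, LED profile, Custom) ship with placeholder values
(`data/camera_profiles.json`); the field device's profile constants
were determined experimentally on hardware and never published.

## Enhancement operators

All sigmas are in mm and converted via `pixel_pitch`, so results are
resolution-invariant; borders are reflect-padded everywhere.

* `contrast_enhance`: linear percentile stretch (default 1st→0,
  99th→1, clipped); constant frames pass through unchanged.
* `dog1`/`dog2`: difference of Gaussians, σ = 0.4/2.0 mm and
  0.8/4.0 mm — band-passes tuned to vein radii of 1–2 mm.
* `log1`: Laplacian of Gaussian at σ = 1.0 mm; `log2`: raw
  4-neighbour Laplacian.
* Signed responses are renormalized affinely to [0, 1] with 0 mapped
  to 0.5 by the max-abs value, preserving sign structure (vein-like =
  below 0.5). Responses whose max-abs is below 1e-12 (float residue of
  a DC frame) are treated as zero signal.
* ROI processing crops, runs the stage on the crop (so reflect padding
  applies at ROI borders), and pastes back; outside pixels are
  bit-identical to the input.

The exact operator constants of the original device were distributed
in supplementary material that is not available; the scales above are
explicit reconstructions, not transcriptions.

## Detection and the marker-hit criterion

Segmentation thresholds the darkest `threshold_quantile` (default
0.05) of the ridge response, applies morphological closing then
opening with a disk of `morph_radius` (closing first so 1-px gaps are
bridged before speckle removal), drops components under
`min_component_area` (50 px, 8-connectivity), and skeletonizes the
survivors into centerline polylines. Skeleton arc-length is pixel
count × pixel pitch (no subpixel fitting).

In the field study a "positive match" was adjudicated visually by
supervising clinicians. Here it is operationalized as a distance rule:
a marked point hits if a mask pixel lies within `hit_tolerance`
(default 2 mm ≈ a typical antecubital vein radius). This is a proxy
for human judgement; the tolerance is configurable and the default is
a judgement call, not a measured quantity.

`max_visible_depth` renders one straight vein (radius 1.0 mm, a
typical antecubital vessel) per grid depth, runs the default pipeline,
and reports the deepest vein that is still *detected*: centerline
recall ≥ 0.5 **and** Michelson contrast ≥ `contrast_floor` (0.02).
Both knobs are exposed; the criterion is an operationalization, since
the original visibility judgement was made by eye. With the default
calibration the limit lands at 5.0 mm on a 0.5–8.0 mm grid (0.1 mm
steps), inside the 4.8 ± 0.7 mm ultrasound band.

Michelson contrast of a vein is `(I_bg − I_vein)/(I_bg + I_vein)` with
`I_vein` the mean intensity on the vein's centerline pixels and
`I_bg` the mean over a local annulus starting 3 mm beyond the tube
footprint (clear of other veins).

## Evaluation statistics

Failure rates are `100·failures/attempts` per BMI class plus a pooled
total; Likert items are summarized by mean, sample SD (n−1) and mode;
SUS is the standard scoring (odd items score−1, even items 5−score,
sum × 2.5) with Bangor bands (>70 acceptable, <50 concern, 50–70
inclusive marginal). Rounding matches the study's printed precision —
rates and vein summaries to 1 decimal, Likert means to 2, SDs to 3 —
using half-up rounding on exact rationals where the inputs are counts.
Sample SD reproduces the published Likert SDs (0.686/0.587/0.523/0.786)
from the packaged 20-row response matrix exactly. BMI classes are
opaque labels; no numeric BMI boundaries are assumed. Likert mode ties
break toward the larger score (no tie occurs in the packaged data).

One known discrepancy: the published attempt table prints 33.0 % for
119 failures in 360 attempts, but 119/360 = 33.0555…%, which rounds to
33.1 under any nearest-rounding rule (truncation would explain 33.0
but contradicts 23/80 = 28.75 being printed as 28.8). The package
reports the arithmetically consistent 33.1.

Usage analytics match session_start/session_end pairs per session id,
format durations as hh:mm:ss, tally events by kind, and rank
screens/settings/profiles/modes by descending count with alphabetical
tie-breaks. An unmatched `session_end` raises an error naming the
session.

## Synthetic study bundle

`make_fixtures(seed, out_dir)` writes a complete mock study: 25
subject phantoms over 3 BMI presets (adipose 0 / 1.5 / 3.5 mm;
subjects split 4/18/3 so 20 clinicians × 25 subjects = 500 attempts
with per-class attempt counts 80/360/60), a 20 × 4 Likert table, 4 SUS
responses, a 64-patient additional-veins table (27 flagged difficult;
Poisson means 2.4 difficult / 1.0 otherwise, giving an overall mean
near 1.6), and a usage-event log.

Attempt marking follows the study protocol: students marked sites
*unaided* and the device adjudicated. Unaided vein finding is modelled
as per-vein visibility `exp(−(d + a)/2.0 mm)`; a seen vein gets a mark
near its centerline with 1 mm Gaussian aim error, an arm with no seen
vein gets a blind guess. Hits are decided by the marker-hit rule
against the truth mask. This makes per-class failure rates monotone in
the BMI presets by construction, mirroring the field gradient; the
exact rates are emergent, not fitted.

What the phantoms do **not** emulate: real tissue texture and specular
skin reflections, motion blur, ambient-light variation, arterial
structures, and inter-subject anatomical variety beyond random
polylines. Passing tests therefore demonstrate internal consistency of
the pipeline and its calibration, not clinical performance.

## Problem sizes and numerical choices

Default frames are 256 × 384 px; the depth sweep uses 76 renders and
completes in seconds, and the full synthetic bundle (25 phantoms, 500
attempts) in a few seconds — sizes chosen so the whole evaluation runs
comfortably on a laptop core. Degenerate inputs are defined rather
than left to chance: constant frames segment to an empty mask, DoG/LoG
of constants return the neutral 0.5, percentile stretch of a constant
frame is the identity, and boundary SUS scores (50, 70) band as
marginal.

## Known limitations

* The optics surrogate has no radiative-transfer basis; its parameters
  are calibrated to one published depth figure, not measured.
* The marker-hit tolerance and the depth-sweep detection criterion
  stand in for human adjudication the original study did not formalize.
* Camera profile values and enhancement constants are reconstructions.
* The clinical outcomes (1.6 ± 1.3 additional veins; SUS 76.75 from
  four clinicians; the live usage log) cannot be recomputed from
  published data; the corresponding operations are verified against
  constructed oracles and generated logs instead.
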