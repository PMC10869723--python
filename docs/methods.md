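# Methods

## The spatial-gain model

B-mode echo intensity of fascicle-aligned muscle scans is dominated by
specular reflection at perimysial interfaces, which run parallel to the
fascicles. When the probe face makes an angle FPA (fascicle probe
angle) with the fascicles, the reflected ray is deflected by twice that
angle, displacing it at the transducer by an amount proportional to
`sin(2·|FPA|)`. The expected mean gray value (MGV) of a muscle ROI is
therefore modeled as

* sine family: `MGV = β₀ − (β₁/2)·sin(2·|FPA|)`
* linear family: `MGV = β₀ − β₁·|FPA|` (first-order expansion; the
  relative deviation `100·(2x − sin 2x)/sin 2x` is ≈ 8.6% at 20° and
  57% at 45°, hence the recommendation to use |FPA| ≤ 30°).

Both are ordinary least squares with an intercept after transforming
the regressor (`sin(2|x|)/2` resp. `|x|`); degrees are the public unit,
radians appear only inside trigonometric evaluation. `β₀` is **MGV_00**
(expected gray value at FPA 0°, a pennation-unbiased echo intensity);
**TEG** = `100·β₁/β₀` of the *linear* family, in percent per degree.
The `β₁` units deliberately differ between families (gray value per
unit of the sine regressor vs gray value per degree); the output schema
records both. Fits pool all frames of a specimen; the pipeline
restricts fitting to |FPA| ≤ 30° by default (configurable).

Model comparison uses adjusted r² and the Gaussian-likelihood AIC with
the full `2π` term and the error variance counted as a parameter
(k = 3), the convention of mainstream linear-model software (verified
against R's `AIC(lm(...))` in the tests). Only AIC differences on the
same data are meaningful; the preferred family has the lower AIC, with
an exact tie resolved toward the linear family as the more practical
model. A numerically perfect fit (RSS ≤ 1e-10) has undefined AIC and
adjusted r² is NaN when the total sum of squares is zero; both are
reported as NaN rather than raised, since they occur only on degenerate
noiseless inputs.

## Angle conventions

Image coordinates are 0-based with x = column and y = row (increasing
downward); orientations are degrees from the image horizontal, positive
counter-clockwise as displayed. The probe face is the image horizontal,
so the FPA **is** the fascicle orientation in image coordinates — the
gel-pad tilt is already physically present in the image and enters no
analysis-time arithmetic. The pennation angle α is the absolute
fascicle–epimysium orientation difference folded into [0, 90). The
generator's sign convention is FPA = α − GA: a gel pad with GA = α
cancels the pennation and produces the brightest image.

## Orientation estimators

Both estimators scan candidate angles with a rotate-and-project scheme:
the image (or ROI crop) is rotated by the negative candidate angle
(bilinear, constant NaN fill), rows are reduced to their mean over
valid pixels, and a scalar score is taken from the row profile.

* **Epimysium**: score = maximum row mean (a specular interface is the
  brightest full-width line); search window ±30° of horizontal over the
  upper half of the frame. If the peak does not exceed the median row
  mean by a factor (default 1.5) the estimator raises "epimysium not
  found".
* **Fascicles**: score = variance of the row-mean profile inside the
  ROI (a projection/Radon-style orientation-energy criterion: aligned
  streaks produce a high-contrast periodic profile); window ±45°. A
  flat orientation energy (max/median score ratio below 2) raises "no
  dominant fascicle orientation".

The scan is coarse-to-fine (1° grid, then 0.25° around the coarse peak,
then 3-point parabolic refinement), giving median absolute errors of
~0.03° on phantoms across pennation angles 2–17° and gel pads ±24°, and
rotation equivariance within ±0.5° (tested for rotations up to ±24°).
The published pipeline this reimplements used a bespoke algorithm whose
details are not public; this estimator is a functional equivalent
chosen for robustness on streak-like images without training data.

ROI placement: the study fixes one ROI size/orientation (default
400×200 px, axis-aligned). Per frame, the frame is derotated by the
epimysium angle, the epimysium row is the brightest full-width row,
mapped back to the central column, and the ROI is centered a fixed
offset (default 80 px) plus half its height below it; an ROI that would
leave the image is an error, never clipped. Detection on the derotated
image is required because near-horizontal fascicle streaks can
otherwise out-shine a tilted epimysium in a narrow column band.

Sweep homogeneity: epimysium angle and MGV are each regressed on frame
index (OLS); a sweep passes when both p-values exceed 0.20, a
conservative screen for probe-translation artifacts. Constant series
pass with p = 1. Note that under the null the MGV p-value is uniform,
so this screen has a false-alarm rate of 0.20 per quantity by design.

## The phantom generator

The generator emulates the display-level appearance of the study
conditions: sweeps at gel-pad angles {−24, −12, 0, 12, 24}°, three
frames per sweep with lateral probe translation, 512×512 8-bit frames.
Scene content is a constant background plus smoothed Gaussian noise
(σ after smoothing = 6 gray values, correlation length ~1.2 px), a
bright epimysium band (value 245, 4 px), and parallel fascicle streaks
(spacing 24 px, thickness 3 px) below it. Probe tilt is simulated by
rotating the scene geometry by −GA about the ROI center; lines are
rendered analytically at their rotated orientations, which is exact and
avoids interpolation bias in the calibration.

Per frame, the streak brightness is solved analytically from the streak
area fraction inside the default ROI so that the noiseless ROI mean
equals the model target `m(FPA)` exactly; configurations whose target
lies outside (0, 255) or whose calibrated streak value leaves [0, 255]
are rejected with an explicit message. Defaults: β₀ = 80, β₁ = 33.5
(sine units), pennation 12°, epimysium row 60, speckle mean 62. The
speckle mean is chosen so that over the default sweep the calibrated
streak brightness stays in ≈[75, 210], below the epimysium band — in
real B-mode the epimysium is the brightest specular interface, and this
ordering keeps the strongest-line detector well-posed. The seed is
mandatory; identical (config, seed) renders are bit-identical, with
per-frame RNG streams derived from (seed, gel-pad angle, frame index).

What the phantom does **not** emulate: Rayleigh/RF speckle statistics,
log-compression of the scanner (the generator works directly in display
gray values), attenuation with depth, gel-pad absorption, curved or
converging fascicles, vessels and adipose inclusions. Passing tests
therefore demonstrate correctness of the geometry, calibration and
statistics of the pipeline, not robustness to every artifact of real
scans.

Observation-level simulators (`simulate_mgv_observations`,
`simulate_study_observations`) sample (FPA, MGV) pairs directly from
the models with Gaussian ROI-level noise (σ = 3 gray values), for
Monte-Carlo studies where rendering images would add only runtime. The
study-level simulator draws per-specimen parameters emulating the
spread observed ex vivo in bovine muscle: α ~ N(11.5°, 4.5²) clipped to
[1.5, 20], MGV_00 ~ N(78, 9²), TEG ~ N(1.85, 0.3²) %/deg, 51 specimens
with 5 gel pads × 3 frames each.

Model-selection direction is assessed on such study-scale ensembles
(51 × 15 observations per replicate). At single-specimen size (n = 15,
|FPA| ≤ 24°, σ = 3) the expected AIC gap between the families is ~0.15
— far inside the noise — so no criterion on single specimens can be
informative; the pooled ensemble, which is also how the method was
originally evaluated, separates the families essentially always.

## Cross sections and segmentation

A synthetic cross-section photograph colors an IMCT network (pale) over
muscle (red-brown) with additive Gaussian color noise (σ = 8). The
network is the central rank band of a smoothed random field: pixels
whose |field − median| falls below the appropriate quantile form long
connected septa whose area fraction equals the requested percentage by
construction (exact to 1/N). `septum_thickness` sets the field's
smoothing scale and thus the septa's typical width, not their exact
thickness.

The classifier is a deliberately transparent single-channel threshold
trained by exhaustive scan over all midpoints between adjacent distinct
values in each channel, both polarities, minimizing training
misclassification. It replaces the interactively trained random-forest
pixel classifier used in the original workflow, whose operative output
was only the percentage of pixels above/below a learned threshold. The
IMCT percentage is computed over the whole image by default; a
foreground mask restricts the denominator when the photograph contains
non-muscle background (which of the two an original analysis used is
not documented; whole-image is the default here). The IMCT%–MGV_00
association is a plain OLS with a two-sided slope test and the standard
correlation-magnitude bins on |r| (boundaries assigned to the lower
bin).

## Pipeline, sizes, determinism

The pipeline is deterministic given inputs; all synthetic randomness
flows from explicit seeds. Default problem sizes were chosen to make
every validation statistically meaningful at interactive runtimes:
500 replicates for parameter-recovery Monte-Carlos (SE of the β₀ mean
≈ 0.07 gray values), 200 per family for model selection, a 4 × 5
pennation × gel-pad grid for orientation recovery, 512² images, and a
10-specimen end-to-end study. Missing sweeps flag the specimen and the
run continues; ages missing from a manifest stay missing — they are
never imputed. The packaged specimen-overview fixture stores the
per-muscle/per-animal counts (51 specimens, 10 muscle codes, 24
animals) and the twelve known ages as an unmapped list, because the
published table does not state which animals they belong to.

## Known limitations

* The orientation estimators assume one dominant, roughly parallel
  streak family and a single bright interface; they are not suited to
  curved fascicles or multi-layer aponeuroses.
* TEG from the linear family depends mildly on the FPA design range
  because the underlying law is sinusoidal; comparisons should use a
  common gel-pad protocol.
* The acoustics helpers (`acoustic_wavelength`, `axial_resolution`) are
  idealized plane-wave/pulse-length bounds, not a device model.
* Real-scanner post-processing (log compression, depth gain) is outside
  the model; MGV_00/TEG inherit whatever display mapping the device
  applies.
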