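# Methods

This note documents the models, estimators and numerical choices behind
`picowash`, and what the synthetic-data generator does and does not
emulate.

## Synthetic scene model (`scenesim`)

The generator renders a transmitted-light view of a periodic plug train
in a rectangular microchannel. Ground truth is *imposed*, not computed
from fluid dynamics: plug geometry, velocity, per-washer dye reduction
and noise are parameters, which is exactly what makes the downstream
estimators testable.

**Geometry and coordinates.** `x` is the flow axis (columns, increasing
downstream), `y` runs across the channel (rows); indices are 0-based
with half-open pixel intervals. All lengths are micrometers; conversion
to pixels happens only at render time. Plugs are rectangles of length
`L_drop` whose ends are rounded by half-disc caps of radius half the
imaged channel breadth — a shape that matches plug-flow micrographs
without simulating the free surface. The train is periodic with period
`L_drop + L_space`; a frame's *phase* is the train offset, drawn
uniformly at random per short-exposure frame (asynchronous sampling of a
fast periodic process).

**Radiometry.** Intradroplet gray is
`background_gray − attenuation_gray · f(x)` where `f(x)` is the local
z-averaged dye fraction; the linear (small-absorbance Beer–Lambert)
model keeps the per-pixel linear calibration exactly identifiable, which
is the property the calibration stage relies on. Noise is additive
Gaussian on gray values, clipped at zero; shot noise is not modelled.
Defaults (`background_gray` 200, `attenuation_gray` 150, 8-bit-like
units) give a dynamic range of 150 gray levels, so the "2% noise"
condition used throughout the tests is `noise_sd = 3`.

**Washing.** Each washer multiplies `f(x)` by a factor ramping linearly
from 1 to `1/stage_dilution` over `gradient_span_um` columns centred on
the washer (default 30 μm). The true intradroplet spatial profile of
residual dye during washing is not known — experiments show dye
retained at the front of the droplet — so `gradient_span` is an
artifact of the generator, not a claim about the flow field.

**Default operating point.** 85 μm plugs with 85 μm spacing (duty
fraction 0.5, consistent with a droplet volume fraction of ~0.5), 50 μm
wide × 60 μm high channel, 2 mL/h emulsion flow, 1 μm/px. At this point
the transit-time estimate — the time for a plug to advance one plug
length at `v = Q/A` — is 0.459 ms, displayed as "~0.5 ms" (one
significant figure), with reciprocal 2.18 kHz displayed as "2 kHz": the
minimum AC field frequency for reliable droplet–washer coalescence.

**Long exposures.** The analytic time average over a uniform phase is
`background − attenuation · p(row) · f(x)`, with the per-row duty
`p(row) = (L_drop − 2·inset(row)) / (L_drop + L_space)` accounting for
the end caps. The ensemble-consistency test verifies that the mean of
many rendered short-exposure frames converges to this image; note the
per-pixel sampling error is dominated by the Bernoulli occupancy
variance `(attenuation·f)² · p(1−p)`, not by the additive noise, so the
convergence criterion uses the full per-pixel standard deviation and a
quantile form (99% of pixels within 3σ/√n, all within 6σ/√n) — a strict
everywhere-3σ bound is statistically impossible over thousands of
pixels.

**What the generator does not emulate.** Real acquisitions add optical
aberrations near channel walls, uneven illumination, misregistration
between the wash/control/background exposures, droplet deformation in
the washer, and partial volume change across it. Passing tests therefore
demonstrate correctness of the *estimators* under the stated imaging
model, not robustness to those instrument effects; `wall_exclusion` and
the geometry-corrected DF formula are the hooks real data would use.

## Retrospective gating (`gating`)

Frames are sorted by the position of one reference droplet. Two
localizers:

- **Centroid**: threshold (Otsu by default, dye is dark), label
  connected components, take the intensity-unweighted centroid column of
  the largest component; frames with no component above a minimum area
  are marked invalid. The area floor defaults to 1 px and in pipeline
  use is best set to ~25% of the expected plug area.
- **Template**: exhaustive SSD `E(x) = Σ_k (g_k(x) − G_ref,k)²` between
  a reference patch and the subimage whose leftmost column is `x`
  (0-based; equivalent to the 1-based `c_{i,j−1+x}` subimage
  convention), evaluated at every admissible `x` with no early exit.
  `x_ref` is the argmin of `E` within caller bounds; ties take the
  smallest `x` (determinism), and a minimum above a mismatch ceiling
  marks the frame invalid.

Search bounds default to the central third of the ROI so exactly one
droplet of a periodic train can occupy them; whether the minimum should
be local or global within bounds is not externally specified, and the
global-within-bounds choice is adopted here. Invalid frames are dropped
rather than interpolated — random phases make frames exchangeable, so
dropping loses sample size but introduces no bias. Sorting is stable
(ties by original frame index); no sub-pixel interpolation of `E(x)` is
attempted, so position resolution is one column. Consequently, exact
rank recovery is only well-posed when distinct phases map to distinct
columns; the gating tests use phases linearly distributed over one train
period (400 frames over the washing duration in the headline check) at a
pixel pitch of one period/400, shuffled randomly.

## Pixel-wise calibration (`calibmap`)

For each known dye fraction, frames are grayscale-converted (unweighted
R-G-B mean), frame-averaged into a reference image (500 frames per
fraction by default, shrinking the reference noise by √500), and the
droplet mask is segmented on the highest-fraction (strongest-contrast)
reference — shared across fractions, which is exact for the stationary
co-registered droplets the generator produces and is the practical
choice because a zero-dye reference has no contrast to segment. Per
pixel, OLS of fraction against averaged gray gives `slope`/`intercept`;
pixels whose gray does not vary (background, singular fit) are marked
NaN and excluded rather than failing the fit. Residual RMS per pixel is
retained for diagnostics.

Applying the model clips fractions into [0, 1] (physical range) *before*
averaging, with the clip count reported so silent distortion is visible.
The map-integrated dilution factor is the **reciprocal of the
mask-mean fraction**, `DF = 1 / mean(f)`; the alternative (mean of
per-pixel reciprocals) diverges on near-zero pixels and is rejected.
Maps are normalized to the undiluted calibration reference, not to each
droplet's own pre-wash state. The top and bottom `wall_exclusion`
fraction of channel rows can be excluded (0.15 reproduces the
rows-9..50 window of a 60-row channel) to mirror the optical-aberration
exclusion used on real devices.

## Long-exposure quantification (`washquant`)

Column profiles integrate gray over the channel cross-section. The
normalized profile `I(x) = (I_wash − I_back)/(I_cntl − I_back)` is
computed with a denominator guard `ε = 10⁻⁶ ×` the denominator's dynamic
range; guarded columns are flagged invalid and excluded from every
average, never zero-filled. Alignment of the three exposures is the
caller's responsibility (no registration algorithm is included).

`DF = [⟨I_pre⟩·duty_post] / [⟨I_post⟩·duty_pre]` cancels the unknown
intensity-to-concentration constant; droplet volume change across the
washer enters only through the duty-fraction factors. Segment averages
for serial washers exclude a guard band of one plug length around each
washer (configurable) because dye removal ramps over a finite distance;
under constant geometry the stage DFs multiply to the overall DF
exactly. A zero post-washer mean raises a distinct "below detection"
error rather than returning infinity, since at that point the estimator
is unbounded, not measured.

Plug geometry is measured per frame by marking a column intradroplet
when its darkest ROI pixel falls below threshold — at the plug mid-row
the rounded caps recede by under a pixel, so lengths are recovered to
~1 px — excluding runs that touch the ROI edges. Spacing is the mean
center-to-center period minus the mean length; the length CV is the
sample SD/mean, reported in percent. Bead retention is the downstream
proportion of droplets containing a particle divided by the upstream
proportion, in percent; values above 100% (sampling noise) are flagged,
not rejected.

## Resistor networks (`fluidics`)

Hydraulic resistance of a rectangular channel uses the exact duct
series
`R = 12μL/(wh³) · [1 − (192h)/(π⁵w) Σ_{n odd} tanh(nπw/2h)/n⁵]⁻¹`
with `h` the smaller dimension, truncated when a term falls below 10⁻¹²
of the running sum (the tests compare against a 1000-term evaluation to
<10⁻⁹ relative across aspect ratios 1–100). The lubrication
approximation `12μL/(wh³(1−0.63h/w))` is deliberately not used: at the
near-square aspect ratios of washer channels (e.g. 15 × 50 μm) it errs
by several percent. Electrical resistance of an electrolyte-filled
channel is `R = L/(σwh)`. Geometry is supplied in micrometers and
converted to SI internally; viscosity defaults to water-like 10⁻³ Pa·s
and the electrolyte conductivity is configuration, not a constant.

`R_wash = R_inject + R_remove` composes the washing path in series
(injection channel → droplet → removal channel, intradroplet resistance
neglected); this composition is an assumption and is echoed in every
report. The design rule `N(R_H + R_L)/R_wash < 0.01` is evaluated per
kind (hydraulic, electrical); a device passes only if every supplied
kind passes. The 0.01 threshold is empirical and configurable; reports
always carry the ratio alongside the verdict.

## Problem sizes and reproducibility

Test and acceptance workloads are sized for a laptop-class single core:
ensemble convergence uses 2000 frames of a 30 × 300 px scene;
calibration uses 500 frames per fraction on a 50 × 160 px scene; noisy
long-exposure recovery averages 400 frames of the default 50 × 600 px
scene per condition; gating reconstructs 400 frames of a 47 × 1100 px
scene. All randomness flows through `numpy.random.default_rng` seeds
carried on the `Scene` or passed explicitly; identical (scene, seed,
frame-count) triples reproduce stacks bit-exactly, and every CLI stage
records its configuration, seed, version and input checksums in a
`provenance.json`.

## Known limitations

- The imaging model is linear and noise is Gaussian; saturated or
  shot-noise-limited cameras are outside the calibration's assumptions.
- No image registration: wash/control/background exposures and
  calibration stacks must be co-registered upstream.
- No multi-droplet tracking, no sub-pixel localization, no chromatic
  unmixing for two-dye experiments.
- Transient (compliance/capacitance) effects and droplet resistance are
  absent from the resistor-network model; the design rule addresses
  steady uniform operation only.
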