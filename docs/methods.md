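# Methods

This note documents the models, parameters and design choices behind
`cario`: what the dehydration statistics measure, how the OCT and MicroCT
morphometry work, what the synthetic generator does and does not emulate,
and the numerical conventions.

## Dehydration statistics

A dehydration acquisition is a T×H×W stack, one frame per second for a
nominal 60 s, starting at the first post-immersion frame (t = 0).  For a
region of interest the mean intensity curve is formed first and the integral
statistic applied second (ROI-mean-first):

* SWIR: `ΔI = Σ_t (I_t − I_min)` — the area between the curve and its global
  minimum.  Dry demineralised enamel scatters strongly; pore water absorbs
  1950-nm light, so the curve rises as water leaves and ΔI grows with the
  amount and rate of fluid loss.
* Thermal: `ΔQ = Σ_t (T_max − T_t)` — the evaporative-cooling area in K·s.

`I_min`/`T_max` are global extrema over the window, not frame-0 values:
curves typically start at the extremum but are not guaranteed to.  The sum
runs over all available frames (including frame 0), so truncated
acquisitions remain analyzable.  Sums use exactly rounded summation
(`math.fsum`), making the statistics independent of summation order.

Both statistics are contrasted against a sound control ROI on the same
tooth: `L−C` (difference) and `L/C` (ratio).  The difference cancels
tooth-wide drying effects that are common to both ROIs; the ratio
normalises by the control and is therefore sensitive to tooth-to-tooth
variation in control drying — which is why it correlates more weakly with
lesion structure in cohort analyses.  A zero control makes the ratio
undefined; it is flagged and the difference still returned.

Per-pixel integrated heat maps (`integrated_heatmap`) apply the same
statistic to each pixel's own series.  This is a deliberately distinct
estimator from the ROI-mean-first default: the two differ whenever
per-pixel extrema occur at different frames (the per-pixel mean dominates
the ROI-curve delta by a Jensen-type inequality).  Heat maps are intended
for ROI designation, not reporting.

Composite-restoration pixels are bright in SWIR and would inflate ΔI; their
exclusion is the caller's responsibility via the masks, and the module only
validates that the lesion and control masks are nonempty and disjoint.

## OCT morphometry

Processing per B-scan: surface detection → threshold segmentation → depth,
reflectivity, TSL.

* **Surface**: per column, the first pixel above a noise floor estimated
  from the top five rows (mean + 3 sd), median-filtered across columns
  (width 5).  Columns with no suprathreshold pixel are marked missing and
  excluded.
* **Segmentation**: below-surface pixels within the analysis columns are
  thresholded.  The threshold is Otsu's value refined by the intermeans
  (isodata) iteration: with a heavy-tailed dark background (deep attenuated
  rows dominate the histogram) plain Otsu can split the background instead
  of separating the bright lesion body, and the intermeans fixed point
  restores the body/background split.  The mask is the largest connected
  suprathreshold component.  Two guards return an empty mask on sound
  tissue: a 10-pixel minimum size, and the requirement that the candidate's
  mean reflectivity reach 15% of the median surface Fresnel peak — sound
  sub-surface scattering sits near 5% of the peak, a demineralised body at
  25% or more.
* **Lesion depth**: per retained column, (deepest mask row − surface row) ×
  axial pitch ÷ 1.6, averaged over columns (mean).  Every reported OCT
  tissue length is the optical length divided by exactly 1.6, the
  refractive index of enamel; 32 rows at 5 μm optical pitch is 100 μm of
  tissue.
* **ΔR**: mean reflectivity over the mask.
* **TSL**: per lesion column, the contiguous run of rows immediately above
  the first body row whose reflectivity stays below 50% of that column's
  body peak; thickness is the median run × pitch ÷ 1.6 (median across
  columns so single dropout columns cannot flip detection, versus the mean
  used for depth).  Detection requires at least 2 axial pixels — "transparent"
  is not quantified by any instrument convention, so the rule is: darker
  than half the local body peak, at least two pixels thick.  TSL thickness
  is reported on the tissue scale, consistent with depth.  A TSL is defined
  only relative to a lesion body; asking for one on sound tissue is an
  error.  The detection rule assumes a surface-adjacent TSL (the layer
  grows from the surface down); transparent zones buried inside the body
  are not searched for.

## MicroCT morphometry

Slices are median-filtered (radius 1 px at 10 μm pitch by default; a
Gaussian option exists because smoothing conventions vary) and probed with
parallel density line profiles (default 5, spaced 2 px) crossing the
surface into the tissue.  On each profile the absolute first difference is
peak-picked with a prominence rule (at least 10% of the maximum step): the
first peak is the air/tissue edge, and of the two most prominent peaks
beyond it the deepest is the lesion floor, giving depth = (floor − surface)
× pitch.  The surface layer is measured as the elevated-density run below
the surface: samples above the midpoint between the estimated sound level
(median beyond the floor) and the local maximum.  The run rule rather than
a gradient peak lets a single-pixel SL still register.  Lines without a
boundary beyond the surface vote "absent"; if all lines vote absent the
result is depth 0 with a flag.  MicroCT lengths are true micrometres and
never receive the 1.6 division.  A standard 3×3 Sobel gradient magnitude is
exposed for 2-D edge maps.

Averaging more lines reduces placement/noise variance; with the default
rendering noise the depth-estimate spread roughly halves from 1 to 5 lines.

## Cohort statistics

Pearson correlation with two-sided p-values (t transform) throughout;
unpaired t-tests default to Welch's unequal-variance form (group variances
are not credibly equal across activity classes), with the pooled Student
variant behind a flag.  No multiple-testing correction is applied in the
default reports — the analyses are confirmatory of a single prespecified
structure — but a Benjamini–Hochberg helper is available.

The TSL band analysis splits lesions at 70 μm, correlates TSL with each
dehydration statistic within each band and t-tests the statistics between
bands.  The activity classification is: no detectable TSL → active;
detected and < 70 μm → partially arrested; ≥ 70 μm → arrested.  The
boundary is assigned inclusively to "arrested".  Lesions without a
detectable TSL are excluded from TSL correlations by default (their
thickness is unknown, not zero); `include_undetected=True` keeps them at 0.
Surface-type strata with fewer than 3 lesions are flagged rather than
computed.

## Synthetic cohort generator

The generator is the test bed standing in for an extracted-tooth dataset.
Each lesion draws, from its own counter-split RNG stream (seed, lesion
index, purpose — so cohorts are bit-reproducible under reordering):

* surface type with weights 0.13/0.81/0.06 (occlusal/smooth/incisal),
  matching the clinical predominance of smooth-surface secondary lesions;
* TSL thickness: 0 with probability 0.2 (no detectable layer ≈ active),
  otherwise uniform on 0–100 μm;
* lesion depth uniform on 80–320 μm, at least 40 μm deeper than the TSL so
  the transparent cap stays enclosed by the lesion;
* mineral loss uniform on 0.05–0.35;
* water pooling uniform on 0–0.8 for occlusal/incisal surfaces only
  (crevices retain water), zero for smooth;
* MicroCT surface layer SL = TSL + U(0, 60) + N(0, 35) μm, clipped to
  [0, depth − 30].  The true generative SL–TSL link is unknown; this choice
  yields a positive but deliberately loose correlation and an SL range
  wider than the TSL range, while keeping a demineralised body band below
  the layer.

**Permeability** is the central coupling: p(TSL) = p₀·exp(−TSL·ln 20 / 70)
clamped below at 0.05·p₀.  The clamp encodes arrest as a saturation — once
the layer blocks fluid exchange, further thickening changes nothing — which
is exactly why the ≥70-μm band shows no within-band correlation.  The
function is monotone nonincreasing, equals baseline at 0, is 5% of baseline
at 70 μm, and never reaches zero.

**SWIR forward model** (arbitrary units): every tooth pixel shares
I(t) = 40 + 2·c·σ(0.15(t−8)) where σ is the logistic function and
c = exp(N(0, 0.35)) is a per-tooth amplitude factor (wetting/texture
variation; it cancels in L−C and compresses L/C).  Lesion pixels add
80·mineral_loss·σ(0.45·p·(t−12)) — plateau set by mineral loss, rate by
permeability — plus a slow 15·pool·σ(0.3(t−20)) pooled-water term.
Composite regions render as a static 180 and sit outside both default ROIs.
Noise is additive Gaussian, sd 2.0 per pixel by default.

**Thermal forward model**: T(t) = 294.15 K − A·(e^{−t/25} − e^{−t/3});
the double exponential is zero at t = 0, dips near t ≈ 7 s and recovers.
Control amplitude A = 0.12·c K; lesion pixels add 3.0·mineral_loss·p +
2.5·pool K.  Noise sd 0.05 K (typical uncooled-microbolometer sensitivity).
Emissivity and humidity are not modelled — the stack is a pure temperature
series.

**OCT rendering** (optical axial units, default 5 μm/row, 220×64): air
noise, a surface Fresnel peak (200), an optional TSL band (8) of
round(TSL×1.6/pitch) rows, a body band (150·min(ml, 0.15)/0.15 — scattering
saturates at 15% mineral loss, so renderings at 0.15 and 0.30 are
identical) down to round(depth×1.6/pitch) rows, then weak attenuated
background (10·e^{−z/300 μm}).  **MicroCT rendering** (true units, 10
μm/px, 120×64): air 15, SL 160, body 90 − 80·ml, sound 120 — body < sound
< SL by construction; zero mineral loss renders flat sound tissue and no
layer.

What the generator does **not** emulate: OCT speckle and the instrument
point-spread function, 3-D volumes (one representative slice/scan per
lesion), stain, gingiva, specular glare, curved or tilted tooth surfaces
(surfaces render flat; the surface-detection median filter is exercised on
synthetic tilted surfaces in tests), beam hardening, and any depth–ΔR
coupling (rendered ΔR depends on mineral loss alone, so the generator does
not reproduce a positive depth–reflectivity correlation).  Passing tests
therefore demonstrate correctness of the measurement chain and the
qualitative cohort structure, not instrument-level realism.

## Problem sizes and numerical choices

Cohort-level checks use 100 lesions (default config), parameter-recovery
checks 50 noise-free lesions, and the null-soundness floor 500 Monte-Carlo
repeats of a zero-mineral-loss tooth; these sizes give stable statistics
while keeping a full run in tens of seconds.  Fixed seeds make every cohort
and every rendering reproducible; per-lesion streams are spawned from the
cohort seed by `SeedSequence` spawn keys.  Degenerate inputs fail loudly:
empty masks, non-finite curves, thermal frames outside 250–350 K, zero
control deltas (flagged ratio), sub-3-point or zero-variance correlation
inputs.  Noise-free MicroCT recovery is run without median smoothing
(there is nothing to smooth, and a 3×3 median erases a single-pixel
surface layer); noisy analyses use the radius-1 default.

## Known limitations

* The activity classes derive from a single structural feature (TSL); real
  adjudication would combine dehydration rates, structure and history.
* The 70-μm cut and the 5% arrest floor are cohort-level conventions, not
  per-lesion physiology.
* The forward models are phenomenological (logistic/double-exponential
  shapes with linear parameter couplings); they are designed to carry the
  assumed statistical structure, not to be photometrically calibrated.
* Imaging through composite restorations (opaque to SWIR when TiO₂-loaded)
  is out of scope; composite regions are rendered only as an ROI hazard.
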