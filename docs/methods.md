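# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limits of what the test suite demonstrates.

## The mapping chain

**Greyscale conversion.**  Multi-band scenes are reduced to one band by an
unweighted mean of the available bands; early-satellite scenes without a
blue band simply average red and green.  A pixel missing in any band is
missing in the greyscale.

**Reference-area calibration.**  Each source scene is regressed against a
common target scene over pseudo-invariant reference areas: dark lakes and
open fens, bright sandpits.  The regression is ordinary least squares of
the target area means on the source area means (target = f(source), the
direction in which the fitted equation is applied to the source raster).
Area means use centre containment — a pixel belongs to a polygon when its
centre does — which is deterministic and robust across resolutions.  Areas
with zero valid pixels in either scene are flagged and excluded from the
fit; no outlier rejection is applied beyond that.  Regressions are
unweighted by area size.  For noiseless affine sensors this recovers the
target radiometry exactly (the suite asserts < 1e-6 at the reference
reflectances); with noise up to ~10 % of the dynamic range the
reference-area R² stays at or above 0.85.

**Drone-mosaic refinement.**  Very-high-resolution mosaics are calibrated
in two steps: a coarse affine fit sampled at random coarse cells, then a
local refinement that aggregates the result to the target grid, forms the
per-cell difference to the target, upsamples it block-constant
(nearest-cell), and subtracts.  Block-constant upsampling is deliberate: a
smoother kernel would blur the per-cell correction, and after refinement
the mosaic's coarse aggregate equals the target exactly while within-cell
contrast is untouched.

**Plot formulas and regressions.**  Lichen volume is v = (c/100)·h with c
the 3-D cover in percent and h the mat height in mm, giving dm³ m⁻², and
biomass is b = 22·v g m⁻².  The cover term enters as a fraction: the
percent form would be dimensionally inconsistent with the 22 g dm⁻³
density and the ~2000 g m⁻² biomass ceiling.  Plot-scale grey level is the
mean of pixels whose centres fall in a 0.35 m radius disc (≈ 0.4 m²)
around the plot centre.  Cover and biomass are fitted on grey by two
independent unweighted OLS lines, not forced through the origin; the
zero-crossing (grey at predicted cover 0) and the biomass cap (biomass
regression evaluated at the grey of predicted cover 100) are derived
quantities of the fit, never constants.

**Maps and statistics.**  Predicted cover is clamped to [0, 100] %,
biomass to [0, cap] and forced to zero wherever cover is zero.  Forests
(canopy shading), water and bare sand (as bright as a full lichen mat) are
always masked; mires are kept in herding-district means but dropped from
the cross-border zone comparison to keep the zones comparable.  Zone
membership is centre-in-buffer of the border line intersected with the
side polygon.  District means are in t km⁻², numerically equal to g m⁻².
The rescaling test mean-aggregates the calibrated greyscale to coarser
pixels and re-predicts biomass; because the clamp at the zero-crossing is
convex, coarse estimates can only fall at or below the native estimate on
patchy scenes — isolated bright patches averaged into dark pixels drop out
of detection.  Validation uses the weighted mean absolute percent error
wMAPE = Σ|O−S| / Σ|O|.

## The district biomass model

Annual recursion for district-mean dry biomass b_t (g m⁻² ≡ t km⁻²):

    b_t = b_{t−1} + g_{t−1} − e_{t−1} − w_{t−1}

with, all evaluated at the start-of-year biomass as the printed equations
state them:

- growth g = f·(b·R(b) − b), R(b) = a·b^(−k), a = 1.95, k = 0.1.  The
  absolute growth a·b^(1−k) − b vanishes at b = 0 (defined, since the
  power form diverges) and at the equilibrium a^(1/k) ≈ 795 g m⁻², and
  peaks at ≈ 31 g m⁻² near 277 g m⁻².  The growth coefficients are taken
  as given constants from a long-term growth experiment; fitting them is
  out of scope.
- the landscape factor f = mean_r[g(b_r)] / g(mean_r b_r) over a random
  point sample of the biomass map: a Jensen correction, ≤ 1 for any
  heterogeneous landscape because absolute growth is concave on the
  relevant domain, = 1 only for a homogeneous one.  Years without maps are
  filled by linear interpolation between the mapped anchors with constant
  continuation beyond the first and last (a nearest-anchor option exists;
  linear was chosen for smoothness).
- intake e = i·d, with i = 0.676 t dry lichen per reindeer-year
  (20 MJ day⁻¹ at 10.8 MJ kg⁻¹ over 365 d ≈ 676 kg) in a pure winter
  district and half of that, 0.338 t, for mixed-use pastures; d is the
  reindeer-year density (count/area)·(occupancy days/365), so 2.3 animals
  km⁻² present 157 days ≈ 1 reindeer-year km⁻².
- loss w = b·d·l, the density-proportional fraction l of standing biomass
  destroyed per reindeer-year km⁻² beyond ingestion (trampling, wastage).

Biomass is floored at zero with clamp events recorded; in unclamped years
the bookkeeping identity holds exactly and the tests assert it.  Model
variants zero individual fluxes (no_loss, intake_only, no_intake) for
attribution runs, and sensitivity runs start from 200/400/600 g m⁻².

**Loss-parameter fitting.**  l is estimated by minimizing the sum of
squared differences between the simulated trajectory and a sparse
reconstructed biomass series, over l ∈ [0, 0.5]: a 51-point grid locates
the basin and bounded Brent (xatol 1e-8) refines it — deterministic and
derivative-free.  All observation years are weighted equally and the
initial biomass anchoring the fit is a configuration choice (default
200 g m⁻² in the pipeline, matching the low end of the sensitivity set);
both choices are exposed rather than hidden.  Self-generated noiseless
histories return the generating l to 1e-4; with 10 % multiplicative
observation noise on 8 observation years the median error over 100
replicates stays under 15 %.

## The synthetic study conditions

The generator emulates the statistical structure of the study system, not
any particular scene:

- **Landcover** from a thresholded smoothed Gaussian field with fractions
  near the regional figures (heath ~0.30, forest ~0.38, mire ~0.28, water
  ~0.04), plus 24 lakes, 9 fens and 15 sandpits as non-overlapping
  ellipses whose per-area intrinsic reflectance is fixed for all years —
  the pseudo-invariance assumption made testable.
- **Lichen fields** as clustered circular patches confined to heath over a
  low-biomass matrix, with a per-patch mat height drawn uniformly from
  25–60 mm (the within-patch height distribution is not observable from
  the source material; uniform bounds are the simplest documented choice,
  and they are configurable).  Everywhere,
  biomass = 22·(cover/100)·height, so truth and plot formulas agree by
  construction.  The winter-pasture side is generated lichen-richer
  (density factor 1.6–1.8), producing border cover ratios in the 1.5–2
  range at 10 km.
- **Scenes** render intrinsic reflectance — piecewise linear in 2-D cover
  between a dark vegetated matrix (0.12) and a bright full mat (0.55),
  with class constants for water/fen/sand — through per-sensor gain,
  offset and additive Gaussian noise truncated at zero, mean-aggregated to
  the sensor pixel (0.25–60 m), with partial coverage rendered as nodata.
  No atmosphere, PSF, topographic shading or cloud geometry is emulated.
- **Plots**: five transects of 40 plots at 10-m intervals laid
  perpendicularly across the fence, half on each side; each plot carries a
  binary mask image whose lichen-pixel fraction equals the recorded 2-D
  cover (within the 1/2500 rounding), a visually-estimated 3-D cover with
  observer noise, and the mat height.
- **Censuses**: exponential herd drift with year-specific shock
  multipliers (emulating harsh-winter crashes) and optional lognormal-like
  noise; a winter district at 157 occupancy days, a year-round district at
  365.

Problem sizes were chosen so the full pipeline runs in seconds: the demo
district is 2 × 1.5 km at 5 m (the full-extent configuration doubles
this), sites are 440 × 400 m at 0.25 m.  What passing tests show is that
the chain is internally consistent and recovers known structure under
these conditions; they do not show that any particular historical scene
would calibrate equally well — real imagery adds atmospheric effects,
georeferencing error, phenology and sensor PSFs that the generator
deliberately omits.  The synthetic reconstruction wMAPE (~50 %) is of the
same order as, but not a measurement of, the error of any real
reconstruction.

## Numerical and design notes

- Rasters are numpy arrays with a top-left origin and square pixels; NaN
  is nodata everywhere; aggregation is NaN-aware block means, dropping
  partial trailing blocks.  I/O is TIFF plus a YAML sidecar for
  georeferencing, and GeoJSON for vectors.
- All generators and the pipeline are pure functions of (configuration,
  seed); sub-streams are derived from the single seed, and rerunning
  reproduces every table bit-identically.
- Degenerate inputs fail loudly: all-equal calibration sources, constant
  plot grey, empty polygons, landscape-factor samples whose mean sits at
  or beyond the growth equilibrium, missing forcing years (named in the
  error).
- The landscape factor is computed on *reconstructed* biomass maps, as in
  the source design, so calibration bias propagates into f_t; values in
  the demo fall in 0.3–0.7.

## Known limitations

- Single-band mapping cannot separate bright lichen from bright sand; the
  sand class is masked rather than discriminated.
- The biomass model has no climate, icing, snow-depth or multi-herbivore
  terms, and no spatially explicit grazing; l absorbs every loss process
  proportional to density and standing biomass.
- Coarse-pixel reference areas (small fens and sandpits at 40–60 m pixels)
  lose pure pixels, which biases bright-end calibration slightly upward —
  visible in the demo as reconstruction overestimates at the coarsest
  years, and the main contributor to its wMAPE.
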