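# lichenline

Reconstruction of reindeer forage-lichen cover from heterogeneous greyscale
imagery, and a mechanistic herding-district lichen biomass model with
loss-parameter fitting — exercised end-to-end on seeded synthetic landscapes
and census series.

## The problem

Pale terricolous forage lichens (*Cladonia*, *Flavocetraria*, *Stereocaulon*)
dominate the reindeer winter diet and are markedly brighter than the
surrounding heath vegetation.  That reflectance contrast makes it possible to
reconstruct decades of lichen cover change from single-band (greyscale)
imagery — old aerial photographs, Keyhole and Landsat scenes, modern
Sentinel-2 and drone mosaics — provided the heterogeneous radiometry is
harmonized.  The package implements that chain and the dynamic model used to
interpret it:

1. **Radiometric calibration.**  Scenes are converted to greyscale (equal
   band weights) and each source scene's mean grey level over a set of
   pseudo-invariant reference areas (dark lakes and fens, bright sandpits)
   is regressed against the same areas in a common target scene
   (`y = slope·x + intercept`, OLS); very-high-resolution mosaics get a
   second, local refinement that forces their coarse-scale aggregate onto
   the target cell-by-cell.
2. **Lichen mapping.**  Vegetation plots link field measurements to imagery:
   lichen volume `v = (c/100)·h` (c = 3-D cover %, h = mat height in mm, so
   v is in dm³ m⁻²) and dry biomass `b = 22·v` g m⁻² (22 g per dm³ of
   lichen).  Linear regressions of point-intercept 2-D cover and biomass on
   plot-scale grey level turn calibrated scenes into cover (%) and biomass
   (g m⁻² ≡ t km⁻²) maps, with negative predictions reclassified to zero
   and biomass capped at its value at the 100 %-cover grey level.  Zonal
   border comparisons, district means, a resolution-rescaling test, and a
   wMAPE validation (`Σ|O−S| / Σ|O|`) complete the mapping stage.
3. **District biomass model.**  Annual bookkeeping of district-mean biomass
   `b_t = b_{t−1} + g_{t−1} − e_{t−1} − w_{t−1}` with growth
   `g = f·(b·R(b) − b)` under the empirical relative growth law
   `R(b) = 1.95·b^(−0.1)`, a Jensen-type landscape factor `f ∈ (0, 1]`
   (mean pointwise growth over the biomass map divided by growth at the
   mean), metabolic intake `e = i·d` (i = 0.676 t per reindeer-year in a
   winter district, 0.338 t in mixed-use pastures; d = reindeer-years km⁻²),
   and density-proportional loss `w = b·d·l` (trampling and wastage).  The
   loss parameter `l` is fitted by bounded least squares against a
   reconstructed biomass history.

Because the historical imagery behind the original analysis is not
redistributable, a first-class synthetic-data module generates the study
conditions — bright clustered lichen patches on a darker matrix,
radiometrically stable reference areas, per-sensor affine distortion and
noise, pixel sizes from sub-metre to 60 m, and multi-decade census series —
so every stage is testable without any download.

## Worked example

The numbered drivers under `analysis/` run the whole study on the bundled
synthetic landscape (seed 1) and write their tables under `results/`:

```sh
python analysis/01_simulate_study_data.py 1
python analysis/02_fit_plot_regressions.py 1
python analysis/03_calibrate_and_map.py 1
python analysis/04_model_districts.py 1
python analysis/05_fit_loss_parameter.py 1
```

Excerpts of what they print, and what the numbers mean:

```
training fit (n=200): r2_cover=1.00, r2_biomass=0.82
held-out on the test site: r2_cover=0.99, r2_biomass=0.86
```

Grey level explains 2-D cover better than biomass — mat-height variation
decouples biomass from what the imagery sees.

```
border comparison, 10-km zone (side B / side A):
  1963: cover 16 % vs 27 %, ratio 1.73
  ...
rescaling coefficients (biomass vs native resolution):
    10 m: 1.00   30 m: 0.97   60 m: 0.88
```

Side B (the winter-pasture analogue, generated lichen-richer) keeps a cover
ratio above 1 throughout; coarsening the pixels loses small bright patches
below the detection threshold, so biomass estimates shrink monotonically
with pixel size.

```
fitted loss parameters against the reconstructed history:
  sideA: l = 0.091   sideB: l = 0.064
recovery check: noiseless l-hat = 0.0190 (truth 0.019); median error
under 10 % noise over 50 replicates = 4%
```

The year-round district needs a larger loss fraction than the winter-only
district, and the fitting machinery recovers a known loss parameter from
self-generated histories.

A `lichenline` CLI exposes the same stages (`simulate-data`, `calibrate`,
`map`, `validate`, `model simulate|fit`, `run-all`); see `lichenline --help`.

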