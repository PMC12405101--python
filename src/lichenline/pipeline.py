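"""End-to-end study pipeline over one seeded synthetic study area.

Stages, in dependency order:

1. two fine-resolution study sites (train/test) with vegetation plots and
   a drone mosaic calibrated to the common target scene in two steps;
2. plot regressions (grey -> 2-D cover, grey -> biomass) trained on the
   training site and evaluated held-out on the test site;
3. a district-scale landscape imaged through a multi-decade suite of
   sensors, each scene calibrated to the reference target via the
   pseudo-invariant reference areas;
4. cover/biomass maps per year, zonal border comparisons, district means,
   the resolution-rescaling test, and the wMAPE validation against the
   (synthetic) field-survey truth;
5. the district biomass model: landscape factors from the maps, censuses
   to reindeer-year densities, sensitivity and variant runs, and the
   loss-parameter fit against the reconstructed biomass history.

Every stage is a pure function of (config, seed); rerunning reproduces
each table bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import mapping as mp
from . import model as mdl
from . import synthetic as syn
from .rasters import Grid, polygon_mask

log = logging.getLogger("lichenline")


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PlatformSpec:
    """One row of the image-source table: platform, year, radiometry."""

    name: str
    year: int
    pixel_m: float
    gain: float
    offset: float
    noise_sd: float
    bands: tuple[str, ...] = ("R", "G", "B")
    coverage_fraction: float = 1.0
    truth_scale: float = 1.0     # lichen-cover multiplier of that year's truth


@dataclass
class PipelineConfig:
    seed: int = 0
    # district landscape
    district_kwargs: dict = field(default_factory=dict)
    platforms: list = field(default_factory=list)
    target_platform: str = "sentinel2_2020"
    # sites
    train_site_kwargs: dict = field(default_factory=dict)
    test_site_kwargs: dict = field(default_factory=dict)
    n_transects: int = 5
    plots_per_transect: int = 40
    # model
    model_years: tuple[int, int] = (1946, 2020)
    b0_values: tuple[float, ...] = (200.0, 400.0, 600.0)
    b0_fit: float = 200.0
    n_ft_points: int = 2000
    sideA_census: dict = field(default_factory=dict)
    sideB_census: dict = field(default_factory=dict)
    buffers: tuple[float, float] = (200.0, 10_000.0)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def default_config(seed: int = 0, scale: float = 1.0) -> PipelineConfig:
    """The bundled demo study: a declining lichen landscape imaged by a
    Table-2-like platform suite.  ``scale`` shrinks the domain for smoke
    tests (0 < scale <= 1)."""
    w, h = 4000.0 * scale, 3000.0 * scale
    platforms = [
        PlatformSpec("keyhole_1963", 1963, 40.0, 170.0, 12.0, 1.2,
                     ("R", "G", "B"), 1.0, truth_scale=1.00),
        PlatformSpec("landsat1_1973", 1973, 60.0, 120.0, 9.0, 1.0,
                     ("R", "G"), 1.0, truth_scale=0.82),
        PlatformSpec("landsat5_1992", 1992, 30.0, 2400.0, 260.0, 14.0,
                     ("R", "G", "B"), 0.95, truth_scale=0.52),
        PlatformSpec("landsat5_1997", 1997, 30.0, 2500.0, 240.0, 14.0,
                     ("R", "G", "B"), 0.75, truth_scale=0.40),
        PlatformSpec("sentinel2_2020", 2020, 10.0, 1.0, 0.0, 0.004,
                     ("R", "G", "B"), 1.0, truth_scale=0.45),
    ]
    site_common = dict(
        extent_m=(440.0, 400.0), base_pixel_m=0.25,
        lichen_patch_density=150.0, matrix_biomass=25.0,
        n_lakes=0, n_fens=0, n_sandpits=0,
        landcover_fractions={"heath": 0.95, "forest": 0.0,
                             "mire": 0.04, "water": 0.01},
        patch_radius_m=(15.0, 50.0), sideB_density_factor=1.6,
    )
    return PipelineConfig(
        seed=seed,
        district_kwargs=dict(extent_m=(w, h), base_pixel_m=5.0,
                             lichen_patch_density=25.0,
                             sideB_density_factor=1.8, seed=seed),
        platforms=platforms,
        train_site_kwargs={**site_common,
                           "patch_biomass_range": (250.0, 1300.0),
                           "seed": seed + 11},
        # the test site spans a narrower cover range, as held-out sites do
        test_site_kwargs={**site_common,
                          "patch_biomass_range": (150.0, 700.0),
                          "lichen_patch_density": 90.0,
                          "seed": seed + 23},
        sideA_census=dict(base_density=1.4, occupancy_days=365.0,
                          growth_rate=0.012,
                          shocks={1997: 0.80, 2000: 0.75},
                          area_km2=3557.0),
        sideB_census=dict(base_density=2.6, occupancy_days=157.0,
                          growth_rate=0.015,
                          shocks={1997: 0.78, 2000: 0.72},
                          area_km2=5808.0),
    )


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Load a config: a seed plus optional overrides of the demo study."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = default_config(seed=int(raw.get("seed", 0)),
                         scale=float(raw.get("scale", 1.0)))
    for key in ("n_transects", "plots_per_transect", "b0_fit", "n_ft_points"):
        if key in raw:
            setattr(cfg, key, type(getattr(cfg, key))(raw[key]))
    if "b0_values" in raw:
        cfg.b0_values = tuple(float(v) for v in raw["b0_values"])
    if "model_years" in raw:
        cfg.model_years = tuple(int(v) for v in raw["model_years"])
    if "district" in raw:
        cfg.district_kwargs.update(raw["district"])
    return cfg


# ---------------------------------------------------------------------------
# stage 1-2: sites and plot regressions

@dataclass
class SiteResult:
    name: str
    landscape: syn.TrueLandscape
    plots: pd.DataFrame          # includes grey_mean from the calibrated mosaic
    drone_model: cal.CalibrationModel


def build_site(name: str, site_kwargs: dict, cfg: PipelineConfig) -> SiteResult:
    """Site landscape, drone mosaic calibrated in two steps, plots with grey."""
    spec = syn.LandscapeSpec(**site_kwargs)
    land = syn.generate_landscape(spec)
    drone = syn.SensorSpec(name=f"drone_{name}", pixel_m=spec.base_pixel_m,
                           gain=0.92, offset=0.05, noise_sd=0.004,
                           year=2020)
    target_sensor = syn.SensorSpec(name=f"sentinel_{name}", pixel_m=10.0,
                                   gain=1.0, offset=0.0, noise_sd=0.002,
                                   year=2020)
    drone_grey = cal.to_greyscale(syn.render_scene(land, drone))
    target_grey = cal.to_greyscale(syn.render_scene(land, target_sensor))
    refined, model = cal.calibrate_drone(drone_grey, target_grey,
                                         seed=spec.seed)
    plots, _masks = syn.generate_plots(land, cfg.n_transects,
                                       cfg.plots_per_transect)
    plots["grey_mean"] = [
        mp.extract_plot_grey(refined, x, y)
        for x, y in zip(plots["x"], plots["y"])]
    plots["site"] = name
    return SiteResult(name=name, landscape=land, plots=plots,
                      drone_model=model)


def train_test_split_sites(plots: pd.DataFrame, train_site: str,
                           test_site: str) -> tuple[mp.LichenRegression, dict]:
    """Fit the lichen regressions on one site, evaluate held-out on another."""
    for s in (train_site, test_site):
        if s not in set(plots["site"]):
            raise ValueError(f"site {s!r} missing from the plot table")
    train = plots[plots["site"] == train_site]
    test = plots[plots["site"] == test_site]
    if test.empty:
        raise ValueError(f"test site {test_site!r} has no plots")
    reg = mp.fit_plot_regressions(train)
    held_out = mp.evaluate_regression(reg, test)
    return reg, held_out


# ---------------------------------------------------------------------------
# stage 3-4: district scenes, calibration, maps, comparisons

@dataclass
class YearMap:
    platform: PlatformSpec
    grey: Grid                   # calibrated greyscale scene
    map_pair: mp.LichenMapPair
    calibration: cal.CalibrationModel
    landcover: np.ndarray        # co-registered with the map grids
    truth_mean: dict             # side -> true district-mean biomass


def _aggregate_landcover(lc: np.ndarray, factor: int) -> np.ndarray:
    """Majority (modal) aggregation of the categorical landcover raster."""
    if factor == 1:
        return lc.copy()
    ny, nx = lc.shape
    ty, tx = (ny // factor) * factor, (nx // factor) * factor
    blocks = lc[:ty, :tx].reshape(ty // factor, factor, tx // factor, factor)
    counts = np.stack([(blocks == c).sum(axis=(1, 3))
                       for c in sorted(syn.LANDCOVER_NAMES)])
    return np.asarray(sorted(syn.LANDCOVER_NAMES))[counts.argmax(axis=0)]


def build_district_maps(cfg: PipelineConfig, reg: mp.LichenRegression
                        ) -> tuple[syn.TrueLandscape, list[YearMap],
                                   pd.DataFrame]:
    """Render, calibrate and map every platform year over the district."""
    base = syn.generate_landscape(syn.LandscapeSpec(**cfg.district_kwargs))
    target_platform = next(p for p in cfg.platforms
                           if p.name == cfg.target_platform)
    target_land = syn.scaled_landscape(base, target_platform.truth_scale)
    target_scene = syn.render_scene(target_land, _sensor(target_platform))
    target_grey = cal.to_greyscale(target_scene)
    target_means = cal.extract_reference_means(target_grey,
                                               base.reference_areas)
    rows, maps = [], []
    for plat in cfg.platforms:
        land_t = (target_land if plat.name == cfg.target_platform
                  else syn.scaled_landscape(base, plat.truth_scale))
        grey = cal.to_greyscale(syn.render_scene(land_t, _sensor(plat)))
        if plat.name == cfg.target_platform:
            model = cal.CalibrationModel(1.0, 0.0, 1.0,
                                         len(base.reference_areas),
                                         plat.name, plat.name)
            grey_cal = grey
        else:
            src_means = cal.extract_reference_means(grey, base.reference_areas)
            pairs = cal.pair_reference_means(src_means, target_means)
            model = cal.fit_calibration(pairs, source=plat.name,
                                        target=cfg.target_platform)
            grey_cal = cal.apply_calibration(grey, model)
        factor = int(round(plat.pixel_m / base.biomass.pixel))
        lc = _aggregate_landcover(base.landcover, factor)
        ny, nx = grey_cal.shape
        lc = lc[:ny, :nx]
        pair = mp.predict_maps(grey_cal, reg, landcover=lc)
        truth_mean = {}
        for side, poly in base.districts.items():
            m = polygon_mask(land_t.biomass, poly)
            m &= ~np.isin(base.landcover, [syn.FOREST, syn.WATER, syn.SAND])
            truth_mean[side] = float(land_t.biomass.values[m].mean())
        maps.append(YearMap(platform=plat, grey=grey_cal, map_pair=pair,
                            calibration=model, landcover=lc,
                            truth_mean=truth_mean))
        rows.append({"platform": plat.name, "year": plat.year,
                     "pixel_m": plat.pixel_m,
                     "slope": model.slope, "intercept": model.intercept,
                     "r_squared": model.r_squared, "n_areas": model.n_areas})
        log.info("mapped %s (%d): calib R^2=%.3f", plat.name, plat.year,
                 model.r_squared)
    return base, maps, pd.DataFrame(rows)


def _sensor(plat: PlatformSpec) -> syn.SensorSpec:
    return syn.SensorSpec(name=plat.name, pixel_m=plat.pixel_m,
                          gain=plat.gain, offset=plat.offset,
                          noise_sd=plat.noise_sd, bands=tuple(plat.bands),
                          year=plat.year,
                          coverage_fraction=plat.coverage_fraction)


# ---------------------------------------------------------------------------
# stage 5: the district biomass model

def _census_to_densities(census_kwargs: dict, years, seed: int) -> dict:
    trend = syn.CensusTrend(growth_rate=census_kwargs.get("growth_rate", 0.0),
                            shock_multipliers=census_kwargs.get("shocks", {}),
                            noise_cv=census_kwargs.get("noise_cv", 0.0))
    census = syn.generate_census(
        years, base_density=census_kwargs["base_density"],
        area_km2=census_kwargs["area_km2"],
        occupancy_days=census_kwargs["occupancy_days"],
        trend=trend, seed=seed)
    return {c.year: mdl.reindeer_year_density(c.count, c.area_km2,
                                              c.occupancy_days)
            for c in census}


def sample_landscape_factor(map_pair: mp.LichenMapPair, polygon,
                            params: mdl.ModelParams, n_points: int,
                            rng: np.random.Generator) -> float:
    """Landscape growth factor from random points on a biomass map."""
    m = polygon_mask(map_pair.biomass, polygon) & ~map_pair.biomass.mask
    idx = np.flatnonzero(m)
    if idx.size == 0:
        raise ValueError("no valid map cells inside the district polygon")
    pick = rng.choice(idx, size=min(n_points, idx.size), replace=False)
    sample = map_pair.biomass.values.ravel()[pick]
    return mdl.landscape_factor(sample, params)


@dataclass
class RunReport:
    seed: int
    config_hash: str
    calibration_table: pd.DataFrame
    regression: mp.LichenRegression
    held_out: dict
    zone_comparisons: pd.DataFrame
    district_means: pd.DataFrame
    rescale_table: pd.DataFrame
    ft_table: pd.DataFrame
    trajectories: pd.DataFrame
    loss_fits: pd.DataFrame
    wmape: dict


def run_all(cfg: PipelineConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute every stage in dependency order and assemble the report."""
    log.info("run_all: seed=%d hash=%s", cfg.seed, cfg.config_hash())
    train = build_site("train", cfg.train_site_kwargs, cfg)
    test = build_site("test", cfg.test_site_kwargs, cfg)
    plots = pd.concat([train.plots, test.plots], ignore_index=True)
    reg, held_out = train_test_split_sites(plots, "train", "test")
    log.info("plot regressions: r2_cover=%.2f r2_biomass=%.2f held-out "
             "r2_cover=%.2f", reg.r2_cover, reg.r2_biomass,
             held_out["r2_cover"])

    base, year_maps, calib_table = build_district_maps(cfg, reg)

    zone_rows, dm_rows = [], []
    for ym in year_maps:
        # the border comparison drops mires as well, like-for-like zones
        pair_cmp = mp.predict_maps(ym.grey, reg, landcover=ym.landcover,
                                   exclude=mp.COMPARISON_EXCLUDE)
        for zc in mp.zonal_comparison(pair_cmp, base.border_line,
                                      base.districts, cfg.buffers):
            zone_rows.append({
                "year": zc.year, "buffer_m": zc.buffer_m,
                "cover_sideA": zc.mean_cover_sideA,
                "cover_sideB": zc.mean_cover_sideB,
                "biomass_sideA": zc.mean_biomass_sideA,
                "biomass_sideB": zc.mean_biomass_sideB,
                "cover_ratio": zc.cover_ratio,
                "biomass_ratio": zc.biomass_ratio})
        for side, poly in base.districts.items():
            for include_mires in (True, False):
                dm_rows.append({
                    "year": ym.platform.year, "side": side,
                    "include_mires": include_mires,
                    "mean_biomass_t_km2": mp.district_mean(
                        ym.map_pair, poly, ym.landcover, include_mires),
                    "truth_mean_t_km2": ym.truth_mean[side]})
    zone_table = pd.DataFrame(zone_rows)
    dm_table = pd.DataFrame(dm_rows)

    # resolution-rescaling test on the finest (target) scene
    target_ym = next(ym for ym in year_maps
                     if ym.platform.name == cfg.target_platform)
    rescale = mp.rescale_coefficients(target_ym.grey, reg,
                                      landcover=target_ym.landcover,
                                      target_pixels=(30.0, 60.0))

    # wMAPE of the reconstructed district means against the survey truth
    wmape_by_side = {}
    for side in base.districts:
        sub = dm_table[(dm_table["side"] == side) & dm_table["include_mires"]]
        wmape_by_side[side] = mp.wmape(sub["truth_mean_t_km2"],
                                       sub["mean_biomass_t_km2"])

    # landscape factors at mapped years, interpolated to the model span
    params = mdl.ModelParams()
    rng = np.random.default_rng(cfg.seed + 101)
    years = list(range(cfg.model_years[0], cfg.model_years[1] + 1))
    ft_rows = []
    fts = {}
    for side, poly in base.districts.items():
        anchors = {}
        for ym in year_maps:
            try:
                anchors[ym.platform.year] = sample_landscape_factor(
                    ym.map_pair, poly, params, cfg.n_ft_points, rng)
            except ValueError:
                continue
        fts[side] = mdl.interpolate_factor(anchors, years)
        for y, f in anchors.items():
            ft_rows.append({"side": side, "year": y, "f_t": f,
                            "provenance": "computed"})
    ft_table = pd.DataFrame(ft_rows)

    densities = {
        "sideA": _census_to_densities(cfg.sideA_census, years, cfg.seed + 3),
        "sideB": _census_to_densities(cfg.sideB_census, years, cfg.seed + 5)}
    intake = {"sideA": 0.338, "sideB": 0.676}

    traj_frames, fit_rows = [], []
    for side in base.districts:
        obs = {ym.platform.year: mp.district_mean(
            ym.map_pair, base.districts[side], ym.landcover, True)
            for ym in year_maps if ym.platform.year in densities[side]}
        from dataclasses import replace as _replace
        p_side = _replace(params, intake_t_per_reindeer_year=intake[side])
        fit = mdl.fit_loss_parameter(obs, cfg.b0_fit, densities[side],
                                     fts[side], p_side)
        fit_rows.append({"side": side, "loss_factor": fit.loss_factor,
                         "sse": fit.sse, "n_obs": fit.n_obs})
        p_fit = _replace(p_side, loss_factor=fit.loss_factor)
        for b0 in cfg.b0_values:
            for variant in mdl.VARIANTS:
                tr = mdl.simulate(b0, years, densities[side], fts[side],
                                  p_fit, variant)
                tr["side"] = side
                tr["b0"] = b0
                traj_frames.append(tr)
        log.info("loss fit %s: l=%.4f (sse=%.1f)", side, fit.loss_factor,
                 fit.sse)
    trajectories = pd.concat(traj_frames, ignore_index=True)
    loss_fits = pd.DataFrame(fit_rows)

    report = RunReport(
        seed=cfg.seed, config_hash=cfg.config_hash(),
        calibration_table=calib_table, regression=reg, held_out=held_out,
        zone_comparisons=zone_table, district_means=dm_table,
        rescale_table=rescale, ft_table=ft_table,
        trajectories=trajectories, loss_fits=loss_fits,
        wmape=wmape_by_side)
    if out_dir is not None:
        write_report(report, out_dir, cfg)
    return report


def write_report(report: RunReport, out_dir: str | Path,
                 cfg: PipelineConfig | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.calibration_table.to_csv(out / "calibration_table.csv", index=False)
    report.zone_comparisons.to_csv(out / "zone_comparisons.csv", index=False)
    report.district_means.to_csv(out / "district_means.csv", index=False)
    report.rescale_table.to_csv(out / "rescale_table.csv", index=False)
    report.ft_table.to_csv(out / "landscape_factors.csv", index=False)
    report.trajectories.to_csv(out / "trajectories.csv", index=False)
    report.loss_fits.to_csv(out / "loss_fits.csv", index=False)
    summary = {
        "seed": report.seed,
        "config_hash": report.config_hash,
        "regression": {
            "cover_slope": report.regression.cover_slope,
            "cover_intercept": report.regression.cover_intercept,
            "biomass_slope": report.regression.biomass_slope,
            "biomass_intercept": report.regression.biomass_intercept,
            "zero_cross_grey": report.regression.zero_cross_grey,
            "cap_biomass_g_m2": report.regression.cap_biomass_g_m2,
            "r2_cover": report.regression.r2_cover,
            "r2_biomass": report.regression.r2_biomass,
        },
        "held_out": report.held_out,
        "wmape": report.wmape,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    if cfg is not None:
        (out / "config_echo.yaml").write_text(
            yaml.safe_dump(json.loads(json.dumps(asdict(cfg), default=str))))
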