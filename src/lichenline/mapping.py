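"""Plot-trained lichen cover/biomass regressions and landscape statistics.

The field link: a 0.25 m^2 plot's lichen volume is v = (c/100) * h with c
the summed 3-D cover (%) and h the mat height (mm), so v is in dm^3 m^-2,
and dry biomass is b = 22 v (g m^-2, 22 g per dm^3 of lichen).  Linear
regressions of point-intercept 2-D cover and of biomass on the plot-scale
grey level turn calibrated greyscale scenes into cover (%) and biomass
(g m^-2 == t km^-2) maps.  Predicted cover below the zero-crossing grey
value is reclassified to zero and biomass is capped at its value at the
grey level where predicted cover reaches 100 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from shapely import contains_xy

from .rasters import Grid
from . import synthetic as syn

LICHEN_DENSITY_G_PER_DM3 = syn.LICHEN_DENSITY_G_PER_DM3

#: forests shade the signal, water is dark, bare sand is as bright as a
#: full lichen mat — all three are masked from every map
DEFAULT_EXCLUDE = frozenset({"forest", "water", "sand"})
#: border comparisons additionally drop mires to keep the zones comparable
COMPARISON_EXCLUDE = frozenset({"forest", "water", "sand", "mire"})


def plot_volume(cover3d_pct: float, height_mm: float) -> float:
    """Lichen volume (dm^3 m^-2) of one plot: (cover/100) * height.

    The cover enters as a fraction: 100 % cover of a 50 mm mat over 1 m^2
    is 50 dm^3, which at 22 g dm^-3 gives the familiar mat biomasses.
    """
    if cover3d_pct < 0 or height_mm < 0:
        raise ValueError("cover and height must be non-negative")
    return (cover3d_pct / 100.0) * height_mm


def plot_biomass(volume_dm3_m2: float) -> float:
    """Dry biomass (g m^-2) from volume at 22 g per dm^3 of lichen."""
    return LICHEN_DENSITY_G_PER_DM3 * volume_dm3_m2


def point_intercept_cover(mask_image: np.ndarray, grid_n: int = 100) -> float:
    """2-D cover (%) by systematic crosshairs over a binary plot image.

    Crosshairs sit at the cell centres of a sqrt(n) x sqrt(n) grid laid
    over the image; the hit fraction maps linearly to cover (50 of 100
    hits = 50 % cover).
    """
    mask = np.asarray(mask_image)
    if mask.size == 0:
        raise ValueError("empty plot image")
    g = int(round(np.sqrt(grid_n)))
    if g * g != grid_n:
        raise ValueError("grid_n must be a perfect square")
    ny, nx = mask.shape
    ii = ((np.arange(g) + 0.5) * ny / g).astype(int)
    jj = ((np.arange(g) + 0.5) * nx / g).astype(int)
    hits = int(mask[np.ix_(ii, jj)].astype(bool).sum())
    return 100.0 * hits / grid_n


def extract_plot_grey(grey: Grid, x: float, y: float,
                      radius: float = 0.35) -> float:
    """Mean grey in a disc of radius ``radius`` m around a plot centre.

    Pixels count when their centres fall in the disc; if the disc is
    smaller than a pixel the containing pixel's value is returned.
    """
    r_px = int(np.ceil(radius / grey.pixel)) + 1
    j = int((x - grey.x0) / grey.pixel)
    i = int((grey.y0 - y) / grey.pixel)
    ny, nx = grey.shape
    i0, i1 = max(0, i - r_px), min(ny, i + r_px + 1)
    j0, j1 = max(0, j - r_px), min(nx, j + r_px + 1)
    xs = grey.x0 + (np.arange(j0, j1) + 0.5) * grey.pixel
    ys = grey.y0 - (np.arange(i0, i1) + 0.5) * grey.pixel
    X, Y = np.meshgrid(xs, ys)
    inside = (X - x) ** 2 + (Y - y) ** 2 <= radius ** 2
    vals = grey.values[i0:i1, j0:j1][inside]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float(grey.values[np.clip(i, 0, ny - 1), np.clip(j, 0, nx - 1)])
    return float(vals.mean())


@dataclass
class LichenRegression:
    """Fitted grey -> cover and grey -> biomass linear maps."""

    cover_slope: float
    cover_intercept: float
    biomass_slope: float
    biomass_intercept: float
    r2_cover: float
    r2_biomass: float
    p_cover: float = float("nan")
    p_biomass: float = float("nan")
    n_plots: int = 0

    @property
    def zero_cross_grey(self) -> float:
        """Grey value below which predicted cover is negative."""
        return -self.cover_intercept / self.cover_slope

    @property
    def grey_at_full_cover(self) -> float:
        return (100.0 - self.cover_intercept) / self.cover_slope

    @property
    def cap_biomass_g_m2(self) -> float:
        """Biomass ceiling: the biomass regression evaluated at the grey
        level where predicted cover reaches 100 %."""
        return self.biomass_slope * self.grey_at_full_cover + self.biomass_intercept


def fit_plot_regressions(plots: pd.DataFrame,
                         grey_col: str = "grey_mean") -> LichenRegression:
    """Two independent OLS fits: cover2d ~ grey and biomass ~ grey."""
    df = plots.dropna(subset=[grey_col, "cover2d_pct", "biomass_g_m2"])
    if len(df) < 3:
        raise ValueError("need at least three plots")
    x = np.asarray(df[grey_col], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: constant grey values")
    X = sm.add_constant(x)
    rc = sm.OLS(np.asarray(df["cover2d_pct"], dtype=float), X).fit()
    rb = sm.OLS(np.asarray(df["biomass_g_m2"], dtype=float), X).fit()
    if rc.params[1] <= 0:
        raise ValueError("cover regression slope must be positive "
                         "(lichen must brighten the scene)")
    return LichenRegression(
        cover_slope=float(rc.params[1]), cover_intercept=float(rc.params[0]),
        biomass_slope=float(rb.params[1]), biomass_intercept=float(rb.params[0]),
        r2_cover=float(rc.rsquared), r2_biomass=float(rb.rsquared),
        p_cover=float(rc.f_pvalue), p_biomass=float(rb.f_pvalue),
        n_plots=len(df))


def evaluate_regression(reg: LichenRegression, plots: pd.DataFrame,
                        grey_col: str = "grey_mean") -> dict:
    """Held-out R^2 of the fitted maps on an independent plot set."""
    out = {}
    x = np.asarray(plots[grey_col], dtype=float)
    for name, slope, icpt, col in (
            ("cover", reg.cover_slope, reg.cover_intercept, "cover2d_pct"),
            ("biomass", reg.biomass_slope, reg.biomass_intercept, "biomass_g_m2")):
        obs = np.asarray(plots[col], dtype=float)
        pred = slope * x + icpt
        ss_res = float(((obs - pred) ** 2).sum())
        ss_tot = float(((obs - obs.mean()) ** 2).sum())
        out[f"r2_{name}"] = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    out["n_plots"] = len(plots)
    return out


@dataclass
class LichenMapPair:
    """Co-registered cover (%) and biomass (g m^-2) maps for one year."""

    cover: Grid
    biomass: Grid
    year: int
    excluded_mask: np.ndarray = field(default=None)


def predict_maps(grey: Grid, reg: LichenRegression,
                 landcover: np.ndarray | None = None,
                 exclude: frozenset = DEFAULT_EXCLUDE) -> LichenMapPair:
    """Predict cover and biomass maps from a calibrated greyscale scene.

    Cover is clamped to [0, 100]; biomass to [0, cap] and forced to zero
    wherever cover is zero (grey below the zero-crossing).  Cells of
    excluded landcover classes become nodata with the exclusion recorded.
    """
    g = grey.values
    cover = np.clip(reg.cover_slope * g + reg.cover_intercept, 0.0, 100.0)
    cap = reg.cap_biomass_g_m2
    biomass = np.clip(reg.biomass_slope * g + reg.biomass_intercept, 0.0, cap)
    biomass = np.where(cover <= 0.0, 0.0, biomass)
    if landcover is None:
        if exclude:
            import warnings
            warnings.warn("no landcover supplied; maps produced without exclusions")
        excluded = np.zeros(g.shape, dtype=bool)
    else:
        code_of = {v: k for k, v in syn.LANDCOVER_NAMES.items()}
        excluded = np.isin(landcover, [code_of[c] for c in exclude])
    cover = np.where(excluded, np.nan, cover)
    biomass = np.where(excluded, np.nan, biomass)
    year = int(grey.meta.get("year", 0))
    return LichenMapPair(
        cover=grey.copy_with(cover, layer="cover2d_pct"),
        biomass=grey.copy_with(biomass, layer="biomass_g_m2"),
        year=year, excluded_mask=excluded)


@dataclass
class ZoneComparison:
    buffer_m: float
    year: int
    mean_cover_sideA: float
    mean_cover_sideB: float
    mean_biomass_sideA: float
    mean_biomass_sideB: float

    @property
    def cover_ratio(self) -> float:
        """side B / side A (B = the winter-pasture analogue)."""
        return self.mean_cover_sideB / self.mean_cover_sideA

    @property
    def biomass_ratio(self) -> float:
        return self.mean_biomass_sideB / self.mean_biomass_sideA


def zonal_comparison(map_pair: LichenMapPair, border_line, sides: dict,
                     buffers=(200.0, 10_000.0)) -> list[ZoneComparison]:
    """Mean cover/biomass per side within each buffer of the border.

    A cell belongs to a zone when its centre lies within the Euclidean
    buffer of the line and inside that side's polygon; excluded/nodata
    cells never contribute.  Ratios are side B over side A.
    """
    X, Y = map_pair.cover.cell_centers()
    xs, ys = X.ravel(), Y.ravel()
    side_masks = {s: contains_xy(poly, xs, ys).reshape(X.shape)
                  for s, poly in sides.items()}
    out = []
    for buf in buffers:
        zone = contains_xy(border_line.buffer(buf), xs, ys).reshape(X.shape)
        means = {}
        for s in ("sideA", "sideB"):
            m = zone & side_masks[s] & ~map_pair.cover.mask
            if not m.any():
                means[s] = (float("nan"), float("nan"))
                continue
            means[s] = (float(map_pair.cover.values[m].mean()),
                        float(map_pair.biomass.values[m].mean()))
        out.append(ZoneComparison(
            buffer_m=float(buf), year=map_pair.year,
            mean_cover_sideA=means["sideA"][0], mean_cover_sideB=means["sideB"][0],
            mean_biomass_sideA=means["sideA"][1], mean_biomass_sideB=means["sideB"][1]))
    return out


def district_mean(map_pair: LichenMapPair, polygon,
                  landcover: np.ndarray | None = None,
                  include_mires: bool = True) -> float:
    """Mean biomass (t km^-2 == g m^-2) over a district polygon.

    Forests and water are always excluded; mires enter or leave the mean
    according to ``include_mires`` (herding-district level estimates keep
    them, cross-border comparisons drop them).
    """
    from .rasters import polygon_mask
    m = polygon_mask(map_pair.biomass, polygon) & ~map_pair.biomass.mask
    if landcover is not None:
        m &= ~np.isin(landcover, [syn.FOREST, syn.WATER])
        if not include_mires:
            m &= landcover != syn.MIRE
    if not m.any():
        raise ValueError("polygon contains no valid cells")
    return float(map_pair.biomass.values[m].mean())


def rescale_coefficients(grey: Grid, reg: LichenRegression,
                         landcover: np.ndarray | None = None,
                         target_pixels=(10.0, 30.0, 60.0),
                         exclude: frozenset = DEFAULT_EXCLUDE) -> pd.DataFrame:
    """Mean-biomass ratio of coarsened scenes to the native resolution.

    The greyscale is mean-aggregated to each coarser pixel size (exclusions
    applied first as nodata), biomass is predicted per resolution, and the
    coefficient is biomass(coarse) / biomass(native).  On patchy scenes the
    clamping at the zero-crossing makes the coefficient fall below 1: small
    bright patches averaged into dark pixels drop out of detection.
    """
    from .rasters import block_aggregate
    if landcover is None:
        exclude = frozenset()
    native = predict_maps(grey, reg, landcover, exclude)
    base_mean = float(np.nanmean(native.biomass.values))
    g0 = grey.copy_with(np.where(native.excluded_mask, np.nan, grey.values))
    rows = [{"pixel_m": grey.pixel, "mean_biomass_g_m2": base_mean,
             "coefficient": 1.0}]
    for p in target_pixels:
        factor = p / grey.pixel
        if abs(factor - round(factor)) > 1e-9 or factor < 1:
            raise ValueError(f"target pixel {p} not a multiple of native "
                             f"{grey.pixel}")
        coarse = block_aggregate(g0, int(round(factor)))
        pair = predict_maps(coarse, reg, landcover=None,
                            exclude=frozenset())
        mean_b = float(np.nanmean(pair.biomass.values))
        rows.append({"pixel_m": p, "mean_biomass_g_m2": mean_b,
                     "coefficient": mean_b / base_mean})
    return pd.DataFrame(rows)


def wmape(observed, reconstructed) -> float:
    """Weighted mean absolute percent error: sum|O-S| / sum|O|."""
    o = np.asarray(observed, dtype=float)
    s = np.asarray(reconstructed, dtype=float)
    denom = np.abs(o).sum()
    if denom == 0:
        raise ValueError("observed series is all zero")
    return float(np.abs(o - s).sum() / denom)
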