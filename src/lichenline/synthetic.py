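"""Seeded synthetic landscapes, scenes, vegetation plots and reindeer censuses.

The generator emulates a subarctic fell landscape split by a border fence:
bright forage-lichen patches on a darker heath matrix, radiometrically
stable dark (lakes, open fens) and bright (sand) reference features, and a
richer lichen cover on the winter-pasture side of the fence.  Scenes are
rendered from the ground truth through per-sensor affine radiometric
distortion plus additive noise, at pixel sizes from drone (sub-metre) to
coarse satellite (60 m).  Everything is a pure function of (spec, seed).

Ground-truth consistency: biomass (g m^-2) = 22 * (cover/100) * height(mm)
everywhere, with a per-patch lichen-mat height field; water and mire carry
zero lichen.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon, box

from .rasters import Grid

LICHEN_DENSITY_G_PER_DM3 = 22.0

#: landcover codes
HEATH, FOREST, MIRE, WATER, SAND = 0, 1, 2, 3, 4
LANDCOVER_NAMES = {HEATH: "heath", FOREST: "forest", MIRE: "mire",
                   WATER: "water", SAND: "sand"}

# intrinsic surface reflectance (dimensionless, 0-1) of the stable classes
REFL_WATER = (0.02, 0.06)
REFL_FEN = (0.05, 0.10)
REFL_SAND = (0.55, 0.70)
#: piecewise-linear vegetated endmembers: dark matrix at 0 % lichen cover,
#: bright full lichen mat at 100 %
REFL_VEG_DARK = 0.12
REFL_LICHEN_BRIGHT = 0.55
REFL_FOREST = 0.10


@dataclass
class LandscapeSpec:
    """Parameters of one synthetic landscape realisation."""

    extent_m: tuple[float, float] = (4000.0, 3000.0)
    base_pixel_m: float = 5.0
    lichen_patch_density: float = 12.0        # patches per km^2 (side A)
    patch_biomass_range: tuple[float, float] = (300.0, 1250.0)   # g m^-2
    matrix_biomass: float = 30.0              # g m^-2
    n_lakes: int = 24
    n_fens: int = 9
    n_sandpits: int = 15
    border_x: float | None = None             # defaults to mid-extent
    landcover_fractions: dict = field(default_factory=lambda: {
        "heath": 0.30, "forest": 0.38, "mire": 0.28, "water": 0.04})
    seed: int = 0
    # gap parameters (documented in docs/methods.md)
    height_range_mm: tuple[float, float] = (25.0, 60.0)   # per-patch mat height
    matrix_height_mm: float = 20.0
    patch_radius_m: tuple[float, float] = (20.0, 70.0)
    sideB_density_factor: float = 1.6         # lichen richer on the winter-pasture side

    def __post_init__(self) -> None:
        w, h = self.extent_m
        if w <= 0 or h <= 0 or self.base_pixel_m <= 0:
            raise ValueError("extents and pixel size must be positive")
        total = sum(self.landcover_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("landcover fractions must sum to 1")
        lo, hi = self.patch_biomass_range
        cap = LICHEN_DENSITY_G_PER_DM3 * self.height_range_mm[1]  # 100 % cover cap
        if not (0 <= lo <= hi <= cap):
            raise ValueError(
                f"patch_biomass_range must lie within [0, {cap:g}] "
                "(100 % cover at the maximum mat height)")
        if self.border_x is None:
            self.border_x = w / 2.0


@dataclass
class RefArea:
    area_id: str
    kind: str            # lake | fen | sand
    cls: str             # dark | bright
    polygon: Polygon
    reflectance: float   # intrinsic, temporally invariant


@dataclass
class TrueLandscape:
    """Unobservable ground truth the mapping chain is tested against."""

    spec: LandscapeSpec
    biomass: Grid        # g m^-2
    cover: Grid          # 2-D cover %
    height: Grid         # lichen mat height, mm
    landcover: np.ndarray  # int codes, same shape as biomass
    reference_areas: list[RefArea]
    border_line: LineString
    districts: dict      # {"sideA": Polygon, "sideB": Polygon}

    _reflectance_cache: np.ndarray | None = field(default=None, repr=False,
                                                  compare=False)

    @property
    def reflectance(self) -> np.ndarray:
        """Intrinsic reflectance field implied by cover and landcover."""
        if self._reflectance_cache is not None:
            return self._reflectance_cache
        refl = REFL_VEG_DARK + (REFL_LICHEN_BRIGHT - REFL_VEG_DARK) * (
            self.cover.values / 100.0)
        lc = self.landcover
        refl = np.where(lc == FOREST, REFL_FOREST, refl)
        refl = np.where(lc == WATER, np.mean(REFL_WATER), refl)
        refl = np.where(lc == MIRE, np.mean(REFL_FEN), refl)
        refl = np.where(lc == SAND, np.mean(REFL_SAND), refl)
        # reference features carry their own fixed per-area reflectance
        from .rasters import polygon_mask
        for area in self.reference_areas:
            m = polygon_mask(self.biomass, area.polygon)
            refl[m] = area.reflectance
        self._reflectance_cache = refl
        return refl


@dataclass
class SensorSpec:
    """Affine radiometric response of one imaging platform."""

    name: str
    pixel_m: float
    gain: float = 1.0
    offset: float = 0.0
    noise_sd: float = 0.0
    bands: tuple[str, ...] = ("R", "G", "B")
    year: int = 2020
    coverage_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_m <= 0:
            raise ValueError("pixel_m must be positive")
        if self.gain == 0:
            raise ValueError("gain must be non-zero")
        if not (0 < self.coverage_fraction <= 1):
            raise ValueError("coverage_fraction must be in (0, 1]")
        if not self.bands:
            raise ValueError("sensor needs at least one band")


@dataclass
class Scene:
    """Rendered multi-band scene: band name -> 2-D array, shared geometry."""

    bands: dict
    x0: float
    y0: float
    pixel: float
    sensor: SensorSpec

    def band_grid(self, name: str) -> Grid:
        return Grid(self.bands[name], self.x0, self.y0, self.pixel,
                    {"band": name, "source": self.sensor.name,
                     "year": self.sensor.year})


@dataclass
class ReindeerCensus:
    year: int
    count: float
    area_km2: float
    occupancy_days: float

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if not (0 <= self.occupancy_days <= 365):
            raise ValueError("occupancy_days must be within [0, 365]")


# ---------------------------------------------------------------------------
# landscape generation

def _smooth_field(rng: np.random.Generator, shape, sigma_px: float) -> np.ndarray:
    """Smoothed Gaussian random field; computed decimated when the
    correlation length is large relative to the pixel, then upsampled."""
    dec = max(1, int(sigma_px / 8.0))
    cy = max(4, -(-shape[0] // dec))
    cx = max(4, -(-shape[1] // dec))
    u = ndimage.gaussian_filter(rng.standard_normal((cy, cx)),
                                sigma=max(1.0, sigma_px / dec))
    if dec == 1:
        return u[:shape[0], :shape[1]]
    u = ndimage.zoom(u, dec, order=1)
    return u[:shape[0], :shape[1]]


def _place_ellipses(rng, n, kind, r_range, domain: Polygon, occupied,
                    max_tries=4000):
    """Rejection-place non-overlapping elliptical reference features."""
    placed = []
    minx, miny, maxx, maxy = domain.bounds
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"domain too small to place {n} non-overlapping '{kind}' "
                f"reference areas of radius {r_range} m")
        cx = rng.uniform(minx, maxx)
        cy = rng.uniform(miny, maxy)
        rx = rng.uniform(*r_range)
        ry = rx * rng.uniform(0.6, 1.0)
        ang = rng.uniform(0, math.pi)
        ell = _ellipse(cx, cy, rx, ry, ang)
        if not domain.contains(ell):
            continue
        if any(ell.distance(o) < 10.0 for o in occupied):
            continue
        occupied.append(ell)
        placed.append(ell)
    return placed


def _ellipse(cx, cy, rx, ry, ang, n=24) -> Polygon:
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    x = rx * np.cos(t)
    y = ry * np.sin(t)
    xr = cx + x * math.cos(ang) - y * math.sin(ang)
    yr = cy + x * math.sin(ang) + y * math.cos(ang)
    return Polygon(np.column_stack([xr, yr]))


def generate_landscape(spec: LandscapeSpec) -> TrueLandscape:
    """Build the ground truth: landcover, reference areas, lichen fields.

    Deterministic for a fixed spec (including its seed).  Lichen patches are
    clustered discs confined to heath; reference features override the
    landcover and never intersect each other.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.extent_m
    px = spec.base_pixel_m
    nx, ny = int(round(w / px)), int(round(h / px))
    if nx < 4 or ny < 4:
        raise ValueError("domain too small for the requested pixel size")
    x0, y0 = 0.0, h

    # --- landcover from a smoothed random field, thresholded by fractions
    u = _smooth_field(rng, (ny, nx), sigma_px=max(2.0, 150.0 / px))
    fr = spec.landcover_fractions
    qs = np.quantile(u, [fr.get("water", 0),
                         fr.get("water", 0) + fr.get("mire", 0),
                         fr.get("water", 0) + fr.get("mire", 0) + fr.get("forest", 0)])
    landcover = np.full((ny, nx), HEATH, dtype=int)
    landcover[u <= qs[0]] = WATER
    landcover[(u > qs[0]) & (u <= qs[1])] = MIRE
    landcover[(u > qs[1]) & (u <= qs[2])] = FOREST

    # --- reference features (pseudo-invariant): lakes, fens, sandpits
    margin = 30.0
    domain = box(margin, margin, w - margin, h - margin)
    occupied: list[Polygon] = []
    lakes = _place_ellipses(rng, spec.n_lakes, "lake", (60.0, 110.0), domain, occupied)
    fens = _place_ellipses(rng, spec.n_fens, "fen", (25.0, 40.0), domain, occupied)
    sands = _place_ellipses(rng, spec.n_sandpits, "sand", (25.0, 40.0), domain, occupied)

    template = Grid(np.zeros((ny, nx)), x0, y0, px)
    from .rasters import polygon_mask
    reference_areas: list[RefArea] = []
    for kind, cls, polys, code, refl_rng in (
            ("lake", "dark", lakes, WATER, REFL_WATER),
            ("fen", "dark", fens, MIRE, REFL_FEN),
            ("sand", "bright", sands, SAND, REFL_SAND)):
        for i, poly in enumerate(polys):
            landcover[polygon_mask(template, poly)] = code
            reference_areas.append(RefArea(
                area_id=f"{kind}_{i:02d}", kind=kind, cls=cls, polygon=poly,
                reflectance=float(rng.uniform(*refl_rng))))

    # --- lichen fields on heath
    cover = np.zeros((ny, nx))
    height = np.zeros((ny, nx))
    heath = landcover == HEATH
    m_h = spec.matrix_height_mm
    matrix_cover = 100.0 * spec.matrix_biomass / (LICHEN_DENSITY_G_PER_DM3 * m_h)
    if matrix_cover > 100:
        raise ValueError("matrix_biomass exceeds full cover at matrix height")
    cover[heath] = matrix_cover
    height[heath] = m_h

    area_km2 = (w * h) / 1e6
    n_patches = int(round(spec.lichen_patch_density * area_km2))
    if n_patches > 0:
        # Thomas-like clustering: parents, then offspring scattered nearby
        n_parents = max(1, n_patches // 3)
        par = np.column_stack([rng.uniform(0, w, n_parents),
                               rng.uniform(0, h, n_parents)])
        idx = rng.integers(0, n_parents, n_patches)
        centers = par[idx] + rng.normal(0, 180.0, (n_patches, 2))
        X, Y = template.cell_centers()
        for k in range(n_patches):
            cx, cy = centers[k]
            if not (0 <= cx <= w and 0 <= cy <= h):
                continue
            # bias richness toward side B (the winter-pasture analogue)
            if cx >= spec.border_x:
                if rng.random() > min(1.0, spec.sideB_density_factor / max(
                        spec.sideB_density_factor, 1.0)):
                    continue
            else:
                keep = 1.0 / spec.sideB_density_factor if spec.sideB_density_factor > 1 else 1.0
                if rng.random() > keep:
                    continue
            r = rng.uniform(*spec.patch_radius_m)
            h_p = rng.uniform(*spec.height_range_mm)
            b_p = rng.uniform(*spec.patch_biomass_range)
            c_p = min(95.0, 100.0 * b_p / (LICHEN_DENSITY_G_PER_DM3 * h_p))
            sel = heath & ((X - cx) ** 2 + (Y - cy) ** 2 <= r * r)
            grow = sel & (c_p > cover)
            cover[grow] = c_p
            height[grow] = h_p

    biomass = LICHEN_DENSITY_G_PER_DM3 * (cover / 100.0) * height

    border = LineString([(spec.border_x, 0.0), (spec.border_x, h)])
    districts = {"sideA": box(0, 0, spec.border_x, h),
                 "sideB": box(spec.border_x, 0, w, h)}
    return TrueLandscape(
        spec=spec,
        biomass=Grid(biomass, x0, y0, px, {"layer": "biomass_g_m2"}),
        cover=Grid(cover, x0, y0, px, {"layer": "cover2d_pct"}),
        height=Grid(height, x0, y0, px, {"layer": "height_mm"}),
        landcover=landcover,
        reference_areas=reference_areas,
        border_line=border,
        districts=districts,
    )


def scaled_landscape(landscape: TrueLandscape, factor: float) -> TrueLandscape:
    """Ground truth with lichen cover (hence biomass) scaled by ``factor``.

    Mat heights and all invariant features (landcover, reference areas,
    border) are untouched — this is how a multi-decade grazing history is
    emulated while the calibration targets stay stable.
    """
    if factor < 0:
        raise ValueError("factor must be non-negative")
    cover = np.clip(landscape.cover.values * factor, 0.0, 100.0)
    biomass = LICHEN_DENSITY_G_PER_DM3 * (cover / 100.0) * landscape.height.values
    return replace(landscape,
                   cover=landscape.cover.copy_with(cover),
                   biomass=landscape.biomass.copy_with(biomass),
                   _reflectance_cache=None)


# ---------------------------------------------------------------------------
# scene rendering

def render_scene(landscape: TrueLandscape, sensor: SensorSpec,
                 rng: np.random.Generator | None = None) -> Scene:
    """Render the landscape through a sensor's affine radiometric response.

    value = gain * reflectance + offset + N(0, noise_sd), truncated at 0,
    mean-aggregated from native cells to the sensor pixel.  Cells outside
    the sensor's coverage window become nodata.
    """
    base_px = landscape.biomass.pixel
    if sensor.pixel_m < base_px - 1e-9:
        raise ValueError("sensor pixel must be >= landscape base pixel")
    factor = sensor.pixel_m / base_px
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("sensor pixel must be an integer multiple of base pixel")
    factor = int(round(factor))
    if rng is None:
        # stable across processes: derive the stream from a CRC of the
        # landscape seed and the sensor identity
        key = f"{landscape.spec.seed}|{sensor.name}|{sensor.year}"
        rng = np.random.default_rng(zlib.crc32(key.encode()) % (2 ** 31))

    refl = landscape.reflectance
    ny, nx = refl.shape
    bands = {}
    for band in sensor.bands:
        v = sensor.gain * refl + sensor.offset
        if sensor.noise_sd > 0:
            v = v + rng.normal(0.0, sensor.noise_sd, v.shape)
        v = np.maximum(v, 0.0)
        g = Grid(v, landscape.biomass.x0, landscape.biomass.y0, base_px)
        from .rasters import block_aggregate
        bands[band] = block_aggregate(g, factor).values

    # coverage: a random axis-aligned window with the requested area fraction
    if sensor.coverage_fraction < 1.0:
        cny, cnx = next(iter(bands.values())).shape
        f = math.sqrt(sensor.coverage_fraction)
        wy, wx = max(1, int(round(cny * f))), max(1, int(round(cnx * f)))
        oy = rng.integers(0, cny - wy + 1)
        ox = rng.integers(0, cnx - wx + 1)
        keep = np.zeros((cny, cnx), dtype=bool)
        keep[oy:oy + wy, ox:ox + wx] = True
        for band in bands:
            bands[band] = np.where(keep, bands[band], np.nan)

    return Scene(bands=bands, x0=landscape.biomass.x0, y0=landscape.biomass.y0,
                 pixel=base_px * factor, sensor=sensor)


# ---------------------------------------------------------------------------
# vegetation plots

def _clumped_mask(rng: np.random.Generator, n_px: int, n_hits: int) -> np.ndarray:
    """Binary plot image with exactly ``n_hits`` lichen pixels, spatially clumped."""
    u = ndimage.gaussian_filter(rng.standard_normal((n_px, n_px)), sigma=4.0)
    order = np.argsort(u, axis=None)[::-1]
    mask = np.zeros(n_px * n_px, dtype=bool)
    mask[order[:n_hits]] = True
    return mask.reshape(n_px, n_px)


def generate_plots(landscape: TrueLandscape, n_transects: int = 5,
                   plots_per_transect: int = 40, plot_size_m: float = 0.5,
                   mask_px: int = 50, cover3d_noise_sd: float = 3.0,
                   seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Vegetation plots on transects laid perpendicularly across the fence.

    Returns a tidy plot table and per-plot binary lichen mask images whose
    pixel fraction matches the recorded true 2-D cover to within 1 %.
    Plots sit at 10-m intervals, half on each side of the border.
    """
    spec = landscape.spec
    rng = np.random.default_rng(spec.seed + 7919 if seed is None else seed)
    w, h = spec.extent_m
    half = (plots_per_transect // 2) * 10.0
    if spec.border_x - half < 0 or spec.border_x + half > w:
        raise ValueError("transects do not fit inside the domain")

    ys = np.linspace(h * 0.15, h * 0.85, n_transects)
    grid = landscape.cover
    rows = []
    masks = {}
    n_cells = mask_px * mask_px
    for t, yc in enumerate(ys):
        for p in range(plots_per_transect):
            xc = spec.border_x - half + 5.0 + 10.0 * p
            j = int((xc - grid.x0) / grid.pixel)
            i = int((grid.y0 - yc) / grid.pixel)
            i = np.clip(i, 0, grid.shape[0] - 1)
            j = np.clip(j, 0, grid.shape[1] - 1)
            true_cover = float(grid.values[i, j])
            height_mm = float(landscape.height.values[i, j])
            hits = int(round(true_cover / 100.0 * n_cells))
            mask = _clumped_mask(rng, mask_px, hits)
            cover2d = 100.0 * hits / n_cells
            # visual 3-D estimate: layered species push it above the projected
            # cover, with observer noise; it is what the volume formula uses
            cover3d = max(0.0, cover2d + float(rng.normal(0.0, cover3d_noise_sd)))
            volume = (cover3d / 100.0) * height_mm
            plot_id = f"T{t + 1}P{p + 1:02d}"
            rows.append({
                "plot_id": plot_id,
                "transect": t + 1,
                "x": xc, "y": float(yc),
                "side": "A" if xc < spec.border_x else "B",
                "true_cover2d_pct": true_cover,
                "cover2d_pct": cover2d,
                "cover3d_pct": cover3d,
                "height_mm": height_mm,
                "volume_dm3_m2": volume,
                "biomass_g_m2": LICHEN_DENSITY_G_PER_DM3 * volume,
            })
            masks[plot_id] = mask
    return pd.DataFrame(rows), masks


# ---------------------------------------------------------------------------
# reindeer censuses and forward-simulated biomass series

@dataclass
class CensusTrend:
    """Multi-decade herd trend: exponential drift with year-specific shocks."""

    growth_rate: float = 0.0           # per year (0 = flat herd)
    shock_multipliers: dict = field(default_factory=dict)  # year -> factor
    noise_cv: float = 0.0              # lognormal-ish CV of counts


def generate_census(years, base_density: float, area_km2: float,
                    occupancy_days: float = 365.0,
                    trend: CensusTrend | None = None,
                    seed: int = 0) -> list[ReindeerCensus]:
    """Annual reindeer counts for one management area, deterministic per seed."""
    years = list(years)
    if not years:
        raise ValueError("years must be non-empty")
    trend = trend or CensusTrend()
    rng = np.random.default_rng(seed)
    t0 = years[0]
    out = []
    for y in years:
        c = base_density * area_km2 * (1.0 + trend.growth_rate) ** (y - t0)
        c *= trend.shock_multipliers.get(y, 1.0)
        if trend.noise_cv > 0:
            c *= max(0.0, 1.0 + float(rng.normal(0.0, trend.noise_cv)))
        out.append(ReindeerCensus(year=int(y), count=float(c),
                                  area_km2=area_km2,
                                  occupancy_days=occupancy_days))
    return out


def forward_reconstruction_series(params, densities, fts, b0: float,
                                  sample_years, noise_rel: float = 0.0,
                                  seed: int = 0) -> dict:
    """Noisy 'reconstructed biomass history' from a forward model run.

    Runs the district biomass model and observes it at ``sample_years`` with
    i.i.d. multiplicative Gaussian noise (relative sd ``noise_rel``); with
    ``noise_rel=0`` it equals the simulated trajectory exactly.  Serves as
    ground truth for loss-parameter recovery.
    """
    from .model import simulate
    years = sorted(densities)
    traj = simulate(b0, years, densities, fts, params)
    rng = np.random.default_rng(seed)
    sim = dict(zip(traj["year"], traj["biomass_g_m2"]))
    out = {}
    for y in sample_years:
        if y not in sim:
            raise ValueError(f"sample year {y} outside the simulated range")
        eps = rng.normal(0.0, noise_rel) if noise_rel > 0 else 0.0
        out[int(y)] = float(max(0.0, sim[y] * (1.0 + eps)))
    return out
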