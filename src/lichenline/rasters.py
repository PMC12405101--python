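"""Minimal planar-CRS raster and vector plumbing.

A raster is a numpy array plus an affine anchor (top-left corner, square
pixel).  Nodata is NaN.  Cell (row i, col j) has its centre at

    x = x0 + (j + 0.5) * pixel,   y = y0 - (i + 0.5) * pixel

i.e. north-up, y decreasing with row index.  I/O is plain TIFF via
``tifffile`` with a YAML sidecar carrying the georeferencing and any
provenance metadata; vectors are shapely geometries written as GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from shapely import contains_xy
from shapely.geometry import mapping as geom_mapping, shape as geom_shape
import tifffile

NODATA = np.nan


@dataclass
class Grid:
    """Single-band raster with planar georeferencing (nodata = NaN)."""

    values: np.ndarray          # 2-D float array
    x0: float                   # easting of the top-left corner (m)
    y0: float                   # northing of the top-left corner (m)
    pixel: float                # square pixel size (m)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.pixel <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean nodata mask (True where missing)."""
        return np.isnan(self.values)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.values.shape
        x = self.x0 + (np.arange(nx) + 0.5) * self.pixel
        y = self.y0 - (np.arange(ny) + 0.5) * self.pixel
        return np.meshgrid(x, y)

    def copy_with(self, values: np.ndarray, **meta) -> "Grid":
        g = replace(self, values=np.asarray(values, dtype=float))
        g.meta = {**self.meta, **meta}
        return g


def block_aggregate(grid: Grid, factor: int) -> Grid:
    """Mean-aggregate to a coarser grid by an integer factor.

    The mean ignores NaN cells; an all-NaN block stays NaN.  Rows/columns
    that do not fill a whole block are dropped (the footprint shrinks by
    less than one coarse pixel).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("aggregation factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return grid.copy_with(grid.values.copy())
    ny, nx = grid.shape
    ty, tx = (ny // factor) * factor, (nx // factor) * factor
    if ty == 0 or tx == 0:
        raise ValueError("grid smaller than one aggregation block")
    v = grid.values[:ty, :tx].reshape(ty // factor, factor, tx // factor, factor)
    s = np.nansum(v, axis=(1, 3))
    n = (~np.isnan(v)).sum(axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    return Grid(out, grid.x0, grid.y0, grid.pixel * factor, dict(grid.meta))


def upsample_nearest(grid: Grid, factor: int) -> Grid:
    """Block-constant (nearest-cell) upsampling by an integer factor."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("upsampling factor must be a positive integer")
    v = np.kron(grid.values, np.ones((int(factor), int(factor))))
    return Grid(v, grid.x0, grid.y0, grid.pixel / factor, dict(grid.meta))


def polygon_mask(grid: Grid, polygon) -> np.ndarray:
    """Boolean mask of cells whose centres fall inside ``polygon``.

    Centre containment is the zonal-statistics convention used throughout:
    deterministic and robust across resolutions.  Evaluation is restricted
    to the polygon's bounding box for speed.
    """
    ny, nx = grid.shape
    minx, miny, maxx, maxy = polygon.bounds
    j0 = max(0, int(np.floor((minx - grid.x0) / grid.pixel)) - 1)
    j1 = min(nx, int(np.ceil((maxx - grid.x0) / grid.pixel)) + 1)
    i0 = max(0, int(np.floor((grid.y0 - maxy) / grid.pixel)) - 1)
    i1 = min(ny, int(np.ceil((grid.y0 - miny) / grid.pixel)) + 1)
    out = np.zeros((ny, nx), dtype=bool)
    if j1 <= j0 or i1 <= i0:
        return out
    x = grid.x0 + (np.arange(j0, j1) + 0.5) * grid.pixel
    y = grid.y0 - (np.arange(i0, i1) + 0.5) * grid.pixel
    X, Y = np.meshgrid(x, y)
    out[i0:i1, j0:j1] = contains_xy(polygon, X.ravel(), Y.ravel()).reshape(X.shape)
    return out


def zonal_mean(grid: Grid, polygon) -> tuple[float, int]:
    """Mean of valid cells inside ``polygon`` and their count."""
    m = polygon_mask(grid, polygon) & ~grid.mask
    n = int(m.sum())
    return (float(grid.values[m].mean()) if n else float("nan")), n


def write_grid(grid: Grid, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, grid.values.astype(np.float32))
    sidecar = {
        "x0": float(grid.x0),
        "y0": float(grid.y0),
        "pixel": float(grid.pixel),
        "nodata": "nan",
        **{k: v for k, v in grid.meta.items() if isinstance(v, (str, int, float, bool))},
    }
    path.with_suffix(path.suffix + ".yml").write_text(yaml.safe_dump(sidecar))


def read_grid(path: str | Path) -> Grid:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)
    meta = yaml.safe_load(path.with_suffix(path.suffix + ".yml").read_text())
    x0, y0, pixel = meta.pop("x0"), meta.pop("y0"), meta.pop("pixel")
    meta.pop("nodata", None)
    return Grid(values, x0, y0, pixel, meta)


def write_geojson(geoms: dict, path: str | Path) -> None:
    """Write a name->geometry mapping as a GeoJSON FeatureCollection."""
    features = [
        {"type": "Feature", "properties": {"name": name}, "geometry": geom_mapping(g)}
        for name, g in geoms.items()
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_geojson(path: str | Path) -> dict:
    fc = json.loads(Path(path).read_text())
    return {f["properties"].get("name", str(i)): geom_shape(f["geometry"])
            for i, f in enumerate(fc["features"])}
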