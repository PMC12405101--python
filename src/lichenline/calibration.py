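"""Greyscale conversion and reference-area radiometric calibration.

Heterogeneous scenes (different cameras, films, satellite sensors) are made
comparable by regressing each source scene's mean grey level over a set of
pseudo-invariant reference areas (dark lakes/fens, bright sand) against the
same areas in a common target scene, then applying the fitted affine map
per pixel.  Very-high-resolution mosaics additionally get a local
refinement that forces their coarse-scale aggregate onto the target.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .rasters import Grid, block_aggregate, upsample_nearest, zonal_mean
from .synthetic import Scene


def to_greyscale(scene: Scene) -> Grid:
    """Unweighted per-pixel mean of the available bands.

    Early satellite scenes missing the blue band simply average the bands
    they have; a single-band scene passes through unchanged.  A pixel that
    is nodata in any band is nodata in the greyscale.
    """
    if not scene.bands:
        raise ValueError("scene has no bands")
    stack = np.stack(list(scene.bands.values()))
    grey = stack.mean(axis=0)   # NaN propagates, as required
    return Grid(grey, scene.x0, scene.y0, scene.pixel,
                {"source": scene.sensor.name, "year": scene.sensor.year,
                 "bands": ",".join(scene.bands)})


def extract_reference_means(grey: Grid, areas) -> pd.DataFrame:
    """Mean grey level of each reference area (valid pixels, centre rule).

    Areas with zero valid pixels are retained in the table with NaN mean
    and n_pixels = 0 so that the pairing step can flag and exclude them.
    """
    areas = list(areas)
    if not areas:
        raise ValueError("empty reference-area set")
    rows = []
    for a in areas:
        mean, n = zonal_mean(grey, a.polygon)
        rows.append({"area_id": a.area_id, "class": a.cls,
                     "mean": mean, "n_pixels": n})
    return pd.DataFrame(rows)


def pair_reference_means(source_means: pd.DataFrame,
                         target_means: pd.DataFrame) -> pd.DataFrame:
    """Join per-area means from a source and the target scene.

    Only areas with at least one valid pixel in both scenes survive;
    excluded areas are listed in the ``excluded`` attribute of the result.
    """
    df = source_means.merge(target_means, on=["area_id", "class"],
                            suffixes=("_source", "_target"))
    ok = (df["n_pixels_source"] >= 1) & (df["n_pixels_target"] >= 1)
    out = df[ok].reset_index(drop=True)
    out.attrs["excluded"] = df.loc[~ok, "area_id"].tolist()
    return out


@dataclass
class CalibrationModel:
    slope: float
    intercept: float
    r_squared: float
    n_areas: int
    source: str = ""
    target: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        return cls(**json.loads(Path(path).read_text()))


def fit_calibration(observations: pd.DataFrame, source: str = "",
                    target: str = "") -> CalibrationModel:
    """OLS of target means on source means over the paired reference areas."""
    x = np.asarray(observations["mean_source"], dtype=float)
    y = np.asarray(observations["mean_target"], dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two reference-area pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all source means are equal")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return CalibrationModel(slope=float(res.params[1]),
                            intercept=float(res.params[0]),
                            r_squared=float(res.rsquared),
                            n_areas=len(x), source=source, target=target)


def apply_calibration(grey: Grid, model: CalibrationModel) -> Grid:
    """Per-pixel affine map slope*x + intercept; nodata preserved."""
    return grey.copy_with(model.slope * grey.values + model.intercept,
                          calibrated_to=model.target)


def refine_local(high_res: Grid, target: Grid) -> Grid:
    """Local refinement of a coarsely calibrated very-high-resolution scene.

    The high-resolution scene is mean-aggregated to the target grid, the
    per-cell difference to the target is formed, upsampled block-constant,
    and subtracted — after which the aggregate of the refined scene equals
    the target on every overlapping valid cell while the within-cell
    contrast of the mosaic is preserved exactly.
    """
    if high_res.pixel >= target.pixel:
        raise ValueError("high_res must be finer than the target")
    factor = target.pixel / high_res.pixel
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("pixel sizes must be integer-commensurate")
    factor = int(round(factor))
    agg = block_aggregate(high_res, factor)
    cny, cnx = agg.shape
    tny, tnx = target.shape
    oy, ox = min(cny, tny), min(cnx, tnx)
    diff = np.zeros((cny, cnx))
    tgt_overlap = target.values[:oy, :ox]
    d = agg.values[:oy, :ox] - tgt_overlap
    valid = ~np.isnan(d)
    if not valid.any():
        raise ValueError("no overlapping valid cells between scenes")
    diff[:oy, :ox] = np.where(valid, d, 0.0)
    d_hi = upsample_nearest(Grid(diff, agg.x0, agg.y0, agg.pixel), factor)
    ny, nx = high_res.shape
    refined = high_res.values - d_hi.values[:ny, :nx]
    return high_res.copy_with(refined, refined_to=target.meta.get("source", ""))


def calibrate_drone(drone_grey: Grid, target: Grid, n_points: int = 400,
                    seed: int = 0) -> tuple[Grid, CalibrationModel]:
    """Two-step calibration of a drone mosaic to the target scene.

    Step 1: coarse affine calibration by OLS between the mosaic aggregated
    to the target grid and the target, sampled at random coarse cells
    (reference areas are rarely present inside a small drone footprint).
    Step 2: :func:`refine_local` removes the remaining local colour-balance
    errors.
    """
    factor = int(round(target.pixel / drone_grey.pixel))
    agg = block_aggregate(drone_grey, factor)
    oy = min(agg.shape[0], target.shape[0])
    ox = min(agg.shape[1], target.shape[1])
    xs = agg.values[:oy, :ox].ravel()
    ys = target.values[:oy, :ox].ravel()
    ok = ~(np.isnan(xs) | np.isnan(ys))
    idx = np.flatnonzero(ok)
    rng = np.random.default_rng(seed)
    if len(idx) > n_points:
        idx = rng.choice(idx, size=n_points, replace=False)
    obs = pd.DataFrame({"mean_source": xs[idx], "mean_target": ys[idx]})
    model = fit_calibration(obs, source=drone_grey.meta.get("source", "drone"),
                            target=target.meta.get("source", "target"))
    coarse = apply_calibration(drone_grey, model)
    refined = refine_local(coarse, target)
    return refined, model
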