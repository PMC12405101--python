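"""District-level mechanistic forage-lichen biomass model.

Annual bookkeeping of district-mean lichen dry biomass b_t (g m^-2, which
equals t km^-2):

    b_t = b_{t-1} + g_{t-1} - e_{t-1} - w_{t-1}

with growth g = f * (b R(b) - b) under the empirical relative growth law
R(b) = a b^{-k} (a = 1.95, k = 0.1), a landscape factor f in (0, 1]
correcting for the concavity of the growth curve over a heterogeneous
biomass distribution (Jensen correction), metabolic intake e = i d with i
tonnes of dry lichen per reindeer-year and d the reindeer-year density
(km^-2), and density-proportional loss (trampling and wastage)
w = b d l with l the annual loss fraction per reindeer-year km^-2.

All fluxes within a year are evaluated at the start-of-year biomass, as
the recursion above states them; biomass is floored at zero with clamp
events recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

VARIANTS = ("full", "no_loss", "intake_only", "no_intake")


@dataclass
class ModelParams:
    """Constants of the district biomass model.

    ``intake_t_per_reindeer_year`` is 0.676 t for a pure winter district
    (lichen is the whole winter diet) and half of that, 0.338 t, for
    mixed-use pastures grazed year-round.  ``loss_factor`` is the annual
    fraction of standing biomass destroyed per reindeer-year km^-2.
    """

    growth_coeff: float = 1.95          # a in R = a b^-k
    growth_exp: float = 0.1             # k
    intake_t_per_reindeer_year: float = 0.676
    loss_factor: float = 0.019
    energy_req_mj_day: float = 20.0     # pregnant female, ~90 kg
    energy_content_mj_kg: float = 10.8  # metabolizable energy of dry lichen

    def __post_init__(self) -> None:
        if self.growth_coeff <= 0 or not (0 < self.growth_exp < 1):
            raise ValueError("growth law requires a > 0 and 0 < k < 1")
        if self.intake_t_per_reindeer_year < 0 or self.loss_factor < 0:
            raise ValueError("intake and loss must be non-negative")

    @property
    def equilibrium_biomass(self) -> float:
        """Biomass where net growth vanishes: a^(1/k) (~795 g m^-2)."""
        return self.growth_coeff ** (1.0 / self.growth_exp)

    @property
    def optimal_biomass(self) -> float:
        """Biomass maximizing absolute growth: (a (1-k))^(1/k)."""
        return (self.growth_coeff * (1.0 - self.growth_exp)) ** (1.0 / self.growth_exp)


def relative_growth(b: float, params: ModelParams) -> float:
    """Relative annual growth R(b) = a b^-k (dimensionless multiplier)."""
    if b < 0:
        raise ValueError("biomass must be non-negative")
    if b == 0:
        return 0.0   # bare ground: no lichen to multiply
    return params.growth_coeff * b ** (-params.growth_exp)


def plot_growth(b: float, params: ModelParams) -> float:
    """Absolute annual growth g(b) = b R(b) - b = a b^(1-k) - b (g m^-2).

    Zero at b = 0 and at the equilibrium a^(1/k); maximal (~31 g m^-2)
    near 300 g m^-2.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("biomass must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(b > 0,
                     params.growth_coeff * b ** (1.0 - params.growth_exp) - b,
                     0.0)
    return float(g) if g.ndim == 0 else g


def max_annual_growth(params: ModelParams) -> float:
    """Peak of the absolute growth curve, found numerically."""
    res = optimize.minimize_scalar(lambda b: -plot_growth(b, params),
                                   bounds=(1e-6, params.equilibrium_biomass),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    return float(-res.fun)


def zero_growth_biomass(params: ModelParams) -> float:
    """Root of R(b) = 1 above zero, found by bracketing."""
    return float(optimize.brentq(
        lambda b: relative_growth(b, params) - 1.0, 1.0,
        10.0 * params.equilibrium_biomass))


def landscape_factor(point_biomasses, params: ModelParams) -> float:
    """Jensen-type landscape growth factor f.

    Mean pointwise growth over a sample of the biomass map divided by the
    growth at the sample mean.  Concavity of g(b) makes f <= 1, with
    equality only for a homogeneous landscape.  Points at zero biomass
    contribute zero growth; points above equilibrium contribute their
    (negative) analytic growth.
    """
    b = np.asarray(point_biomasses, dtype=float)
    if b.size == 0:
        raise ValueError("empty biomass sample")
    mean_b = float(b.mean())
    denom = plot_growth(mean_b, params)
    if mean_b <= 0 or denom <= 0:
        raise ValueError(
            "landscape factor undefined: mean biomass at or beyond the "
            "zero-growth equilibrium")
    return float(np.mean(plot_growth(b, params)) / denom)


def interpolate_factor(anchors: dict, years, method: str = "linear") -> dict:
    """Fill the landscape factor for unmapped years from the mapped anchors.

    Linear interpolation between bracketing anchors, constant continuation
    beyond the first/last anchor; ``method="nearest"`` snaps to the closest
    anchor instead.
    """
    if not anchors:
        raise ValueError("need at least one anchor year")
    ax = np.array(sorted(anchors), dtype=float)
    ay = np.array([anchors[int(a)] for a in ax], dtype=float)
    years = np.asarray(list(years), dtype=float)
    if method == "linear":
        vals = np.interp(years, ax, ay)
    elif method == "nearest":
        idx = np.abs(years[:, None] - ax[None, :]).argmin(axis=1)
        vals = ay[idx]
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    return {int(y): float(v) for y, v in zip(years, vals)}


def reindeer_year_density(count: float, area_km2: float,
                          occupancy_days: float) -> float:
    """Reindeer-years per km^2: (count/area) * (days present / 365).

    2.3 animals km^-2 present 157 days is ~1 reindeer-year km^-2, the
    normalization that makes winter-only and year-round districts
    comparable.
    """
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    if not (0 <= occupancy_days <= 365):
        raise ValueError("occupancy_days must be within [0, 365]")
    return (count / area_km2) * (occupancy_days / 365.0)


def metabolic_intake_constant(energy_req_mj_day: float = 20.0,
                              energy_content_mj_kg: float = 10.8,
                              days: float = 365.0) -> float:
    """Dry lichen (kg) metabolized per reindeer over ``days`` days.

    20 MJ day^-1 at 10.8 MJ kg^-1 over a full year gives ~676 kg.
    """
    if energy_content_mj_kg <= 0:
        raise ValueError("energy content must be positive")
    return energy_req_mj_day / energy_content_mj_kg * days


def annual_step(b: float, d: float, f: float, params: ModelParams,
                variant: str = "full") -> tuple[float, float, float, float]:
    """One model year: returns (growth, intake, loss, next biomass).

    All three fluxes are evaluated at the start-of-year biomass ``b``
    (g m^-2), with reindeer-year density ``d`` (km^-2) and landscape
    factor ``f``.  The next biomass is floored at zero.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if b < 0 or d < 0:
        raise ValueError("biomass and density must be non-negative")
    if not (0 < f <= 1):
        raise ValueError("landscape factor must lie in (0, 1]")
    g = f * plot_growth(b, params)
    e = params.intake_t_per_reindeer_year * d
    w = b * d * params.loss_factor
    if variant == "no_loss":
        w = 0.0
    elif variant == "intake_only":
        g, w = 0.0, 0.0
    elif variant == "no_intake":
        e = 0.0
    b_next = b + g - e - w
    return g, e, w, max(0.0, b_next)


def simulate(b0: float, years, densities: dict, fts: dict | float,
             params: ModelParams, variant: str = "full") -> pd.DataFrame:
    """Iterate the annual recursion over ``years``.

    ``densities`` maps year -> reindeer-year density; ``fts`` maps year ->
    landscape factor (or is a single constant).  The returned trajectory
    records the start-of-year biomass and the year's fluxes; ``clamped``
    flags years where the zero floor bound.
    """
    years = sorted(int(y) for y in years)
    if not years:
        raise ValueError("empty year range")
    if not isinstance(fts, dict):
        fts = {y: float(fts) for y in years}
    for y in years:
        if y not in densities:
            raise ValueError(f"missing reindeer density for year {y}")
        if y not in fts:
            raise ValueError(f"missing landscape factor for year {y}")
    rows = []
    b = float(b0)
    for y in years:
        g, e, w, b_next = annual_step(b, densities[y], fts[y], params, variant)
        rows.append({"year": y, "biomass_g_m2": b, "growth": g, "intake": e,
                     "loss": w, "clamped": b + g - e - w < 0,
                     "variant": variant})
        b = b_next
    return pd.DataFrame(rows)


@dataclass
class LossFit:
    loss_factor: float
    sse: float
    residuals: pd.DataFrame
    n_obs: int


def fit_loss_parameter(observed: dict, b0: float, densities: dict,
                       fts: dict | float, params: ModelParams,
                       bounds: tuple[float, float] = (0.0, 0.5),
                       grid_n: int = 51) -> LossFit:
    """Least-squares estimate of the loss factor l.

    Minimizes the SSE between the simulated trajectory and a sparse
    observed biomass series over l in ``bounds``: a coarse grid locates
    the basin, bounded Brent refines it.  Deterministic and
    derivative-free.
    """
    obs_years = sorted(int(y) for y in observed)
    if len(obs_years) < 2:
        raise ValueError("need at least two observation years")
    years = sorted(densities)
    for y in obs_years:
        if y not in densities:
            raise ValueError(f"observation year {y} outside simulation range")

    def sse(l: float) -> float:
        p = replace(params, loss_factor=float(l))
        traj = simulate(b0, years, densities, fts, p)
        sim = dict(zip(traj["year"], traj["biomass_g_m2"]))
        val = sum((sim[y] - observed[y]) ** 2 for y in obs_years)
        if not np.isfinite(val):
            raise ValueError("non-finite objective in loss fit")
        return val

    grid = np.linspace(bounds[0], bounds[1], grid_n)
    errs = np.array([sse(l) for l in grid])
    k = int(errs.argmin())
    lo = grid[max(0, k - 1)]
    hi = grid[min(grid_n - 1, k + 1)]
    if hi <= lo:
        l_hat = float(grid[k])
    else:
        res = optimize.minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-8})
        l_hat = float(res.x)
        if sse(l_hat) > errs[k]:
            l_hat = float(grid[k])
    p = replace(params, loss_factor=l_hat)
    traj = simulate(b0, years, densities, fts, p)
    sim = dict(zip(traj["year"], traj["biomass_g_m2"]))
    resid = pd.DataFrame({
        "year": obs_years,
        "observed": [observed[y] for y in obs_years],
        "simulated": [sim[y] for y in obs_years]})
    resid["residual"] = resid["simulated"] - resid["observed"]
    return LossFit(loss_factor=l_hat, sse=float((resid["residual"] ** 2).sum()),
                   residuals=resid, n_obs=len(obs_years))


def loss_to_intake_ratio(trajectory: pd.DataFrame,
                         params: ModelParams) -> pd.Series:
    """Per-reindeer-year lost mass over ingested mass: b_t * l / i.

    The 'how many annual rations are destroyed per animal' diagnostic;
    linear in the standing biomass for fixed l and i.
    """
    if params.intake_t_per_reindeer_year <= 0:
        raise ValueError("intake must be positive")
    return (trajectory["biomass_g_m2"] * params.loss_factor /
            params.intake_t_per_reindeer_year).rename("loss_to_intake")
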