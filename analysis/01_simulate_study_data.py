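#!/usr/bin/env python
"""Generate the synthetic study area: sites, plots, district, censuses.

Builds two fine-resolution study sites with transect plots across the
border fence, the district-scale landscape with its 48 pseudo-invariant
reference areas, and the two multi-decade reindeer census series.
Writes the plot table and census tables under results/data/.
"""

import sys
from pathlib import Path

import pandas as pd

from lichenline import model as mdl
from lichenline import pipeline as pl
from lichenline import synthetic as syn

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "data"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = pl.default_config(seed=SEED, scale=0.5)

    train = pl.build_site("train", cfg.train_site_kwargs, cfg)
    test = pl.build_site("test", cfg.test_site_kwargs, cfg)
    plots = pd.concat([train.plots, test.plots], ignore_index=True)
    plots.to_csv(OUT / "vegetation_plots.csv", index=False)
    print(f"plots: {len(plots)} rows over 2 sites "
          f"({cfg.n_transects} transects x {cfg.plots_per_transect} plots)")
    for site, sub in plots.groupby("site"):
        print(f"  {site}: 2D cover {sub.cover2d_pct.min():.0f}-"
              f"{sub.cover2d_pct.max():.0f} %, biomass "
              f"{sub.biomass_g_m2.min():.0f}-{sub.biomass_g_m2.max():.0f} "
              f"g m^-2")

    district = syn.generate_landscape(syn.LandscapeSpec(**cfg.district_kwargs))
    n_dark = sum(a.cls == "dark" for a in district.reference_areas)
    n_bright = len(district.reference_areas) - n_dark
    print(f"district landscape: {district.biomass.shape} cells at "
          f"{district.biomass.pixel:.0f} m, {n_dark} dark + {n_bright} "
          f"bright reference areas")

    years = range(cfg.model_years[0], cfg.model_years[1] + 1)
    for side, kwargs in (("sideA", cfg.sideA_census),
                         ("sideB", cfg.sideB_census)):
        trend = syn.CensusTrend(growth_rate=kwargs["growth_rate"],
                                shock_multipliers=kwargs["shocks"])
        census = syn.generate_census(
            years, kwargs["base_density"], kwargs["area_km2"],
            kwargs["occupancy_days"], trend, seed=cfg.seed)
        df = pd.DataFrame([{"year": c.year, "count": c.count,
                            "area_km2": c.area_km2,
                            "occupancy_days": c.occupancy_days,
                            "reindeer_years_km2": mdl.reindeer_year_density(
                                c.count, c.area_km2, c.occupancy_days)}
                           for c in census])
        df.to_csv(OUT / f"census_{side}.csv", index=False)
        print(f"census {side}: density {df.reindeer_years_km2.iloc[0]:.2f} "
              f"-> {df.reindeer_years_km2.iloc[-1]:.2f} reindeer-years km^-2")


if __name__ == "__main__":
    main()
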