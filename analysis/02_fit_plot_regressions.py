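#!/usr/bin/env python
"""Fit the grey -> lichen cover and grey -> biomass plot regressions.

Trains both linear maps on the training site's plots (drone mosaic
calibrated to the common target in two steps) and evaluates them held-out
on the second site, mirroring the train-on-one-landscape /
test-on-the-other design.  Writes results/plot_regression.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from lichenline import pipeline as pl

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    cfg = pl.default_config(seed=SEED, scale=0.5)
    train = pl.build_site("train", cfg.train_site_kwargs, cfg)
    test = pl.build_site("test", cfg.test_site_kwargs, cfg)
    plots = pd.concat([train.plots, test.plots], ignore_index=True)
    reg, held = pl.train_test_split_sites(plots, "train", "test")

    print(f"training fit (n={reg.n_plots}): "
          f"r2_cover={reg.r2_cover:.2f}, r2_biomass={reg.r2_biomass:.2f} "
          f"(p_cover={reg.p_cover:.1e})")
    print(f"held-out on the test site: r2_cover={held['r2_cover']:.2f}, "
          f"r2_biomass={held['r2_biomass']:.2f}")
    print(f"zero-crossing grey value: {reg.zero_cross_grey:.3f} "
          f"(cover predicted negative below it, reclassified to 0)")
    print(f"biomass cap at the 100 %-cover grey value: "
          f"{reg.cap_biomass_g_m2:.0f} g m^-2")

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    (out / "plot_regression.json").write_text(json.dumps({
        "cover_slope": reg.cover_slope,
        "cover_intercept": reg.cover_intercept,
        "biomass_slope": reg.biomass_slope,
        "biomass_intercept": reg.biomass_intercept,
        "r2_cover": reg.r2_cover, "r2_biomass": reg.r2_biomass,
        "p_cover": reg.p_cover, "p_biomass": reg.p_biomass,
        "zero_cross_grey": reg.zero_cross_grey,
        "cap_biomass_g_m2": reg.cap_biomass_g_m2,
        "held_out": held}, indent=2))
    print("wrote results/plot_regression.json")


if __name__ == "__main__":
    main()
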