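import numpy as np
import pytest

from lichenline import pipeline as pl
from lichenline import synthetic as syn


@pytest.fixture(scope="session")
def demo_config():
    return pl.default_config(seed=1, scale=0.5)


@pytest.fixture(scope="session")
def district_landscape(demo_config):
    """Half-extent district landscape with the full reference-area inventory."""
    return syn.generate_landscape(syn.LandscapeSpec(**demo_config.district_kwargs))


@pytest.fixture(scope="session")
def train_site(demo_config):
    return pl.build_site("train", demo_config.train_site_kwargs, demo_config)


@pytest.fixture(scope="session")
def report(demo_config):
    """One full pipeline run shared by the integration-level tests."""
    return pl.run_all(demo_config)


@pytest.fixture(scope="session")
def tiny_spec():
    """A fast, feature-light landscape for unit-level generator tests."""
    return syn.LandscapeSpec(
        extent_m=(800.0, 600.0), base_pixel_m=5.0,
        lichen_patch_density=30.0, n_lakes=2, n_fens=1, n_sandpits=1,
        landcover_fractions={"heath": 0.5, "forest": 0.25,
                             "mire": 0.2, "water": 0.05},
        seed=42)


@pytest.fixture(scope="session")
def tiny_landscape(tiny_spec):
    return syn.generate_landscape(tiny_spec)
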