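import numpy as np
import pandas as pd
import pytest

from firematch.scenarios import null1_config
from firematch.synthetic import generate_scenario


@pytest.fixture(scope="session")
def null_scenario():
    """One moderately sized confounded landscape with zero treatment effect."""
    cfg = null1_config(seed=7, n_points=6000, n_countries=3)
    points, rasters, truth = generate_scenario(cfg)
    return cfg, points, rasters, truth


@pytest.fixture()
def toy_points():
    """Tiny hand-checkable point table (8 rows, 2 biomes)."""
    rng = np.random.default_rng(0)
    n = 8
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "lon": np.linspace(0.1, 3.9, n),
            "lat": np.linspace(40.1, 41.9, n),
            "country": ["C01"] * n,
            "biome": ["a", "a", "a", "a", "b", "b", "b", "b"],
            "mgmt_class": [
                "plantation_temperate", "natural_production",
                "natural_production", "natural_production",
                "plantation_temperate", "natural_production",
                "natural_production", "plantation_temperate",
            ],
            "confidence": [0.90, 0.70, 0.69, 0.95, 0.80, 0.75, 0.71, 0.99],
            "tree_cover": [0.30, 0.29, 0.80, 0.55, 0.31, 0.90, 0.10, 0.62],
            "burned": [1, 0, 0, 1, 0, 0, 1, 0],
        }
    )
    for name in ("elevation", "slope", "temp_hot_q", "precip_dry_q",
                 "precip_wet_q", "fwi95", "burn_hist_15y", "dist_road",
                 "pop_density"):
        df[name] = rng.normal(size=n)
    return df
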