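import numpy as np
import pandas as pd
import pytest

import airtier as at


@pytest.fixture(scope="session")
def small_scene():
    """12 blocks x 120 h scene used by several integration tests."""
    cfg = at.SceneConfig(
        n_blocks=12,
        hours=pd.date_range("2012-01-01", periods=120, freq="h"),
        seed=42,
    )
    return at.generate_scene(cfg)


@pytest.fixture(scope="session")
def small_tiers(small_scene):
    """All six tiers for the small scene (PM2.5-like parameters)."""
    tiers, aer = at.compute_tiers(
        small_scene, at.DEFAULT_POLLUTANTS["PM2.5"], fit_cov=False
    )
    return tiers, aer


def toy_field(values, tier="outdoor_stok", pollutant="PM2.5", start="2012-01-01"):
    values = np.asarray(values, dtype=float)
    return at.ConcentrationField(
        values=values,
        block_ids=np.array([f"b{i}" for i in range(values.shape[0])]),
        hours=pd.date_range(start, periods=values.shape[1], freq="h"),
        pollutant=pollutant,
        tier=tier,
    )
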