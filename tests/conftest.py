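import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import oifnet as o

settings.register_profile(
    "ci", deadline=None, max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_census():
    """Tiny hand-built census: 3 species, 6 census points."""
    dates = pd.date_range("2002-01-01", periods=6, freq="15D")
    counts = np.array([
        [0.0, 2.0, 4.0, 0.0, 2.0, 4.0],
        [1.0, 1.0, 2.0, 3.0, 5.0, 8.0],
        [0.0, 0.0, 1.0, 0.0, 1.0, 2.0],
    ])
    meta = [
        o.SpeciesMeta(1, "sp1", "one", is_fish_stock=True, is_native=True),
        o.SpeciesMeta(2, "sp2", "two", is_fish_stock=False, is_native=False),
        o.SpeciesMeta(3, "sp3", "three", is_fish_stock=True, is_native=True,
                      dynamical_role="competitive"),
    ]
    return o.CensusTable(
        timestamps=pd.DatetimeIndex(dates), counts=counts,
        surface_temp=np.array([8.0, 12.0, 16.0, 21.0, 26.0, 15.0]),
        bottom_temp=np.array([8.0, 12.0, 16.0, 21.0, 26.0, 15.0]),
        species_meta=meta,
    )


@pytest.fixture(scope="session")
def default_community():
    """The default synthetic study community (seed 0), shared across tests."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab, truth = o.gen_community(o.SyntheticConfig(seed=0))
    return tab, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
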