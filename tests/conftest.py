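import numpy as np
import pandas as pd
import pytest

from vinedev.inference_core import MCMCConfig
from vinedev.synthetic_data import Design, GroundTruth, make_bundle
from vinedev.thermal_time import CardinalTemperatures


@pytest.fixture(scope="session")
def riesling_ct():
    """The cool-climate cardinal triplet used throughout."""
    return CardinalTemperatures(10.8, 19.0, 24.7)


@pytest.fixture(scope="session")
def small_design():
    return Design(
        plants_per_ring=2, shoots_per_plant=2,
        rating_doys={2018: tuple(range(102, 150, 6)), 2019: tuple(range(101, 149, 6))},
        digitized_shoots_per_plant=3,
    )


@pytest.fixture(scope="session")
def small_bundle(small_design):
    """Compact synthetic bundle shared by the model-fitting tests."""
    return make_bundle(GroundTruth(design=small_design), seed=11)


@pytest.fixture(scope="session")
def fast_mcmc():
    """Short-chain sampling config for tests."""
    return MCMCConfig(n_chains=2, n_warmup=400, n_kept=400, seed=7)


@pytest.fixture(scope="session")
def hourly_frame():
    """Deterministic one-year hourly series builder."""

    def build(year=2018, temp_fn=None):
        ndays = pd.Timestamp(year, 12, 31).dayofyear
        ts = pd.date_range(f"{year}-01-01", periods=ndays * 24, freq="h")
        doy = ts.dayofyear.to_numpy()
        hour = ts.hour.to_numpy()
        if temp_fn is None:
            temp = 12.0 + 8.0 * np.cos(2 * np.pi * (doy - 200) / 365.25) \
                + 4.0 * np.sin(2 * np.pi * (hour - 9) / 24)
        else:
            temp = temp_fn(doy, hour)
        return pd.DataFrame({"timestamp": ts, "t_air_c": temp})

    return build
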