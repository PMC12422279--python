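import numpy as np
import pandas as pd
import pytest

from camtrapdensity import (MovementParams, Region, make_uniform_grid,
                            species_defaults)


@pytest.fixture(scope="session")
def fox_params():
    return species_defaults()["Lycalopex spp."]


@pytest.fixture(scope="session")
def study_grid():
    """The study design: ten cameras, 2 x 5, 1,000 m spacing."""
    return make_uniform_grid()


@pytest.fixture(scope="session")
def fast_params():
    """Fox-like parameters with a light activity level for cheap tests."""
    return MovementParams("Lycalopex spp.", mean_step_m=13.18,
                          sd_step_m=17.31, sd_turn_deg=26.31,
                          steps_per_month=300, home_range_km2=5.31)


@pytest.fixture(scope="session")
def unconfined():
    return Region(origin=(-1e7, -1e7), width_m=2e7, height_m=2e7)


def make_records(minutes, site="A", camera="C01", species="Lycalopex spp.",
                 t0="2021-06-01 00:00:00"):
    """Record table with photos at the given minute offsets."""
    base = pd.Timestamp(t0)
    df = pd.DataFrame({
        "site": site, "camera_id": camera, "species": species,
        "timestamp": pd.Series(
            [base + pd.Timedelta(minutes=float(m)) for m in minutes],
            dtype="datetime64[ns]"),
    })
    df["individual_id"] = pd.array([pd.NA] * len(df), dtype="Int64")
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
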