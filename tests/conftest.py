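import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import thermoyield as ty

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return ty.SyntheticConfig(
        n_units=4,
        years=(2018, 2019, 2020, 2021, 2022),
        grid_shape=(8, 8),
        cloud_prob=0.2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_weather(small_config):
    return ty.generate_weather(small_config)


@pytest.fixture(scope="session")
def small_vegetation(small_config, small_weather):
    return ty.generate_vegetation(small_weather, small_config)


@pytest.fixture(scope="session")
def small_matrix(small_config, small_weather, small_vegetation):
    return ty.build_predictor_matrix(
        small_weather,
        small_vegetation,
        small_config.gdd_params(),
        ty.MilestoneGrid(),
        reference_years=list(small_config.years),
    )


def make_linear_panel(n_units=8, n_years=4, n_cols=10, noise_sd=0.0, seed=0):
    """Small (unit, year) design with y = baseline + 0.8*x1 + 0.5*x2 + noise."""
    rng = np.random.default_rng(seed)
    units = [f"u{i}" for i in range(n_units)]
    years = list(range(2018, 2018 + n_years))
    idx = pd.MultiIndex.from_product([units, years], names=["unit_id", "year"])
    X = pd.DataFrame(
        rng.uniform(0, 1, size=(len(idx), n_cols)),
        index=idx,
        columns=[f"x{j}" for j in range(n_cols)],
    )
    baselines = pd.Series(rng.uniform(30, 90, n_units), index=units)
    y = (
        baselines.reindex(idx.get_level_values("unit_id")).to_numpy()
        + 0.8 * X["x1"].to_numpy()
        + 0.5 * X["x2"].to_numpy()
        + rng.normal(0, noise_sd, len(idx))
    )
    return X, pd.Series(y, index=idx, name="yield_dt_ha"), baselines
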