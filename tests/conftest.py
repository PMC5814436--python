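import numpy as np
import pandas as pd
import pytest

import envgap as eg
from envgap.covariates import EnvDataset


def make_env(values, names=("x",), role="available"):
    """Build a small EnvDataset from a value matrix (rows = records)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != len(names):
        values = values.T
    frame = pd.DataFrame(values, columns=list(names))
    frame.insert(0, "cell_id", np.arange(len(frame)))
    frame["year"] = 2010
    frame["month"] = 7
    return EnvDataset(role=role, covariate_names=tuple(names), frame=frame)


@pytest.fixture
def env_factory():
    return make_env


@pytest.fixture(scope="session")
def basin_config():
    return eg.BasinConfig(n_cols=24, n_rows=12, cell_size=10.0,
                          land_fraction=0.15, n_subregions=4,
                          years=(2010, 2011), seed=42)


@pytest.fixture(scope="session")
def grid(basin_config):
    return eg.generate_basin(basin_config)


@pytest.fixture(scope="session")
def static_fields(grid, basin_config):
    return eg.generate_static_covariates(grid, basin_config.seed)


@pytest.fixture(scope="session")
def dynamic_fields(grid, basin_config):
    return eg.generate_dynamic_covariates(grid, basin_config)


@pytest.fixture(scope="session")
def tracklines(grid, basin_config):
    design = eg.SurveyDesign(n_surveys=60, geographic_concentration=20.0,
                             seasonal_concentration=8.0,
                             mean_trackline_length=60.0)
    return eg.generate_survey_program(grid, design, basin_config)


@pytest.fixture(scope="session")
def effort(tracklines, grid):
    return eg.intersect_effort(tracklines, grid, period=((2010, 1), (2011, 12)))


@pytest.fixture(scope="session")
def available(effort, static_fields, dynamic_fields):
    return eg.build_available_dataset(effort, static_fields, dynamic_fields)


@pytest.fixture(scope="session")
def climatology(dynamic_fields):
    return eg.build_climatology(dynamic_fields)
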