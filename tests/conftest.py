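import numpy as np
import pandas as pd
import pytest

from trisoscape import (
    SyntheticConfig,
    gen_climate_grid,
    gen_d18op_field,
    gen_sites,
    standardize_species,
)


def small_config(**kw) -> SyntheticConfig:
    """Reduced domain (coarser step, fewer sites) for fast unit tests."""
    base = dict(step=1.0, n_sites=80, n_stations=40, seed=0)
    base.update(kw)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def default_cfg() -> SyntheticConfig:
    return SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def default_grid(default_cfg):
    return gen_d18op_field(default_cfg, gen_climate_grid(default_cfg))


@pytest.fixture(scope="session")
def default_sites(default_cfg, default_grid) -> pd.DataFrame:
    return standardize_species(gen_sites(default_cfg, default_grid))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
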