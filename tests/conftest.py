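import numpy as np
import pytest

from uelshift import envniche, synthdata as sd


@pytest.fixture(scope="session")
def world_config():
    return sd.WorldConfig(n_background=4000, seed=11)


@pytest.fixture(scope="session")
def background(world_config):
    return sd.make_world(world_config)


@pytest.fixture(scope="session")
def region_config():
    return sd.RegionConfig(n_points=500)


@pytest.fixture(scope="session")
def regional(region_config, world_config):
    return sd.make_region(region_config, world_config, seed=12)


@pytest.fixture(scope="session")
def pca(background):
    return envniche.fit_pca(background)


@pytest.fixture(scope="session")
def step_series():
    """A clean presence/absence step: suitable below 3000 m, not above."""
    rng = np.random.default_rng(42)
    elev = np.sort(rng.uniform(1900, 3600, 400))
    return elev, (elev <= 3000).astype(int)
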