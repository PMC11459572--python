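import numpy as np
import pytest

from fertimap.seeding import substream_seed
from fertimap.synthetic import (
    SimulationConfig,
    simulate_clusters,
    simulate_covariate_rasters,
    simulate_matern_field,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A 60 x 60 km world with 80 clusters — fast but structurally complete."""
    return SimulationConfig(
        region_extent=(0.0, 0.0, 60.0, 60.0),
        n_clusters=80,
        women_per_cluster=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """(stack, field, clusters) generated once for read-only tests."""
    stack = simulate_covariate_rasters(small_config)
    field = simulate_matern_field(
        small_config.grid, small_config.matern,
        substream_seed(small_config.seed, "field"),
    )
    clusters = simulate_clusters(small_config)
    return stack, field, clusters


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
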