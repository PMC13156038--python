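import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from peptidemaps import pairwise_distances
from peptidemaps.simulate import make_atlas

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_atlas():
    """Compact whole-brain atlas: 60 cortical + 20 subcortical + hypothalamus."""
    return make_atlas(60, 20, True, seed=101)


@pytest.fixture(scope="session")
def small_dist(small_atlas):
    return pairwise_distances(small_atlas)


@pytest.fixture(scope="session")
def medium_atlas():
    return make_atlas(120, 30, True, seed=51)


@pytest.fixture(scope="session")
def medium_dist(medium_atlas):
    return pairwise_distances(medium_atlas)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
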