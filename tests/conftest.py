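import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from tmslandscape.networks import default_networks
from tmslandscape.synthetic import make_head_model


@pytest.fixture(scope="session")
def networks():
    return default_networks()


@pytest.fixture(scope="session")
def sensorimotor(networks):
    return networks["sensorimotor"]


@pytest.fixture(scope="session")
def head(networks):
    """Default-geometry head model shared across tests (26 ROIs, 52 voxels)."""
    return make_head_model(52, seed=0, networks=networks)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
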