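import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vaxwill as vw

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def two_node_net():
    """Complete graph on two agents; W is the all-1/2 matrix."""
    return vw.SocialNetwork.from_edges([(0, 1)])


@pytest.fixture
def star4_net():
    """Star with hub 0 and leaves 1..3."""
    return vw.SocialNetwork.from_edges([(0, 1), (0, 2), (0, 3)])


@pytest.fixture(scope="session")
def pa_net():
    """Heavy-tailed preferential-attachment network for pipeline tests."""
    return vw.make_network("preferential-attachment", 120, 8, seed=7)


@pytest.fixture(scope="session")
def er_net():
    return vw.make_network("homogeneous-random", 100, 10, seed=7)


def random_instance(seed: int, n_min: int = 8, n_max: int = 40):
    """Small random connected network plus valid agent parameters."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    kind = ["homogeneous-random", "preferential-attachment", "small-world"][seed % 3]
    net = vw.make_network(kind, max(n, 10), 4, seed=seed)
    lam = rng.random(net.n)
    lam[int(rng.integers(net.n))] = min(lam.min(), 0.5)  # ensure some lam < 1
    p0 = rng.random(net.n)
    return net, vw.AgentParameters(lam=lam, p0=p0)
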