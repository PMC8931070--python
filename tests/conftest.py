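import numpy as np
import pytest

from foodshock.experiments import run_grid
from foodshock.generate import GeneratorParams, fixture, generate_network


@pytest.fixture
def chain3():
    return fixture("chain3")


@pytest.fixture
def star5():
    return fixture("star5")


@pytest.fixture
def twoblock8():
    return fixture("twoblock8")


def small_network(seed: int, n: int = 10, rescale: bool = True):
    """Small generated network; optionally calorie-rescaled to O(100) weights.

    The cascade model is homogeneous of degree one in calories, so rescaling
    only changes units; it keeps cross-implementation comparisons in a range
    where absolute float tolerances are meaningful.
    """
    params = GeneratorParams(n_countries=n, seed=seed, diameter_slack=6)
    net = generate_network(params)
    if rescale:
        net = net.rescaled(100.0 / net.weights.max())
    return net


@pytest.fixture(scope="session")
def default_net():
    """The reference 172-country synthetic network (seed 1)."""
    return generate_network(GeneratorParams(seed=1))


@pytest.fixture(scope="session")
def default_grid(default_net):
    """Full origin x alpha experiment grid on the reference network."""
    return run_grid(default_net)
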