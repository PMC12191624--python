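import numpy as np
import pytest

from mutsampler import (
    CausalNetwork,
    Parameterization,
    default_battery_32,
    load_network,
)


@pytest.fixture(scope="session")
def diamond():
    return load_network("diamond_generative")


@pytest.fixture(scope="session")
def diamond_ya_inh():
    return load_network("diamond_ya_inhibitory")


@pytest.fixture(scope="session")
def diamond_yb_inh():
    return load_network("diamond_yb_inhibitory")


@pytest.fixture(scope="session")
def common_cause():
    return load_network("common_cause")


@pytest.fixture(scope="session")
def chain():
    return load_network("chain")


@pytest.fixture(scope="session")
def common_effect():
    return load_network("common_effect")


@pytest.fixture(scope="session")
def battery32(diamond):
    return default_battery_32(diamond)


@pytest.fixture(scope="session")
def group_params(diamond):
    """Tied parameterization at the group-average fitted values for the
    all-generative condition."""
    return Parameterization.shared(diamond, 0.65, 0.476, 0.454)


def random_shared_params(network, rng, with_inh=False):
    """One random tied parameterization from the generator's default box."""
    return Parameterization.shared(
        network,
        root_prior=rng.uniform(0.4, 0.8),
        w_gen=rng.uniform(0.2, 1.0),
        w_exo=rng.uniform(0.0, 1.0),
        w_inh=rng.uniform(-1.0, -0.2) if with_inh else None,
    )
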