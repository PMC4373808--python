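"""Shared fixtures: benchmark networks and recordings reused across tests.

The heavy simulations (500 s recordings of 50-neuron networks) are session
scoped so that each is run once and shared by the unit and acceptance tests.
"""

import numpy as np
import pytest

import kinising as ki

pytest_plugins = ()

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def fig1_net():
    """Purely excitatory benchmark: N=50, c=0.3, J=0.9 mV, delta=3 ms."""
    return ki.make_random_network(50, 0.3, ki.EfficacySpec.delta(0.9),
                                  ki.DelaySpec.constant(3.0), seed=21)


@pytest.fixture(scope="session")
def fig1_record(fig1_net):
    return ki.simulate(fig1_net, 500_000.0, seed=22)


@pytest.fixture(scope="session")
def fig2_net():
    """Purely excitatory with exponentially distributed delays 1-20 ms."""
    return ki.make_random_network(50, 0.3, ki.EfficacySpec.delta(0.9),
                                  ki.DelaySpec.truncated_exponential(1.0, 20.0),
                                  seed=23)


@pytest.fixture(scope="session")
def fig2_record(fig2_net):
    return ki.simulate(fig2_net, 500_000.0, seed=24)


@pytest.fixture(scope="session")
def ei_net():
    """Mixed E/I benchmark: N_E=N_I=25, c=0.1, J=+-0.54 mV, delays exp 1-20 ms."""
    return ki.make_random_network(50, 0.1, ki.EfficacySpec.delta(0.54),
                                  ki.DelaySpec.truncated_exponential(1.0, 20.0),
                                  population_split=0.5, seed=11)


@pytest.fixture(scope="session")
def ei_record(ei_net):
    return ki.simulate(ei_net, 500_000.0, seed=12)


@pytest.fixture(scope="session")
def ei_corr(ei_record):
    from kinising.raster import binarize
    return ki.compute_correlations(binarize(ei_record, dt=1.0))


@pytest.fixture(scope="session")
def uniform_net():
    """Mixed E/I with uniform efficacy magnitudes in (0, 0.54) mV, delta=3 ms."""
    return ki.make_random_network(50, 0.1, ki.EfficacySpec.uniform(0.0, 0.54),
                                  ki.DelaySpec.constant(3.0),
                                  population_split=0.5, seed=25)


@pytest.fixture(scope="session")
def uniform_record(uniform_net):
    return ki.simulate(uniform_net, 500_000.0, seed=26)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
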