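import numpy as np
import pytest

from synfilter import InputSpec, NeuronParams, OUPrior, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """Short 3-channel tutor session shared by filter tests."""
    prior = OUPrior.homogeneous(3, 0.0, 1.0, 5.0)
    spec = InputSpec(d=3, rate=30.0)
    neuron = NeuronParams(g0=20.0, beta=0.2, tau_m=0.025)
    session = simulate_session(prior, spec, neuron, T=2.0, dt=1e-3, seed=7)
    return prior, neuron, session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
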