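import numpy as np
import pytest

from adaptnet.connectivity import NetworkSpec, WeightMatrix, generate_dale
from adaptnet.dynamics import ModelParams


@pytest.fixture
def small_dale():
    """A small sparse Dale network for fast dynamical tests."""
    spec = NetworkSpec(N=60, f_E=0.5, d=0.5, mu_E=0.1, mu_I_mag=0.1,
                       sigma_E=0.12, sigma_I=0.12, seed=7)
    return generate_dale(spec)


@pytest.fixture
def weak_network():
    """A strongly stable network (tiny weights) that relaxes to a fixed point."""
    rng = np.random.default_rng(3)
    N = 20
    values = rng.normal(0.0, 0.02, size=(N, N))
    labels = np.array(["E"] * 10 + ["I"] * 10)
    return WeightMatrix(values, labels)


@pytest.fixture
def default_params():
    return ModelParams()


@pytest.fixture
def no_adapt_params():
    return ModelParams(sfa_enabled=False, std_enabled=False)
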