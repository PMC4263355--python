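import numpy as np
import pytest

from synprop.model_core import balance_ratio
from synprop.params import StandardParams
from synprop.stimuli import BackgroundSpec


@pytest.fixture(scope="session")
def params():
    return StandardParams()


@pytest.fixture(scope="session")
def alpha(params):
    """Excitation/inhibition balance ratio for the standard parameters."""
    return balance_ratio(params.neuron(), params.kernel_ex(),
                         params.kernel_in())


@pytest.fixture(scope="session")
def balanced_bg(params, alpha):
    return BackgroundSpec(rate_ex=params.bg_rate_ex, rate_in=params.bg_rate_in,
                          eps_ex=params.bg_eps_ex,
                          eps_in=alpha * params.bg_eps_ex)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
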