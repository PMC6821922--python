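import numpy as np
import pytest

from mastsync import ModelParams, simulate


@pytest.fixture(scope="session")
def fig8_like_trajectory():
    """One noisy period-3-regime run: R_C=2, beta=6, e_I=0.2, 106 trees."""
    return simulate(ModelParams(R_C=2.0, beta=6.0, e_I=0.2, e_C=0.0, N=106, seed=0))


@pytest.fixture(scope="session")
def noise_free_sync_trajectory():
    """Noise-free coupled run inside the period-3 window."""
    return simulate(ModelParams(R_C=2.0, beta=6.0, N=30, seed=1, T_record=30))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
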