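import numpy as np
import pytest

from mibgplanar import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def noise_free_study():
    """One default noise-free phantom study (early, delayed, truth)."""
    return generate_phantom(PhantomConfig(noise="none"))


@pytest.fixture(scope="session")
def small_noise_free_study():
    """A 128-px noise-free phantom for cheaper geometry tests."""
    return generate_phantom(PhantomConfig(matrix_size=128, noise="none"))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
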