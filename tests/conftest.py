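import numpy as np
import pytest

from perfcolor.phantom import PhantomParams, add_poisson_noise, generate_clean_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_gray(rng):
    """Random unit-range 64x64 grayscale image."""
    return rng.uniform(0.0, 1.0, size=(64, 64))


@pytest.fixture
def clean_phantom():
    """Noise-free annulus phantom with a moderate defect."""
    return generate_clean_phantom(PhantomParams(defect_severity=0.5, seed=7))


@pytest.fixture
def noisy_phantom(clean_phantom):
    return add_poisson_noise(clean_phantom, counts_scale=200.0, seed=7)
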