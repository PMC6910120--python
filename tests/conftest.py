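import numpy as np
import pytest

from tfield1d.fieldgen import NoiseSpec, SignalSpec, generate_noise


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_noise():
    """A 10 x 101 smooth noise sample (fwhm 20, fixed seed)."""
    return generate_noise(NoiseSpec(J=10, Q=101, fwhm=20.0, seed=7))


@pytest.fixture
def pulse_spec():
    return SignalSpec(q=50.0, sigma=3.0, amp=2.3)
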