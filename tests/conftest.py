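import numpy as np
import pytest

from circatemp.cosinor import _design
from circatemp.series import N_PROFILE_BINS, DayProfile


def profile_from_coeffs(M, a1, b1, a2, b2, channel="chest", counts=7):
    """Noise-free day profile evaluated from cosinor coefficients."""
    t = np.arange(N_PROFILE_BINS) * 5 / 60.0
    y = _design(t) @ np.array([M, a1, b1, a2, b2])
    return DayProfile(y, np.full(N_PROFILE_BINS, counts), channel)


@pytest.fixture
def flat_profile():
    return profile_from_coeffs(36.0, 0, 0, 0, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
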