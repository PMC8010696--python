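import numpy as np
import pytest

from meridianvision import NoiseConfig, SweepStimulus, default_observer


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def observer():
    return default_observer()


@pytest.fixture(scope="session")
def stimulus():
    return SweepStimulus()


@pytest.fixture(scope="session")
def silent_noise():
    """No background noise, no phase jitter: the deterministic EEG limit."""
    return NoiseConfig(pink_rms=0.0, white_rms=0.0, phase_jitter_sd=0.0)


class ForcedResponses:
    """Stand-in RNG whose uniform draws force every trial's outcome: 0 makes
    each comparison u < p succeed (always correct), 1 makes it fail."""

    def __init__(self, value: float):
        self.value = value

    def random(self, n: int) -> np.ndarray:
        return np.full(n, self.value)


@pytest.fixture
def always_correct():
    return ForcedResponses(0.0)


@pytest.fixture
def always_wrong():
    return ForcedResponses(1.0)
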