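import numpy as np
import pytest

from pfcsync import LFPSignal, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tone(freq: float, fs: float, duration: float,
              amp: float = 1.0, phase: float = 0.0) -> LFPSignal:
    t = np.arange(int(round(duration * fs))) / fs
    return LFPSignal(amp * np.cos(2 * np.pi * freq * t + phase), fs)


@pytest.fixture
def fast_config() -> SyntheticConfig:
    """Small experiment for pipeline-level tests."""
    return SyntheticConfig(
        n_vehicle_sessions=2, n_pcp_sessions=2, duration=30.0, fs=500.0,
        n_units_per_session=3, base_rate=3.0, rate_jitter=0.2, seed=7)
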