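import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sleepscore import (
    Channel,
    ScoringConfig,
    SignalVector,
    SynthParams,
    simulate_recording,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg() -> ScoringConfig:
    return ScoringConfig()  # fs 250 Hz, order 3, 4 s epochs


@pytest.fixture(scope="session")
def short_recording():
    """Ten minutes of clean synthetic recording with ground truth."""
    return simulate_recording(SynthParams(duration_s=600.0, seed=11))


@pytest.fixture(scope="session")
def spiky_recording():
    """Ten minutes with injected spike artifacts."""
    return simulate_recording(
        SynthParams(duration_s=600.0, spike_rate_per_min=2.0, seed=12)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_signal(values, fs=250.0, channel=Channel.EEG) -> SignalVector:
    return SignalVector(np.asarray(values, dtype=float), fs=fs, channel=channel)
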