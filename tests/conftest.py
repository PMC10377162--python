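import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tausense as ts

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ref_config() -> ts.InstrumentConfig:
    """Reference instrument: 1023 channels, 109.73 ps/channel, peak 10,000."""
    return ts.InstrumentConfig(seed=0)


@pytest.fixture(scope="session")
def ref_irf(ref_config) -> ts.DecayHistogram:
    return ts.make_irf(ref_config)


@pytest.fixture(scope="session")
def mini_config() -> ts.InstrumentConfig:
    """Small, fast instrument for property tests."""
    return ts.InstrumentConfig(
        n_channels=128, peak_target=2000, irf_center=500.0, seed=0
    )


@pytest.fixture(scope="session")
def mini_irf(mini_config) -> ts.DecayHistogram:
    return ts.make_irf(mini_config)


def make_delta_irf(config: ts.InstrumentConfig) -> ts.DecayHistogram:
    """Single-channel prompt: convolution with it is the identity."""
    counts = np.zeros(config.n_channels, dtype=np.int64)
    counts[0] = config.peak_target
    return ts.DecayHistogram(times=config.times, counts=counts, role="prompt")


@pytest.fixture(scope="session")
def delta_irf(mini_config) -> ts.DecayHistogram:
    return make_delta_irf(mini_config)


def reseed(config: ts.InstrumentConfig, seed: int) -> ts.InstrumentConfig:
    return dataclasses.replace(config, seed=seed)
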