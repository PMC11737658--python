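"""Shared fixtures: small synthetic sessions and record builders."""

import numpy as np
import pytest

from domekit.simulate import SimulationParams, simulate_session
from domekit.timing import TimingConfig


@pytest.fixture(scope="session")
def default_config():
    return TimingConfig()


@pytest.fixture(scope="session")
def clean_session():
    """A short session with no skips, pauses, or photodiode noise."""
    params = SimulationParams(
        n_frames=400,
        skip_probability=0.0,
        noise_sd_fraction=0.0,
        rise_tau_ms=0.0,
        seed=11,
    )
    return simulate_session(params)


@pytest.fixture(scope="session")
def noisy_skip_session():
    """A session at the default study conditions (2% skips, 2% noise)."""
    params = SimulationParams(n_frames=1600, seed=7)
    return simulate_session(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
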