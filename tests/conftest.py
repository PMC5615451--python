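import numpy as np
import pytest

from csfpulse import (
    SyntheticConfig,
    decompose,
    generate_subject,
    phase_to_velocity,
)


@pytest.fixture(scope="session")
def small_config():
    """Default study conditions on a reduced 64-voxel matrix (same physics)."""
    return SyntheticConfig(grid_size=64, seed=0)


@pytest.fixture(scope="session")
def clean_config():
    """Noise- and blur-free variant for exact waveform recovery checks."""
    return SyntheticConfig(grid_size=64, seed=0, noise_sd=0.0, blur_sigma=0.0)


@pytest.fixture(scope="session")
def clean_subject(clean_config):
    phase, truth = generate_subject(clean_config)
    return phase, truth


@pytest.fixture(scope="session")
def clean_components(clean_subject):
    phase, truth = clean_subject
    vel = phase_to_velocity(phase)
    return decompose(vel), truth, vel
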