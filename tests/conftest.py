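import numpy as np
import pytest

from emofusion import SimulationConfig, default_meta, simulate_dataset


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small DEAP-shaped set: 2 subjects x 6 videos, 4 s trials at 128 Hz."""
    return SimulationConfig(
        n_subjects=2,
        n_videos=6,
        duration_s=4.0,
        seed=11,
        eeg_effect=1.0,
        gsr_effect=1.0,
        rating_noise_sd=0.5,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cfg):
    return simulate_dataset(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_meta(tiny_cfg):
    return default_meta(tiny_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
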