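import numpy as np
import pytest

from babelnirs.config import load_config
from babelnirs.simulate import (
    HemodynamicGroundTruth, NoiseModel, make_participants, simulate_cohort,
)


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def montage(config):
    return config.montage


@pytest.fixture(scope="session")
def design(config):
    return config.design


def small_cohort(config, n_per_group=1, amplitude=1.5, noise=None, seed=0):
    """Simulate a small cohort with a uniform injected response."""
    participants = make_participants(n_per_group, n_per_group, n_per_group)
    truth = HemodynamicGroundTruth.uniform(
        participants, config.design.conditions, config.montage.channel_ids,
        hbo2_amplitude=amplitude,
    )
    noise = noise or NoiseModel(seed=seed)
    recordings, truth = simulate_cohort(
        config.design, participants, truth, noise, config.montage
    )
    return recordings, truth


@pytest.fixture(scope="session")
def silent_recording(config):
    """One noise-free recording with a 1.5 umol uniform HbO2 response."""
    recs, truth = small_cohort(config, noise=NoiseModel.silent(11))
    return recs[0], truth


@pytest.fixture(scope="session")
def noisy_recording(config):
    recs, truth = small_cohort(config, seed=13)
    return recs[0], truth
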