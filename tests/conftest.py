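"""Shared fixtures: small synthetic sessions and derived feature series.

Session-scoped so the expensive raw-signal synthesis and AR extraction run
once per test session.
"""

import warnings

import numpy as np
import pytest

from ecogdecode import (SimConfig, extract_features, generate_session,
                        downsample_joystick, label_onset)
from ecogdecode.onset import trial_step_bounds

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_channels=4, n_trials=24, seed=11)


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config)


@pytest.fixture(scope="session")
def small_features(small_session):
    return extract_features(small_session)


@pytest.fixture(scope="session")
def small_labels(small_session, small_features):
    radial = downsample_joystick(small_session.joystick_xy,
                                 fs=small_session.sampling_rate)
    bounds = trial_step_bounds(small_session.trials,
                               small_features.step_times,
                               small_features.n_steps)
    return label_onset(radial, small_session.max_radial_extension, bounds)


@pytest.fixture(scope="session")
def null_config():
    return SimConfig.null_effect(n_channels=4, n_trials=24, seed=13)
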