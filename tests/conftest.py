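"""Shared fixtures: a modest trained auditory map and calibrated configs.

The session-scoped map is trained once on 20k babbled samples — enough
for closed-loop behavior; accuracy-budget checks train their own
full-size map.
"""

import numpy as np
import pytest

import speechsfc as s


@pytest.fixture(scope="session")
def babble_data():
    return s.babble(20_000, seed=7)


@pytest.fixture(scope="session")
def babble_split(babble_data):
    return s.train_test_split_babble(babble_data, seed=7)


@pytest.fixture(scope="session")
def trained_map(babble_split):
    train, _ = babble_split
    return s.AuditoryMap(random_state=7).fit(train.positions, train.formants)


@pytest.fixture(scope="session")
def exact_map():
    return s.ExactAuditoryMap()


@pytest.fixture(scope="session")
def quiet_config():
    """All noise levels zero, no perturbations."""
    return s.SimConfig(noise=s.NoiseConfig(0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def baseline_config(exact_map):
    """Baseline noise levels with norms calibrated on the vowel sequence."""
    return s.calibrate(s.vowel_sequence_score(), s.SimConfig(), exact_map)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
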