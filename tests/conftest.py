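"""Shared fixtures: small seeded synthetic sessions, generated at test time."""

import numpy as np
import pytest

from emgctl.preprocess import make_intensity_profile, prepare_training_set
from emgctl.synth import SynthConfig, generate_training_session


def make_session_data(seed: int, reps: int = 1, cfg: SynthConfig | None = None):
    """Prepared (filtered, windowed, labeled) training set for one session."""
    profile = make_intensity_profile(reps=reps)
    recs = generate_training_session(cfg, seed=seed, profile=profile)
    return prepare_training_set(recs, profile=profile)


@pytest.fixture(scope="session")
def session_data():
    """A 1-repetition training session (about 2.2k windows), seed 101."""
    return make_session_data(101, reps=1)


@pytest.fixture(scope="session")
def session_data_b():
    """An independent session from a different seed, for held-out checks."""
    return make_session_data(202, reps=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
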