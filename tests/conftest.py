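import numpy as np
import pytest

import gaitmet as gm


@pytest.fixture(scope="session")
def templates():
    return gm.default_templates()


@pytest.fixture(scope="session")
def subject():
    return gm.SubjectInfo(height=1.75, mass=70.0, age=30.0, sex="male")


@pytest.fixture(scope="session")
def walk_session(templates):
    """One noise-free 60-s walking session at 1.25 m/s, shared across tests."""
    profile = gm.sample_subjects(1, seed=42)[0]
    session = gm.simulate_session(profile, templates,
                                  gm.steady_protocol("walk", 1.25, 60.0),
                                  gm.NoiseConfig.zero(), seed=42)
    return profile, session


@pytest.fixture(scope="session")
def noisy_walk_session(templates):
    profile = gm.sample_subjects(1, seed=43)[0]
    session = gm.simulate_session(profile, templates,
                                  gm.steady_protocol("walk", 1.25, 60.0),
                                  gm.NoiseConfig(), seed=43)
    return profile, session


@pytest.fixture(scope="session")
def toy_model(templates):
    """A ridge model trained on two synthetic subjects and two conditions."""
    from gaitmet.evaluation import build_cohort, training_matrix
    subjects = gm.sample_subjects(2, seed=5)
    cohort = build_cohort(subjects, templates,
                          [("walk", 1.25), ("run", 2.75)], 60.0,
                          gm.NoiseConfig(), seed=7)
    X, y, _ = training_matrix(cohort, [0, 1])
    return gm.train_on_features(X, y), X, y
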