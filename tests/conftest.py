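import numpy as np
import pytest

from fogseg.io import MarkerTrial
from fogseg.graph import DEFAULT_NODE_NAMES
from fogseg.synth import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_trial(rng):
    """A 9-marker trial with a FOG run in the middle."""
    T = 60
    positions = rng.normal(0, 1, size=(T, 9, 3)).cumsum(axis=0)
    labels = np.zeros(T, dtype=int)
    labels[20:35] = 1
    return MarkerTrial(subject_id="S1", trial_id="S1_T1", rate_hz=100.0,
                       marker_names=DEFAULT_NODE_NAMES,
                       positions=positions, labels=labels)


@pytest.fixture(scope="session")
def small_cohort():
    spec = CohortSpec(n_subjects=3, trials_per_subject=2,
                      trial_duration_s=(6.0, 8.0), nonfreezer_fraction=0.34,
                      seed=5)
    return generate_cohort(spec)
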