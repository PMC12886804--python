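import numpy as np
import pytest
from hypothesis import settings

# derandomized hypothesis profile so CI runs are reproducible
settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def short_reference():
    """A compressed task timing used where full-length trials are not needed."""
    from hapticlab.cohort import TaskReference

    return TaskReference(phase_durations=(1.0, 1.5, 1.5, 1.0, 5.0))


@pytest.fixture(scope="session")
def small_trial(short_reference):
    """One fully generated trial (all three streams), shared across tests."""
    from hapticlab.cohort import generate_trial

    return generate_trial("GV", 1, 1, 42, ref=short_reference, repetitions=1)


@pytest.fixture(scope="session")
def small_envelope(small_trial):
    from hapticlab.metrics import preprocess_emg

    return preprocess_emg(small_trial.emg, 1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
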