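import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ehrcf import default_spec, confounded_spec, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_spec():
    return default_spec(n_subjects=10_000, seed=7)


@pytest.fixture(scope="session")
def demo_cohort(demo_spec):
    return simulate_cohort(demo_spec)


@pytest.fixture(scope="session")
def confounded_cohort():
    return simulate_cohort(confounded_spec(n_subjects=20_000, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_events():
    """Six events for two subjects; subject 1's window is [70, 75]."""
    return pd.DataFrame({
        "subject_id": [1, 1, 1, 1, 1, 2],
        "raw_code": ["401.1", "401.1", "401.1", "401.9", "250.0", "250.0"],
        "event_age": [70.5, 71.0, 74.9, 72.0, 69.0, 66.0],
    })


@pytest.fixture()
def tiny_windows():
    return pd.DataFrame(
        {"age_start": [70.0, 65.0], "age_end": [75.0, 70.0]},
        index=pd.Index([1, 2], name="subject_id"))
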