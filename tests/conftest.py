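import numpy as np
import pytest

from genjust.cohort import (CohortConfig, participants_frame, simulate_cohort,
                            trials_frame)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_cohort():
    """A small cohort with no injected quality failures."""
    cfg = CohortConfig(n_participants=40, bad_fractions={}, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_frames(clean_cohort):
    return trials_frame(clean_cohort), participants_frame(clean_cohort)
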