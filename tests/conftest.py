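import numpy as np
import pytest

import cldqmap as cm


@pytest.fixture(scope="session")
def us5l():
    return cm.ValueSet.us5l()


@pytest.fixture(scope="session")
def floor(us5l):
    return us5l.floor


@pytest.fixture(scope="session")
def scored_cohort_500(us5l):
    """Default synthetic cohort, complete-case filtered and scored."""
    cohort = cm.generate_cohort(500, seed=3)
    complete, _ = cm.filter_complete_cases(cohort)
    return cm.score_cohort(complete, us5l)


@pytest.fixture(scope="session")
def scored_cohort_2000(us5l):
    cohort = cm.generate_cohort(2000, seed=42)
    complete, _ = cm.filter_complete_cases(cohort)
    return cm.score_cohort(complete, us5l)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
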