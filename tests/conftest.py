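import numpy as np
import pytest
from hypothesis import settings

from vitd_centiles import PUBLISHED_MODEL, CohortSpec, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def published():
    return PUBLISHED_MODEL


@pytest.fixture(scope="session")
def cohort_5000():
    """One study-sized synthetic cohort, reused across read-only tests."""
    return generate_cohort(CohortSpec(n=5000, seed=20150901))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
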