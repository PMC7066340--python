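import pytest

import mddvuln as m


@pytest.fixture(scope="session")
def scheme():
    return m.default_scheme()


@pytest.fixture(scope="session")
def cohort():
    return m.reference_cohort()


@pytest.fixture(scope="session")
def summary(cohort, scheme):
    return m.summarize_cohort(cohort, scheme)


@pytest.fixture(scope="session")
def study_params():
    """The canonical cohort parameter vector (mu carried as 0.00342)."""
    return m.STUDY_PARAMETERS


@pytest.fixture(scope="session")
def estimated(summary):
    """Full-precision estimation report from the reference cohort."""
    return m.estimate_all(summary)
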