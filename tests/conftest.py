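import pytest

from ddxfusion import generate_cohort, study_config


@pytest.fixture(scope="session")
def small_cohort():
    """A modest calibrated cohort shared by read-only tests."""
    return generate_cohort(study_config(seed=11, n_cases=60))


@pytest.fixture(scope="session")
def small_cohort_rows(small_cohort):
    from ddxfusion import expand_rows

    return expand_rows(small_cohort)
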