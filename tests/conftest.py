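import pytest

from memrisk import builtin_cohort, run_study_analysis


@pytest.fixture(scope="session")
def cohort():
    """The packaged 14-patient study cohort."""
    return builtin_cohort()


@pytest.fixture(scope="session")
def study_result(cohort):
    """Full group analysis of the packaged cohort (computed once)."""
    return run_study_analysis(cohort)
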