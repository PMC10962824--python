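import pytest

import rehabmcdm as rm


@pytest.fixture(scope="session")
def hierarchy():
    return rm.datasets.default_hierarchy()


@pytest.fixture(scope="session")
def panel():
    return rm.datasets.default_expert_panel()


@pytest.fixture(scope="session")
def cohort_scores():
    """Tidy (patient, assessment, score) table of the packaged cohort."""
    return rm.datasets.cohort_scores()


@pytest.fixture(scope="session")
def patient_scores(cohort_scores):
    return cohort_scores[cohort_scores["patient"] != "healthy"]


@pytest.fixture(scope="session")
def votes():
    return rm.datasets.cohort_expert_votes()


@pytest.fixture(scope="session")
def weights(hierarchy, panel):
    return rm.compute_weights(hierarchy, panel)


@pytest.fixture(scope="session")
def corrected_values(cohort_scores):
    return rm.corrected_value_set(
        cohort_scores[cohort_scores["assessment"] == "I"]["score"],
        cohort_scores[cohort_scores["assessment"] == "II"]["score"],
    )
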