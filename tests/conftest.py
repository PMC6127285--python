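import pytest

import secondhit as sh


@pytest.fixture(scope="session")
def cohort():
    return sh.load_cohort_fixture()


@pytest.fixture(scope="session")
def cohort_results(cohort):
    return sh.run_cohort(cohort)


@pytest.fixture(scope="session")
def cohort_summary(cohort, cohort_results):
    return sh.summarize(cohort_results, cohort)


@pytest.fixture(scope="session")
def gene_map():
    return sh.load_gene_phenotypes()
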