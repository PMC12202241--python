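import pytest

from trialcea import (
    AnalysisConfig,
    GeneratorConfig,
    build_analysis_table,
    bundled_value_set,
    default_unit_cost_table,
    generate_cohort,
)


@pytest.fixture(scope="session")
def unit_costs():
    return default_unit_cost_table()


@pytest.fixture(scope="session")
def value_set():
    return bundled_value_set()


@pytest.fixture(scope="session")
def cohort():
    """Trial-sized synthetic cohort (88 IG / 80 CG), fixed seed."""
    return generate_cohort(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def analysis_table(cohort, unit_costs, value_set):
    return build_analysis_table(cohort, unit_costs, value_set, AnalysisConfig(B=0))
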