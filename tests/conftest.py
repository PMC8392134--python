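import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wes_fixture():
    from ppglval.fixtures import build_table1_fixture

    return build_table1_fixture()


@pytest.fixture(scope="session")
def v1_fixture():
    from ppglval.fixtures import build_v1_validation_fixture

    return build_v1_validation_fixture()


@pytest.fixture(scope="session")
def cohorts():
    from ppglval.fixtures import build_cohort_fixtures

    return build_cohort_fixtures()
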