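import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_cohort():
    from lynchtriage import paper_fixture

    return paper_fixture()


@pytest.fixture(scope="session")
def fixture_decisions(fixture_cohort):
    from lynchtriage import triage_cohort

    return triage_cohort(fixture_cohort)


@pytest.fixture(scope="session")
def fixture_summary(fixture_cohort, fixture_decisions):
    from lynchtriage import cascade_summary

    return cascade_summary(
        fixture_decisions, [p.germline for p in fixture_cohort]
    )
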