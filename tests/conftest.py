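import pytest
from hypothesis import HealthCheck, settings

import occaudit as oa

settings.register_profile(
    "default", deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def kb():
    return oa.load_concept_rules()


@pytest.fixture(scope="session")
def fixture_matrix():
    return oa.load_classification_matrix()


@pytest.fixture(scope="session")
def region_table():
    return oa.load_region_table()


@pytest.fixture(scope="session")
def fixture_records(fixture_matrix):
    return oa.expand_matrix(fixture_matrix, seed=1)


@pytest.fixture(scope="session")
def fixture_classified(fixture_records, kb):
    return oa.classify_records(fixture_records, kb)
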