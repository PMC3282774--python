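import pytest
from hypothesis import settings

from genemeta import MetaConfig, paper_fixture, run_meta

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixture_table():
    return paper_fixture()


@pytest.fixture(scope="session")
def fixture_report(fixture_table):
    return run_meta(fixture_table, MetaConfig())


@pytest.fixture(scope="session")
def fixture_by_id(fixture_table):
    return {r.study_id: r for r in fixture_table}
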