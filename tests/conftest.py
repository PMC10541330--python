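from __future__ import annotations

import pytest

from hrfph import DEFAULT_CONFIG, analyze_cohort, reconstruct_fixture
from hrfph.cohort import FixtureSpec


@pytest.fixture(scope="session")
def config():
    return DEFAULT_CONFIG


@pytest.fixture(scope="session")
def fixture_records(config):
    return reconstruct_fixture(config=config)


@pytest.fixture(scope="session")
def fixture_report(fixture_records, config):
    return analyze_cohort(fixture_records, config)


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec()
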