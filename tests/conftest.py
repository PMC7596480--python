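"""Shared fixtures: miniature configurations that run in seconds."""

import pytest

from tubetransit.synthetic import make_fixture_configs


@pytest.fixture(scope="session")
def fixture_configs():
    return make_fixture_configs()


@pytest.fixture(scope="session")
def oracle_config(fixture_configs):
    return fixture_configs["oracle_equivalence"]
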