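import pytest

from protprops.constants import DEFAULT_TABLES
from protprops.fixtures import worked_example, worked_example_set


@pytest.fixture(scope="session")
def tables():
    return DEFAULT_TABLES


@pytest.fixture(scope="session")
def examples():
    """Worked-example sequences keyed by id."""
    return {rec.seq_id: rec for rec in worked_example_set()}


@pytest.fixture
def axa():
    return worked_example("ambiguous_axa")
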