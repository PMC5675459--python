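import pytest

from pairscreen import table2_fixture


@pytest.fixture(scope="session")
def screen():
    """The embedded two-cell-line reference screen (read-only across tests)."""
    return table2_fixture()
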