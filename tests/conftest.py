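import pytest

from tests.helpers import influential_fixture


@pytest.fixture
def influential_ivs():
    """Instrument set where exactly one SNP ('strong') is influential:
    removing it flips IVW significance, so refinement takes two rounds."""
    return influential_fixture()
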