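import pytest

from nbetascan import (
    ProteinRecord,
    default_profile,
    make_reference_constructs,
    natrxh_like_sequence,
)


@pytest.fixture(scope="session")
def profile():
    return default_profile()


@pytest.fixture(scope="session")
def constructs():
    return make_reference_constructs()


@pytest.fixture(scope="session")
def natrxh_record():
    return ProteinRecord(id="natrxh", sequence=natrxh_like_sequence())
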