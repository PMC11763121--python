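import pytest

from dhnscan.config import RunConfig
from dhnscan.scoring import default_tables


@pytest.fixture(scope="session")
def tables():
    return default_tables()


@pytest.fixture(scope="session")
def cfg():
    return RunConfig()
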