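import pytest

from wcat.frames import default_schema
from wcat.simulate import SimConfig


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture()
def clean_config():
    """Noise-free simulation conditions."""
    return SimConfig(seed=7, mu=0.0)
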