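import pytest
from hypothesis import settings

from tambja import load_table1

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def table1():
    return load_table1()
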