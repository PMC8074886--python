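import pytest
from hypothesis import settings

from cdquant import default_analytes

settings.register_profile("cdquant", derandomize=True, deadline=None,
                          max_examples=100)
settings.load_profile("cdquant")


@pytest.fixture(scope="session")
def analytes():
    return default_analytes()


@pytest.fixture(scope="session")
def leu(analytes):
    return analytes["leu"]


@pytest.fixture(scope="session")
def met(analytes):
    return analytes["met"]
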