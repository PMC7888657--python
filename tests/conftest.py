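import pytest
from hypothesis import settings

from oxcascade.io import default_parameters
from oxcascade.model import Genotype

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def defaults():
    """The shipped calibrated parameter set."""
    return default_parameters()


@pytest.fixture(scope="session")
def wt():
    return Genotype.wild_type()


@pytest.fixture(scope="session")
def dhfixl():
    return Genotype.delta_hfixl()


@pytest.fixture(scope="session")
def dfnrn():
    return Genotype.delta_fnrn()
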