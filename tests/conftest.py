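import numpy as np
import pytest

from tandemdose import nuclear_data as nd
from tandemdose import synthetic as syn


@pytest.fixture(scope="session")
def chains():
    return nd.load_decay_data()


@pytest.fixture(scope="session")
def lu_chain(chains):
    return chains["Lu-177"]


@pytest.fixture(scope="session")
def ac_chain(chains):
    return chains["Ac-225"]


@pytest.fixture(scope="session")
def lu_nuclide(lu_chain):
    return lu_chain.nuclides["Lu-177"]


@pytest.fixture(scope="session")
def ac_nuclide(ac_chain):
    return ac_chain.nuclides["Ac-225"]


@pytest.fixture
def default_config():
    return syn.SimConfig(seed=1)


@pytest.fixture(scope="session")
def paper_grid():
    """The 5-point sampling design used throughout: 1, 4, 24, 48, 168 h."""
    return np.array([1.0, 4.0, 24.0, 48.0, 168.0])
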