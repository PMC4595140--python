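import pytest

from nearhgt.fixtures import make_fixture
from nearhgt.synteny import Genome


@pytest.fixture(scope="session")
def transfer_fixture():
    """Four strains + two references with one implanted transfer."""
    return make_fixture(seed=11)


@pytest.fixture(scope="session")
def null_fixture():
    """Same construction without any transfer."""
    return make_fixture(seed=12, n_transfers=0)


@pytest.fixture
def toy_pair():
    g1 = Genome("G1", tuple("abgcde"))
    g2 = Genome("G2", tuple("cbgaxy"))
    return g1, g2
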