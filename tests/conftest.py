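import pytest

from crossbeta.chemshift import RandomCoilTable
from crossbeta.fibril_model import ideal_inregister_protomer
from crossbeta.synth_data import (
    fibril_core_inputs,
    load_construct,
    mini_arch_fixture,
    q_ladder_fixture,
)

CORE_START = 441


@pytest.fixture(scope="session")
def rc_table():
    return RandomCoilTable.bundled()


@pytest.fixture(scope="session")
def construct():
    return load_construct()


@pytest.fixture(scope="session")
def core_sequence(construct):
    seq, start = construct
    return seq[CORE_START - start:461 - start]


@pytest.fixture(scope="session")
def ideal_strand(core_sequence):
    """Uniform-torsion in-register strand of the fibril core (441-460)."""
    return ideal_inregister_protomer(core_sequence, start_number=CORE_START)


@pytest.fixture(scope="session")
def mini_arch():
    return mini_arch_fixture()


@pytest.fixture(scope="session")
def q_ladder():
    return q_ladder_fixture()


@pytest.fixture(scope="session")
def core_inputs():
    return fibril_core_inputs(seed=7)
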