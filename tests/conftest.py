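import numpy as np
import pytest

from meganumt.fixtures import (
    HV0_COMPONENT, MIXED_MITOTYPE, U4C1_COMPONENT, load_case_fixture,
)
from meganumt.haplogroups import builtin_motif_table
from meganumt.reference import load_reference


@pytest.fixture(scope="session")
def ref():
    return load_reference()


@pytest.fixture(scope="session")
def motifs():
    return builtin_motif_table()


@pytest.fixture(scope="session")
def case():
    return load_case_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20210115)


@pytest.fixture(scope="session")
def mixed_mitotype():
    return MIXED_MITOTYPE


@pytest.fixture(scope="session")
def hv0():
    return HV0_COMPONENT


@pytest.fixture(scope="session")
def u4c1():
    return U4C1_COMPONENT
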