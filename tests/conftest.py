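import numpy as np
import pytest

from gomelt.go_model import Conformation, GoParameters
from gomelt.structure_io import build_contact_map, generate_barrel_fixture


@pytest.fixture(scope="session")
def barrel():
    return generate_barrel_fixture()


@pytest.fixture(scope="session")
def barrel_map(barrel):
    return build_contact_map(barrel)


@pytest.fixture(scope="session")
def go_params():
    return GoParameters()


@pytest.fixture()
def native_conf(barrel):
    return Conformation(barrel.ca_coordinates.copy(), 0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_260_920)


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.729   6.768  -4.123  1.00  0.00           C
ATOM      4  CA  GLY A   2      10.034   5.919  -1.917  1.00  0.00           C
ATOM      5  CA  SER A   3       9.040   8.269   0.912  1.00  0.00           C
TER
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.50  0.00           C
ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.50  0.00           C
ATOM      3  CA  GLY A   2       4.800   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture()
def minimal_pdb_text():
    return MINIMAL_PDB


@pytest.fixture()
def altloc_pdb_text():
    return ALTLOC_PDB
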