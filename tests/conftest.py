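import numpy as np
import pytest

import replidock as rd


@pytest.fixture(scope="session")
def toy():
    """The standard synthetic complex: 30+20 residues, 40 native contacts."""
    return rd.make_toy_complex(30, 20, 40, seed=7)


@pytest.fixture(scope="session")
def decoy_fixture(toy):
    """10 near-native + 90 co-located far decoys with exact ground truth."""
    return rd.make_decoy_fixture(toy, 10, 90, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


MINIMAL_PDB = """\
ATOM      1  N   ALA E   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA E   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA E   1      12.767   7.082  -4.964  1.00  0.00           C
ATOM      4  O   ALA E   1      13.302   7.672  -5.907  1.00  0.00           O
ATOM      5  CB  ALA E   1      10.520   6.356  -4.147  1.00  0.00           C
ATOM      6  N   GLY I   2       2.000   2.000   2.000  1.00  0.00           N
ATOM      7  CA  GLY I   2       3.000   2.500   2.500  1.00  0.00           C
ATOM      8  C   GLY I   2       4.000   2.000   2.000  1.00  0.00           C
ATOM      9  O   GLY I   2       4.500   1.500   3.000  1.00  0.00           O
END
"""

HETATM_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       1.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture()
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture()
def hetatm_pdb(tmp_path):
    p = tmp_path / "hetatm.pdb"
    p.write_text(HETATM_ONLY_PDB)
    return p
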