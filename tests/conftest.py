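import numpy as np
import pytest

from fodm.scales import kd_normalized
from fodm.structure_io import read_structure

# Two ALA residues (two heavy atoms each), one water, one HEM ligand:
# enough to exercise parsing, filtering and effective-atom averaging.
MINI_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.000   0.000   0.000  1.00  0.00           C
ATOM      3  N   GLY A   2       4.000   4.000   0.000  1.00  0.00           N
ATOM      4  CA  GLY A   2       4.000   6.000   0.000  1.00  0.00           C
HETATM    5  O   HOH A 101       9.000   0.000   0.000  1.00  0.00           O
HETATM    6 FE   HEM A 102      12.000   0.000   0.000  1.00  0.00          FE
END
"""


@pytest.fixture(scope="session")
def scale():
    return kd_normalized()


@pytest.fixture
def mini_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return path


@pytest.fixture
def mini_structure(mini_pdb):
    return read_structure(mini_pdb)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250928)


def random_rotation(seed: int) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR of a Gaussian matrix)."""
    g = np.random.default_rng(seed).normal(size=(3, 3))
    q, r = np.linalg.qr(g)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
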