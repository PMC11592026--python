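import numpy as np
import pytest

from pybbq import fixtures as fx

TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.989   2.828   0.000  1.00  0.00           C
ATOM      7  C   GLY A   2       5.504   2.695   0.000  1.00  0.00           C
ATOM      8  O   GLY A   2       6.031   1.590   0.000  1.00  0.00           O
END
"""

TINY_PDB_ALTLOC = TINY_PDB.replace(
    "ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O",
    "ATOM      4  O  AALA A   1       1.251   2.390   0.000  0.60  0.00           O\n"
    "ATOM      9  O  BALA A   1       1.251   2.600   0.000  0.40  0.00           O",
)


@pytest.fixture(scope="session")
def helix_chain():
    return fx.make_ideal_helix(20)


@pytest.fixture(scope="session")
def sheet_chain():
    return fx.make_ideal_sheet(6)


@pytest.fixture(scope="session")
def random_chain():
    return fx.make_synthetic_chain(60, seed=7)


@pytest.fixture(scope="session")
def random_chains():
    return [fx.make_synthetic_chain(40, seed=100 + s) for s in range(5)]


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture
def tiny_pdb_altloc(tmp_path):
    path = tmp_path / "tiny_alt.pdb"
    path.write_text(TINY_PDB_ALTLOC)
    return path


def random_rigid_motion(seed=0):
    """A deterministic random rotation matrix + translation vector."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.normal(scale=10.0, size=3)
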