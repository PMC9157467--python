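import numpy as np
import pytest

from hbondnmr import structio
from hbondnmr.structio import Atom, Model
from hbondnmr.synthdata import make_ideal_helix

TOY_TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.40 10.00           C
ATOM      3  CA BALA A   1       1.400   0.100   0.000  0.60 10.00           C
ATOM      4  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      5  N   ALA A   2       3.300   1.500   0.000  1.00  0.00           N
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.000   0.000   0.100  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.100  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.100  1.00  0.00           C
ENDMDL
END
"""


@pytest.fixture
def toy_two_model_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_TWO_MODEL_PDB)
    return path


@pytest.fixture(scope="session")
def helix12():
    return make_ideal_helix(12)


@pytest.fixture(scope="session")
def helix60():
    return make_ideal_helix(60)


@pytest.fixture
def helix_pdb(tmp_path, helix60):
    path = tmp_path / "helix.pdb"
    structio.write_annotated_structure(helix60[0], {}, path)
    return path


def make_random_nho_model(rng, n_residues=6, box=8.0) -> Model:
    """Random small structure: each residue carries N+H (random orientation)
    and a carbonyl O at a random position, for brute-force cross-checks."""
    atoms = []
    for resnum in range(1, n_residues + 1):
        n = rng.uniform(0, box, size=3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        h = n + 1.02 * direction
        o = rng.uniform(0, box, size=3)
        atoms += [
            Atom("N", "N", resnum, "ALA", "A", tuple(n)),
            Atom("H", "H", resnum, "ALA", "A", tuple(h)),
            Atom("O", "O", resnum, "ALA", "A", tuple(o)),
        ]
    return Model(model_id=1, atoms=atoms)
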