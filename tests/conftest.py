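import numpy as np
import pytest

from softdock.fixtures import make_toy_complex
from softdock.structure import ASPTable, Atom, Structure


@pytest.fixture(scope="session")
def default_table():
    return ASPTable.default()


@pytest.fixture(scope="session")
def toy():
    """One shared toy complex (seed 1) for tests that only read it."""
    return make_toy_complex(1)


def make_structure(coords, chain="A", element="C", resname="UNK", asp=None):
    """Build a pseudo-structure with one atom per residue."""
    table = ASPTable.default()
    atoms = [
        Atom(
            serial=i + 1,
            name="CA",
            element=element,
            resname=resname,
            residue_id=(chain, i + 1, ""),
            coord=tuple(np.asarray(c, dtype=float)),
            vdw_radius=table.radius_of(element),
            asp=asp,
        )
        for i, c in enumerate(coords)
    ]
    return Structure(atoms, id=f"test-{chain}")


@pytest.fixture
def pseudo_structure():
    return make_structure


PDB_THREE_ATOMS = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.750   7.106  -4.953  1.00  0.00           C
END
"""

PDB_TWO_CHAINS = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY B   1       0.000  20.000   0.000  1.00  0.00           C
END
"""

# hydrogens, waters, alternate locations and HETATM must all be filtered
PDB_MESSY = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  HA  ALA A   1       0.500   0.500   0.500  1.00  0.00           H
ATOM      3  CB AALA A   1       1.000   1.000   1.000  0.50  0.00           C
ATOM      4  CB BALA A   1       1.100   1.000   1.000  0.50  0.00           C
HETATM    5  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O
END
"""


@pytest.fixture
def pdb_file(tmp_path):
    def write(content, name="test.pdb"):
        p = tmp_path / name
        p.write_text(content)
        return p

    return write
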