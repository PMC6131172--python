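import numpy as np
import pytest

from confens.structure_io import AtomRecord, Frame


def make_atom(
    name="CA",
    resnum=1,
    xyz=(0.0, 0.0, 0.0),
    chain="A",
    alt="",
    occ=1.0,
    resname="ALA",
    serial=1,
):
    return AtomRecord(
        serial=serial,
        atom_name=name,
        alt_loc=alt,
        residue_name=resname,
        chain_id=chain,
        residue_number=resnum,
        coordinates=np.asarray(xyz, dtype=float),
        occupancy=occ,
    )


def ca_frame(coords, first_residue=1, model_index=0, label="test"):
    """A Cα-trace Frame from an (N, 3) array."""
    atoms = [
        make_atom("CA", first_residue + i, c, serial=i + 1)
        for i, c in enumerate(np.asarray(coords, dtype=float))
    ]
    return Frame(atoms, model_index, label)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_coords(rng):
    def _make(n=10, scale=5.0):
        return rng.normal(scale=scale, size=(n, 3))

    return _make


MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1      11.104   6.134  -6.504  1.00  0.00\n"
    "END\n"
)

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.100   0.000   0.000  1.00  0.00
ATOM      2  CA  ALA A   1       1.558   0.000   0.000  1.00  0.00
ATOM      3  C   ALA A   1       2.109   1.420   0.000  1.00  0.00
ENDMDL
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def two_model_pdb(tmp_path):
    p = tmp_path / "two_model.pdb"
    p.write_text(TWO_MODEL_PDB)
    return p
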