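"""Shared fixtures: small inline PDB texts and synthetic ensembles."""

import numpy as np
import pytest

import coldadapt as ca

# 3-residue toy peptide (ALA-GLY-ALA), 16 atoms including one N-terminal
# hydrogen and a C-terminal OXT; coordinates in angstroms.
TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  H   ALA A   1       0.000   1.000   0.000  1.00  0.00           H
ATOM      3  CA  ALA A   1       1.500   0.400   0.100  1.00  0.00           C
ATOM      4  C   ALA A   1       3.000   0.000   0.000  1.00  0.00           C
ATOM      5  O   ALA A   1       3.100  -1.200   0.100  1.00  0.00           O
ATOM      6  CB  ALA A   1       1.600   1.900   0.300  1.00  0.00           C
ATOM      7  N   GLY A   2       4.000   0.900   0.000  1.00  0.00           N
ATOM      8  CA  GLY A   2       5.500   0.500   0.200  1.00  0.00           C
ATOM      9  C   GLY A   2       6.900   1.000   0.000  1.00  0.00           C
ATOM     10  O   GLY A   2       7.000   2.200   0.100  1.00  0.00           O
ATOM     11  N   ALA A   3       8.000   0.200   0.000  1.00  0.00           N
ATOM     12  CA  ALA A   3       9.500   0.600   0.100  1.00  0.00           C
ATOM     13  C   ALA A   3      10.900   0.100   0.000  1.00  0.00           C
ATOM     14  O   ALA A   3      11.000  -1.100   0.200  1.00  0.00           O
ATOM     15  CB  ALA A   3       9.600   2.100   0.400  1.00  0.00           C
ATOM     16  OXT ALA A   3      12.000   0.900   0.000  1.00  0.00           O
TER
END
"""

TOY_PDB_WITH_MG = TOY_PDB.replace(
    "TER\nEND\n",
    "TER\n"
    "HETATM   17 MG    MG A 100       5.000   5.000   5.000  1.00  0.00"
    "          MG\n"
    "END\n",
)


@pytest.fixture
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture
def toy_pdb_mg(tmp_path):
    p = tmp_path / "toy_mg.pdb"
    p.write_text(TOY_PDB_WITH_MG)
    return p


@pytest.fixture
def toy_structure(toy_pdb):
    return ca.read_structure(toy_pdb)


@pytest.fixture(scope="session")
def basin_pair():
    """Two 10-residue basin references with fitted RMSD ~5 nm apart."""
    return ca.make_basin_references(2, 10, separation=5.0, seed=11)


@pytest.fixture(scope="session")
def disjoint_ensembles(basin_pair):
    """One ensemble per basin, 500 frames each, jitter 0.05 nm."""
    spec = ca.BasinSpec(
        basin_pair, [np.array([1.0, 0.0]), np.array([0.0, 1.0])],
        intra_basin_sigma=0.05, min_separation=4.0, n_frames=500, seed=7)
    return ca.gen_basin_mixture(spec, 0), ca.gen_basin_mixture(spec, 1)


def multi_model_pdb(tmp_path, n_models, drop_atom_in_model=None):
    """Write TOY_PDB as an n-model trajectory, optionally corrupting one
    model by removing an atom."""
    body = [ln for ln in TOY_PDB.splitlines() if ln.startswith("ATOM")]
    lines = []
    for k in range(1, n_models + 1):
        lines.append(f"MODEL {k:>8d}")
        model_body = body[:-1] if k == drop_atom_in_model else body
        lines.extend(model_body)
        lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    p = tmp_path / f"traj_{n_models}.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p
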