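import numpy as np
import pytest

from ppihotspots.structure import AtomRecord, ProteinStructure, Residue


def single_atom_structure(element="C", pos=(0.0, 0.0, 0.0), aa="GLY", name="CA"):
    res = Residue("A", 1, "", aa, [AtomRecord(1, name, element, np.asarray(pos, float))])
    return ProteinStructure("toy", [res])


def cluster_structure(positions, element="C"):
    """All atoms in one glycine 'residue' -- convenient for SASA tests."""
    atoms = [
        AtomRecord(i + 1, f"C{i}" if i else "CA", element, np.asarray(p, float))
        for i, p in enumerate(positions)
    ]
    res = Residue("A", 1, "", "GLY", atoms)
    return ProteinStructure("cluster", [res])


def residue_at(chain, number, aa, atom_specs):
    """atom_specs: list of (name, element, xyz)."""
    atoms = [
        AtomRecord(i + 1, n, e, np.asarray(p, float))
        for i, (n, e, p) in enumerate(atom_specs)
    ]
    return Residue(chain, number, "", aa, atoms)


@pytest.fixture
def three_res_pdb():
    """Minimal hand-written three-residue single-chain PDB."""
    return "\n".join([
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C",
        "ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C",
        "ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O",
        "ATOM      5  CB  ALA A   1       2.000  -0.760   1.200  1.00  0.00           C",
        "ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N",
        "ATOM      7  CA  GLY A   2       3.989   2.836   0.000  1.00  0.00           C",
        "ATOM      8  C   GLY A   2       5.504   2.705   0.000  1.00  0.00           C",
        "ATOM      9  O   GLY A   2       6.030   1.595   0.000  1.00  0.00           O",
        "ATOM     10  N   SER A   3       6.204   3.832   0.000  1.00  0.00           N",
        "ATOM     11  CA  SER A   3       7.660   3.843   0.000  1.00  0.00           C",
        "ATOM     12  C   SER A   3       8.224   5.256   0.000  1.00  0.00           C",
        "ATOM     13  O   SER A   3       7.477   6.234   0.000  1.00  0.00           O",
        "ATOM     14  CB  SER A   3       8.200   3.100   1.230  1.00  0.00           C",
        "ATOM     15  OG  SER A   3       8.000   1.710   1.160  1.00  0.00           O",
        "TER",
        "END",
    ]) + "\n"


@pytest.fixture
def altloc_pdb():
    return "\n".join([
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.60  0.00           C",
        "ATOM      3  CA BALA A   1       1.500   0.100   0.000  0.40  0.00           C",
        "ATOM      4  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C",
        "ATOM      5  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O",
        "END",
    ]) + "\n"


def make_two_part_pdb(gap: float):
    """Two single-residue chains whose closest atoms are ``gap`` A apart."""
    lines = [
        "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C",
        "ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C",
        "ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O",
        "TER",
        f"ATOM      5  N   GLY B   1      {2.009 + gap:8.3f}{1.420:8.3f}{0.0:8.3f}  1.00  0.00           N",
        f"ATOM      6  CA  GLY B   1      {3.467 + gap:8.3f}{1.420:8.3f}{0.0:8.3f}  1.00  0.00           C",
        f"ATOM      7  C   GLY B   1      {4.018 + gap:8.3f}{2.840:8.3f}{0.0:8.3f}  1.00  0.00           C",
        f"ATOM      8  O   GLY B   1      {3.260 + gap:8.3f}{3.810:8.3f}{0.0:8.3f}  1.00  0.00           O",
        "TER",
        "END",
    ]
    return "\n".join(lines) + "\n"


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.cos(angle / 2)
    b, c, d = -axis * np.sin(angle / 2)
    return np.array([
        [a * a + b * b - c * c - d * d, 2 * (b * c + a * d), 2 * (b * d - a * c)],
        [2 * (b * c - a * d), a * a + c * c - b * b - d * d, 2 * (c * d + a * b)],
        [2 * (b * d + a * c), 2 * (c * d - a * b), a * a + d * d - b * b - c * c],
    ])


def transform_structure(structure: ProteinStructure, R, t) -> ProteinStructure:
    new_res = []
    for res in structure.residues:
        atoms = [
            AtomRecord(a.serial, a.name, a.element, R @ a.position + t, a.occupancy, a.altloc)
            for a in res.atoms
        ]
        new_res.append(Residue(res.chain, res.number, res.icode, res.aa, atoms))
    return ProteinStructure(structure.id, new_res)
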