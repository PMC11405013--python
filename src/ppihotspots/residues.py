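"""Residue topology and extended-conformation templates.

Heavy-atom connectivity for the 20 canonical residues, plus an internal-
coordinate description used to build each residue's *extended reference*
conformation (extended backbone, anti side-chain rotamers).  The reference
conformation is the declared zero of the per-residue gas-phase energy ledger;
it is built deterministically by a natural-extension (NeRF) tree walk and
cached per amino-acid type.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

BACKBONE = ("N", "CA", "C", "O")

#: Heavy-atom side-chain bonds per residue type (backbone N-CA-C=O implied).
SIDE_BONDS: dict[str, tuple[tuple[str, str], ...]] = {
    "ALA": (("CA", "CB"),),
    "ARG": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2")),
    "ASN": (("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")),
    "ASP": (("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")),
    "CYS": (("CA", "CB"), ("CB", "SG")),
    "GLN": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")),
    "GLU": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")),
    "GLY": (),
    "HIS": (("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"),
            ("CE1", "NE2"), ("NE2", "CD2")),
    "ILE": (("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")),
    "LEU": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")),
    "LYS": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")),
    "MET": (("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")),
    "PHE": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")),
    "PRO": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")),
    "SER": (("CA", "CB"), ("CB", "OG")),
    "THR": (("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")),
    "TRP": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"),
            ("NE1", "CE2"), ("CE2", "CD2"), ("CD2", "CE3"), ("CE2", "CZ2"),
            ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")),
    "TYR": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH")),
    "VAL": (("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")),
}


def residue_bonds(aa: str) -> list[tuple[str, str]]:
    """All heavy-atom bonds of one residue (backbone + side chain)."""
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    bonds += list(SIDE_BONDS[aa])
    return bonds


def heavy_atoms(aa: str) -> list[str]:
    names = list(BACKBONE)
    for a, b in SIDE_BONDS[aa]:
        for x in (a, b):
            if x not in names:
                names.append(x)
    return names


#: Side-chain internal coordinates: atom placed from (p1, p2, p3) with bond
#: length r (A), angle at p1 (deg) and dihedral atom-p1-p2-p3 (deg).  Chains
#: use anti (180 deg) rotamers; rings are laid out approximately planar.
_Z = {
    "ARG": [("CG", "CB", "CA", "N", 1.52, 111, 180), ("CD", "CG", "CB", "CA", 1.52, 111, 180),
            ("NE", "CD", "CG", "CB", 1.47, 111, 180), ("CZ", "NE", "CD", "CG", 1.33, 124, 180),
            ("NH1", "CZ", "NE", "CD", 1.33, 120, 0), ("NH2", "CZ", "NE", "CD", 1.33, 120, 180)],
    "ASN": [("CG", "CB", "CA", "N", 1.52, 111, 180), ("OD1", "CG", "CB", "CA", 1.23, 120, 0),
            ("ND2", "CG", "CB", "CA", 1.33, 120, 180)],
    "ASP": [("CG", "CB", "CA", "N", 1.52, 111, 180), ("OD1", "CG", "CB", "CA", 1.25, 118, 0),
            ("OD2", "CG", "CB", "CA", 1.25, 118, 180)],
    "CYS": [("SG", "CB", "CA", "N", 1.81, 111, 180)],
    "GLN": [("CG", "CB", "CA", "N", 1.52, 111, 180), ("CD", "CG", "CB", "CA", 1.52, 111, 180),
            ("OE1", "CD", "CG", "CB", 1.23, 120, 0), ("NE2", "CD", "CG", "CB", 1.33, 120, 180)],
    "GLU": [("CG", "CB", "CA", "N", 1.52, 111, 180), ("CD", "CG", "CB", "CA", 1.52, 111, 180),
            ("OE1", "CD", "CG", "CB", 1.25, 118, 0), ("OE2", "CD", "CG", "CB", 1.25, 118, 180)],
    "HIS": [("CG", "CB", "CA", "N", 1.50, 111, 180), ("ND1", "CG", "CB", "CA", 1.38, 122, 90),
            ("CD2", "CG", "CB", "CA", 1.36, 129, -90), ("CE1", "ND1", "CG", "CB", 1.32, 108, 180),
            ("NE2", "CE1", "ND1", "CG", 1.32, 109, 0)],
    "ILE": [("CG1", "CB", "CA", "N", 1.53, 111, 180), ("CG2", "CB", "CA", "N", 1.53, 111, -60),
            ("CD1", "CG1", "CB", "CA", 1.52, 111, 180)],
    "LEU": [("CG", "CB", "CA", "N", 1.53, 116, 180), ("CD1", "CG", "CB", "CA", 1.52, 111, 60),
            ("CD2", "CG", "CB", "CA", 1.52, 111, 180)],
    "LYS": [("CG", "CB", "CA", "N", 1.52, 111, 180), ("CD", "CG", "CB", "CA", 1.52, 111, 180),
            ("CE", "CD", "CG", "CB", 1.52, 111, 180), ("NZ", "CE", "CD", "CG", 1.49, 111, 180)],
    "MET": [("CG", "CB", "CA", "N", 1.52, 111, 180), ("SD", "CG", "CB", "CA", 1.81, 112, 180),
            ("CE", "SD", "CG", "CB", 1.79, 100, 180)],
    "PHE": [("CG", "CB", "CA", "N", 1.50, 114, 180), ("CD1", "CG", "CB", "CA", 1.39, 120, 90),
            ("CD2", "CG", "CB", "CA", 1.39, 120, -90), ("CE1", "CD1", "CG", "CB", 1.39, 120, 180),
            ("CE2", "CD2", "CG", "CB", 1.39, 120, 180), ("CZ", "CE1", "CD1", "CG", 1.39, 120, 0)],
    "PRO": [("CG", "CB", "CA", "N", 1.50, 104, 30), ("CD", "CG", "CB", "CA", 1.51, 104, -35)],
    "SER": [("OG", "CB", "CA", "N", 1.42, 111, 180)],
    "THR": [("OG1", "CB", "CA", "N", 1.42, 109, 180), ("CG2", "CB", "CA", "N", 1.53, 111, -60)],
    "TRP": [("CG", "CB", "CA", "N", 1.50, 114, 180), ("CD1", "CG", "CB", "CA", 1.37, 127, 90),
            ("CD2", "CG", "CB", "CA", 1.43, 127, -90), ("NE1", "CD1", "CG", "CB", 1.38, 110, 180),
            ("CE2", "NE1", "CD1", "CG", 1.37, 109, 0), ("CE3", "CD2", "CG", "CB", 1.40, 134, 180),
            ("CZ2", "CE2", "NE1", "CD1", 1.40, 130, 180), ("CZ3", "CE3", "CD2", "CG", 1.39, 118, 180),
            ("CH2", "CZ2", "CE2", "NE1", 1.39, 122, 180)],
    "TYR": [("CG", "CB", "CA", "N", 1.50, 114, 180), ("CD1", "CG", "CB", "CA", 1.39, 120, 90),
            ("CD2", "CG", "CB", "CA", 1.39, 120, -90), ("CE1", "CD1", "CG", "CB", 1.39, 120, 180),
            ("CE2", "CD2", "CG", "CB", 1.39, 120, 180), ("CZ", "CE1", "CD1", "CG", 1.39, 120, 0),
            ("OH", "CZ", "CE1", "CD1", 1.38, 120, 180)],
    "ALA": [], "GLY": [], "VAL": [
            ("CG1", "CB", "CA", "N", 1.53, 111, 180), ("CG2", "CB", "CA", "N", 1.53, 111, -60)],
}


def nerf_place(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
               r: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    """Place atom X with |X-p1| = r, angle(X,p1,p2) = theta and dihedral
    (X,p1,p2,p3) = phi (natural extension reference frame)."""
    theta, phi = math.radians(theta_deg), math.radians(phi_deg)
    bc = p1 - p2
    bc /= np.linalg.norm(bc)
    ab = p2 - p3
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:  # collinear frame; pick any perpendicular
        n = np.cross(bc, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(n) < 1e-10:
            n = np.cross(bc, np.array([0.0, 1.0, 0.0]))
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d = np.array([
        -r * math.cos(theta),
        r * math.sin(theta) * math.cos(phi),
        r * math.sin(theta) * math.sin(phi),
    ])
    return p1 + d[0] * bc + d[1] * m + d[2] * n


@lru_cache(maxsize=32)
def extended_template(aa: str) -> dict[str, np.ndarray]:
    """Heavy-atom coordinates of one residue in the extended reference
    conformation (deterministic; cached per residue type)."""
    if aa not in SIDE_BONDS:
        raise ValueError(f"unknown amino acid {aa!r}")
    coords: dict[str, np.ndarray] = {}
    coords["N"] = np.zeros(3)
    coords["CA"] = np.array([1.458, 0.0, 0.0])
    # C in the xy plane with tetrahedral-ish N-CA-C angle
    ang = math.radians(180.0 - 111.2)
    coords["C"] = coords["CA"] + 1.525 * np.array([math.cos(ang), math.sin(ang), 0.0])
    coords["O"] = nerf_place(coords["C"], coords["CA"], coords["N"], 1.231, 120.5, -45.0)
    if aa != "GLY":
        coords["CB"] = nerf_place(coords["CA"], coords["C"], coords["N"], 1.53, 110.5, 122.6)
    for name, p1, p2, p3, r, theta, phi in _Z[aa]:
        coords[name] = nerf_place(coords[p1], coords[p2], coords[p3], r, theta, phi)
    return coords
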