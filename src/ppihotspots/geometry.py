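"""Coordinate-level geometry: solvent accessibility, contacts and interfaces.

Solvent-accessible surface area (SASA) is computed with the Shrake-Rupley
rolling-probe algorithm on a deterministic golden-spiral point lattice
(default 960 points/atom, probe 1.4 A).  Contact predicates use Bondi van der
Waals radii.  Interface residues follow the standard definition: a residue of
the target protein with at least one atom within a distance cutoff (default
5 A) of any partner-protein atom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import ComplexStructure, ProteinStructure, Residue

#: Bondi (1964) van der Waals radii, Angstrom.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

PROBE_RADIUS = 1.4


def vdw_radius(element: str) -> float:
    r = VDW_RADII.get(element.upper())
    if r is None:
        raise ValueError(f"no van der Waals radius for element {element!r}")
    return r


@dataclass
class SasaResult:
    per_residue: dict[tuple[str, int, str], float]
    per_atom: dict[tuple, float] = field(default_factory=dict)

    def total(self) -> float:
        return float(sum(self.per_residue.values()))


@dataclass
class InterfaceAnnotation:
    interface: set[tuple[str, int, str]]
    cutoff: float = 5.0


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` near-uniform points on the unit sphere (deterministic lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = math.pi * (3.0 - math.sqrt(5.0)) * i
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _heavy_atoms(structure: ProteinStructure):
    """(residue key, atom name, element, position) for all heavy atoms."""
    out = []
    for res in structure.residues:
        for a in res.atoms:
            if a.element != "H":
                out.append((res.key, a.name, a.element, a.position))
    return out


def shrake_rupley_sasa(
    structure: ProteinStructure,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = 960,
) -> SasaResult:
    """Per-residue (and per-atom) SASA in A^2, heavy atoms only."""
    atoms = _heavy_atoms(structure)
    if not atoms:
        raise ValueError("no heavy atoms")
    coords = np.array([a[3] for a in atoms])
    radii = np.array([vdw_radius(a[2]) + probe_radius for a in atoms])
    sphere = golden_spiral_points(n_points)

    tree = cKDTree(coords)
    rmax = radii.max()
    per_atom: dict[tuple, float] = {}
    per_res: dict[tuple[str, int, str], float] = {}
    for i, (key, name, _elem, pos) in enumerate(atoms):
        pts = pos + radii[i] * sphere
        neigh = [j for j in tree.query_ball_point(pos, radii[i] + rmax) if j != i]
        accessible = np.ones(len(pts), dtype=bool)
        for j in neigh:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > radii[j] ** 2
        area = accessible.mean() * 4.0 * math.pi * radii[i] ** 2
        per_atom[(key, name)] = float(area)
        per_res[key] = per_res.get(key, 0.0) + float(area)
    for key in structure.keys:
        per_res.setdefault(key, 0.0)
    return SasaResult(per_residue=per_res, per_atom=per_atom)


# ---------------------------------------------------------------------------
# contact predicates


def vdw_contact(res_a: Residue, res_b: Residue, tolerance: float = 0.5) -> bool:
    """True iff some heavy-atom pair is within the sum of vdW radii plus
    ``tolerance`` (inclusive boundary)."""
    for a in res_a.atoms:
        if a.element == "H":
            continue
        ra = vdw_radius(a.element)
        for b in res_b.atoms:
            if b.element == "H":
                continue
            cut = ra + vdw_radius(b.element) + tolerance
            d = float(np.linalg.norm(a.position - b.position))
            if d <= cut + 1e-9:
                return True
    return False


#: Heavy-atom hydrogen-bond donors per residue type: donor atom -> bonded
#: antecedent used for the angle test.
HB_DONORS: dict[str, dict[str, str]] = {
    "*": {"N": "CA"},  # backbone amide
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "CYS": {"SG": "CB"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "LYS": {"NZ": "CE"},
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "HIS": {"ND1": "CG", "NE2": "CE1"},
    "TRP": {"NE1": "CD1"},
}

#: Heavy-atom hydrogen-bond acceptors per residue type.
HB_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "*": ("O", "OXT"),  # backbone carbonyl / C-terminus
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
}


def _donors(res: Residue):
    table = dict(HB_DONORS["*"])
    table.update(HB_DONORS.get(res.aa, {}))
    for name, ante in table.items():
        d, a = res.atom(name), res.atom(ante)
        if d is not None and a is not None:
            yield d, a


def _acceptors(res: Residue):
    names = HB_ACCEPTORS["*"] + HB_ACCEPTORS.get(res.aa, ())
    for name in names:
        a = res.atom(name)
        if a is not None:
            yield a


def hydrogen_bond(
    res_a: Residue,
    res_b: Residue,
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> bool:
    """Geometric hydrogen bond between two residues (either direction).

    Heavy-atom criterion, usable when hydrogens are absent: a donor-acceptor
    pair within ``d_max`` with antecedent-donor-acceptor angle >= ``angle_min``
    degrees.
    """
    for donor_res, accept_res in ((res_a, res_b), (res_b, res_a)):
        for donor, ante in _donors(donor_res):
            for acc in _acceptors(accept_res):
                d = float(np.linalg.norm(donor.position - acc.position))
                if d > d_max or d < 1e-6:
                    continue
                v1 = ante.position - donor.position
                v2 = acc.position - donor.position
                cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                if angle >= angle_min:
                    return True
    return False


# ---------------------------------------------------------------------------
# interfaces


def interface_residues(complex_: ComplexStructure, cutoff: float = 5.0) -> InterfaceAnnotation:
    """Target-side residues with >=1 atom within ``cutoff`` of any partner atom."""
    if not complex_.part_a.residues or not complex_.part_b.residues:
        raise ValueError("both sides of the complex must be non-empty")
    b_coords = np.vstack([res.coords(heavy_only=False) for res in complex_.part_b.residues])
    tree = cKDTree(b_coords)
    iface: set[tuple[str, int, str]] = set()
    for res in complex_.part_a.residues:
        d, _ = tree.query(res.coords(heavy_only=False), k=1)
        if np.min(d) <= cutoff:
            iface.add(res.key)
    return InterfaceAnnotation(interface=iface, cutoff=cutoff)


def classify_hotspot_site(
    hotspots: set[tuple[str, int, str]],
    complexes: list[ComplexStructure],
    d_max: float = 3.5,
    angle_min: float = 120.0,
    tolerance: float = 0.5,
) -> dict[tuple[str, int, str], str]:
    """Label each hot-spot residue ``interface`` or ``noninterface``.

    A hot spot is an interface one if it makes a hydrogen bond or a vdW
    contact with the partner side in *any* of the provided complexes.
    """
    out: dict[tuple[str, int, str], str] = {}
    for key in sorted(hotspots):
        found = None
        for cx in complexes:
            res = cx.part_a.get(key)
            if res is None:
                continue
            found = found or "noninterface"
            for other in cx.part_b.residues:
                if vdw_contact(res, other, tolerance=tolerance) or hydrogen_bond(
                    res, other, d_max=d_max, angle_min=angle_min
                ):
                    found = "interface"
                    break
            if found == "interface":
                break
        if found is None:
            raise ValueError(f"hot-spot key not resolvable in any complex: {key}")
        out[key] = found
    return out
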