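"""Per-residue gas-phase molecular-mechanics energy decomposition.

For each residue *i* of a folded structure we report, in kcal/mol,

* ``E_vdw`` and ``E_ele`` -- half of every inter-residue Lennard-Jones 12-6 /
  Coulomb pair term touching *i* (the standard half-split per-residue
  decomposition, so the per-residue ledger sums exactly to the total
  inter-residue nonbonded energy),
* ``E_int`` -- the intra-residue nonbonded energy (1-4 pairs scaled, closer
  pairs excluded) minus the same quantity for the residue's extended
  reference template, and
* ``E_gas = E_int + E_vdw + E_ele``.

The parameter set is a heavy-atom united table shipped with the package
(hydrogen charges summed onto the bonded heavy atom, Amber-style element
Lennard-Jones constants).  It is a self-contained approximation designed for
reproducibility, not a re-parameterization of any published all-atom force
field; an adapter accepts externally computed per-residue energy tables.

Exclusion rules follow molecular-mechanics convention: bonded-path distances
1 and 2 excluded, distance 3 (the "1-4" pairs) scaled by 1/2.0 (vdW) and
1/1.2 (electrostatics), both within residues and across peptide bonds.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .residues import extended_template, heavy_atoms, residue_bonds
from .structure import ProteinStructure, Residue, AtomRecord

logger = logging.getLogger(__name__)

COULOMB_K = 332.0636  # kcal*A/(mol*e^2)
SCALE_VDW_14 = 1.0 / 2.0
SCALE_ELE_14 = 1.0 / 1.2
PEPTIDE_CN_MAX = 1.9  # A; consecutive residues closer than this are bonded


@dataclass(frozen=True)
class AtomParams:
    charge: float
    rmin_half: float
    epsilon: float


class ForceFieldParams:
    """Per-(residue type, atom name) charges and Lennard-Jones constants."""

    def __init__(self, table: dict[tuple[str, str], AtomParams], version: str = "custom"):
        self.table = table
        self.version = version

    @classmethod
    def default(cls) -> "ForceFieldParams":
        text = resources.files("ppihotspots.data").joinpath("forcefield.tsv").read_text()
        table: dict[tuple[str, str], AtomParams] = {}
        version = "v1"
        for line in text.splitlines():
            if line.startswith("#") or line.startswith("aa\t") or not line.strip():
                if line.startswith("#") and " v" in line:
                    version = line.rsplit(" ", 1)[-1]
                continue
            aa, atom, q, r2, eps = line.split("\t")
            table[(aa, atom)] = AtomParams(float(q), float(r2), float(eps))
        return cls(table, version=version)

    def lookup(self, aa: str, atom_name: str) -> AtomParams:
        p = self.table.get((aa, atom_name))
        if p is None:
            raise KeyError(f"no parameters for {aa}:{atom_name}")
        return p

    def has(self, aa: str, atom_name: str) -> bool:
        return (aa, atom_name) in self.table


@dataclass
class EnergyDecomposition:
    """Per-residue energy ledger (kcal/mol), keyed like the structure."""

    e_int: dict[tuple, float]
    e_vdw: dict[tuple, float]
    e_ele: dict[tuple, float]
    incomplete: set[tuple] = field(default_factory=set)

    @property
    def e_gas(self) -> dict[tuple, float]:
        return {k: self.e_int[k] + self.e_vdw[k] + self.e_ele[k] for k in self.e_int}

    def total_inter(self) -> float:
        return sum(self.e_vdw.values()) + sum(self.e_ele.values())


def pair_nonbonded(
    pos_i: np.ndarray,
    pos_j: np.ndarray,
    prm_i: AtomParams,
    prm_j: AtomParams,
) -> tuple[float, float]:
    """(vdW, electrostatic) energy of one atom pair, kcal/mol.

    Lennard-Jones 12-6 with arithmetic r_min / geometric epsilon combination;
    Coulomb with k = 332.0636 kcal*A/(mol*e^2).
    """
    r = float(np.linalg.norm(np.asarray(pos_i, float) - np.asarray(pos_j, float)))
    if r <= 0.0:
        raise ValueError("zero interatomic distance")
    rmin = prm_i.rmin_half + prm_j.rmin_half
    eps = math.sqrt(prm_i.epsilon * prm_j.epsilon)
    s6 = (rmin / r) ** 6
    vdw = eps * (s6 * s6 - 2.0 * s6)
    ele = COULOMB_K * prm_i.charge * prm_j.charge / r
    return vdw, ele


# ---------------------------------------------------------------------------
# bond graph and exclusions


def _atom_index(structure: ProteinStructure, params: ForceFieldParams):
    """Flatten parameterized heavy atoms; returns lists and a lookup map."""
    atoms = []  # (res_idx, name, position, AtomParams)
    index: dict[tuple[int, str], int] = {}
    incomplete: set[tuple] = set()
    for ri, res in enumerate(structure.residues):
        names_present = set()
        for a in res.atoms:
            if a.element == "H":
                continue
            if a.name == "OXT":  # C-terminal carboxylate oxygen: reuse O params
                prm = params.lookup(res.aa, "O")
            elif params.has(res.aa, a.name):
                prm = params.lookup(res.aa, a.name)
            else:
                logger.warning("unparameterized atom %s in %s %s; skipped", a.name, res.aa, res.key)
                continue
            index[(ri, a.name)] = len(atoms)
            atoms.append((ri, a.name, a.position, prm))
            names_present.add(a.name)
        missing = set(heavy_atoms(res.aa)) - names_present
        if missing:
            logger.warning("residue %s %s missing heavy atoms %s", res.aa, res.key, sorted(missing))
            incomplete.add(res.key)
    return atoms, index, incomplete


def _bond_adjacency(structure: ProteinStructure, index, n_atoms: int) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(n_atoms)]

    def link(i, j):
        adj[i].append(j)
        adj[j].append(i)

    for ri, res in enumerate(structure.residues):
        for a, b in residue_bonds(res.aa):
            ia, ib = index.get((ri, a)), index.get((ri, b))
            if ia is not None and ib is not None:
                link(ia, ib)
        ioxt, ic = index.get((ri, "OXT")), index.get((ri, "C"))
        if ioxt is not None and ic is not None:
            link(ioxt, ic)
    # peptide bonds between consecutive residues of the same chain
    for ri in range(len(structure.residues) - 1):
        r1, r2 = structure.residues[ri], structure.residues[ri + 1]
        if r1.chain != r2.chain:
            continue
        ic, in_ = index.get((ri, "C")), index.get((ri + 1, "N"))
        if ic is None or in_ is None:
            continue
        c_pos = structure.residues[ri].atom("C").position
        n_pos = structure.residues[ri + 1].atom("N").position
        if np.linalg.norm(c_pos - n_pos) <= PEPTIDE_CN_MAX:
            link(ic, in_)
    return adj


def _path_weights(adj: list[list[int]], start: int) -> dict[int, int]:
    """Bonded-path distances <= 3 from ``start`` (BFS, small neighborhoods)."""
    dist = {start: 0}
    q = deque([start])
    while q:
        u = q.popleft()
        if dist[u] == 3:
            continue
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def _nb_scale(d: int | None) -> tuple[float, float]:
    """(vdW, ele) scaling by bonded-path distance; None means unconnected."""
    if d is None or d >= 4:
        return 1.0, 1.0
    if d == 3:
        return SCALE_VDW_14, SCALE_ELE_14
    return 0.0, 0.0


# ---------------------------------------------------------------------------
# extended reference


def _intra_template_energy(aa: str, params: ForceFieldParams) -> float:
    coords = extended_template(aa)
    return _intra_energy_from_coords(aa, coords, params)


def _intra_energy_from_coords(aa: str, coords: dict[str, np.ndarray], params: ForceFieldParams) -> float:
    names = [n for n in heavy_atoms(aa) if n in coords]
    adjmap: dict[str, list[str]] = {n: [] for n in names}
    for a, b in residue_bonds(aa):
        if a in adjmap and b in adjmap:
            adjmap[a].append(b)
            adjmap[b].append(a)
    # bonded-path distance by BFS on names
    def pathd(a: str, b: str) -> int | None:
        seen = {a: 0}
        q = deque([a])
        while q:
            u = q.popleft()
            if seen[u] >= 4:
                continue
            for v in adjmap[u]:
                if v not in seen:
                    seen[v] = seen[u] + 1
                    if v == b:
                        return seen[v]
                    q.append(v)
        return seen.get(b)

    total = 0.0
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            sv, se = _nb_scale(pathd(names[i], names[j]))
            if sv == 0.0 and se == 0.0:
                continue
            vdw, ele = pair_nonbonded(
                coords[names[i]], coords[names[j]],
                params.lookup(aa, names[i]), params.lookup(aa, names[j]),
            )
            total += sv * vdw + se * ele
    return total


_reference_cache: dict[tuple[str, int], float] = {}


def build_extended_reference(aa: str, params: ForceFieldParams) -> float:
    """Intra-residue nonbonded energy of the extended template (kcal/mol);
    cached per residue type and parameter set."""
    key = (aa, id(params))
    if key not in _reference_cache:
        _reference_cache[key] = _intra_template_energy(aa, params)
    return _reference_cache[key]


# ---------------------------------------------------------------------------
# main decomposition


def residue_gas_energy(
    structure: ProteinStructure,
    params: ForceFieldParams | None = None,
) -> EnergyDecomposition:
    """Per-residue gas-phase energy decomposition of a folded structure.

    Exact all-pairs sum (no distance truncation).  Inter-residue pair terms
    are half-split between the two residues; ``E_int`` is referenced to the
    extended template so a lone residue posed exactly at its template scores
    zero in every component.
    """
    if params is None:
        params = ForceFieldParams.default()
    atoms, index, incomplete = _atom_index(structure, params)
    n = len(atoms)
    adj = _bond_adjacency(structure, index, n)
    keys = [r.key for r in structure.residues]

    e_int = {k: 0.0 for k in keys}
    e_vdw = {k: 0.0 for k in keys}
    e_ele = {k: 0.0 for k in keys}

    for i in range(n):
        ri, _, pos_i, prm_i = atoms[i]
        near = _path_weights(adj, i)
        for j in range(i + 1, n):
            rj, _, pos_j, prm_j = atoms[j]
            sv, se = _nb_scale(near.get(j))
            if sv == 0.0 and se == 0.0:
                continue
            vdw, ele = pair_nonbonded(pos_i, pos_j, prm_i, prm_j)
            vdw *= sv
            ele *= se
            if ri == rj:
                e_int[keys[ri]] += vdw + ele
            else:
                e_vdw[keys[ri]] += 0.5 * vdw
                e_vdw[keys[rj]] += 0.5 * vdw
                e_ele[keys[ri]] += 0.5 * ele
                e_ele[keys[rj]] += 0.5 * ele

    for ri, res in enumerate(structure.residues):
        e_int[res.key] -= build_extended_reference(res.aa, params)

    return EnergyDecomposition(e_int=e_int, e_vdw=e_vdw, e_ele=e_ele, incomplete=incomplete)


# ---------------------------------------------------------------------------
# optional clash relief


def relax_clashes(
    structure: ProteinStructure,
    params: ForceFieldParams | None = None,
    max_steps: int = 500,
    step: float = 0.05,
    clash_factor: float = 0.7,
) -> ProteinStructure:
    """Repulsive-only steepest-descent displacement to relieve steric clashes.

    Atoms move down the gradient of the r^-12 Lennard-Jones repulsion with a
    per-atom displacement cap of ``step`` A per iteration; a step that would
    increase the number of clashing pairs (distance < ``clash_factor`` times
    the summed r_min/2) is rejected.  ``step=0`` is the identity.
    """
    if params is None:
        params = ForceFieldParams.default()
    if step == 0.0 or max_steps == 0:
        return structure
    atoms, index, _ = _atom_index(structure, params)
    coords = np.array([a[2] for a in atoms])
    rmin2 = np.array([a[3].rmin_half for a in atoms])
    eps = np.array([a[3].epsilon for a in atoms])
    adj = _bond_adjacency(structure, index, len(atoms))
    bonded = {(i, j) for i in range(len(adj)) for j in adj[i]}

    def clash_pairs(c):
        out = []
        for i in range(len(c)):
            for j in range(i + 1, len(c)):
                if (i, j) in bonded:
                    continue
                lim = clash_factor * (rmin2[i] + rmin2[j])
                if np.linalg.norm(c[i] - c[j]) < lim:
                    out.append((i, j))
        return out

    n_clash = len(clash_pairs(coords))
    cap = step
    for _ in range(max_steps):
        if n_clash == 0:
            break
        grad = np.zeros_like(coords)
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                if (i, j) in bonded:
                    continue
                d = coords[i] - coords[j]
                r = np.linalg.norm(d)
                rmin = rmin2[i] + rmin2[j]
                if r >= rmin or r <= 1e-6:
                    continue
                e = math.sqrt(eps[i] * eps[j])
                mag = 12.0 * e * (rmin / r) ** 12 / r  # -d/dr of repulsive term
                grad[i] += mag * d / r
                grad[j] -= mag * d / r
        norms = np.linalg.norm(grad, axis=1, keepdims=True)
        scale = np.where(norms > 0, np.minimum(1.0, cap / np.maximum(norms, 1e-12)), 0.0)
        trial = coords + grad * scale
        trial_clashes = len(clash_pairs(trial))
        if trial_clashes <= n_clash:
            coords, n_clash = trial, trial_clashes
        else:
            cap *= 0.5
            if cap < 1e-4:
                break

    # rebuild structure with displaced heavy atoms
    new_res = []
    for ri, res in enumerate(structure.residues):
        new_atoms = []
        for a in res.atoms:
            k = index.get((ri, a.name))
            if k is None:
                new_atoms.append(a)
            else:
                new_atoms.append(AtomRecord(a.serial, a.name, a.element, coords[k],
                                            a.occupancy, a.altloc))
        new_res.append(Residue(res.chain, res.number, res.icode, res.aa, new_atoms))
    return ProteinStructure(id=structure.id, residues=new_res)


# ---------------------------------------------------------------------------
# TSV adapters


def write_energy_table(decomp: EnergyDecomposition) -> str:
    lines = ["chain\tnumber\ticode\te_int\te_vdw\te_ele\te_gas"]
    for k in decomp.e_int:
        ch, num, ic = k
        g = decomp.e_int[k] + decomp.e_vdw[k] + decomp.e_ele[k]
        lines.append(f"{ch}\t{num}\t{ic}\t{decomp.e_int[k]:.6f}\t{decomp.e_vdw[k]:.6f}"
                     f"\t{decomp.e_ele[k]:.6f}\t{g:.6f}")
    return "\n".join(lines) + "\n"


def read_energy_table(text: str) -> EnergyDecomposition:
    """Adapter for externally computed per-residue energies (same schema)."""
    e_int, e_vdw, e_ele = {}, {}, {}
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    if header[:3] != ["chain", "number", "icode"]:
        raise ValueError("unrecognized energy table header")
    for ln in lines[1:]:
        parts = ln.split("\t")
        key = (parts[0], int(parts[1]), parts[2])
        e_int[key] = float(parts[3])
        e_vdw[key] = float(parts[4])
        e_ele[key] = float(parts[5])
    return EnergyDecomposition(e_int=e_int, e_vdw=e_vdw, e_ele=e_ele)
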