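"""Parsing of PDB structures into a light per-residue/per-atom model.

The package works on a single selected chain of an unbound (free) protein
structure, or on a two-sided complex used for interface operations.  Parsing
and writing of the PDB format itself is delegated to :mod:`gemmi`; this module
owns chain selection, altloc collapsing, MODEL-1 selection and the mapping of
common modified residues onto their canonical parents.

Residues are keyed by ``(chain, number, icode)`` using PDB numbering, which is
preserved in everything user-facing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

AA3_TO_1 = dict(
    zip(AA3, "A R N D C Q E G H I L K M F P S T W Y V".split())
)

#: Modified / alternate residue names mapped onto canonical parents.
NONCANONICAL_MAP = {
    "MSE": "MET",  # selenomethionine
    "SEP": "SER",  # phosphoserine
    "TPO": "THR",  # phosphothreonine
    "PTR": "TYR",  # phosphotyrosine
    "MLY": "LYS",  # N-dimethyllysine
    "KCX": "LYS",  # carboxylysine
    "CSO": "CYS",  # S-hydroxycysteine
    "CME": "CYS",  # S,S-(2-hydroxyethyl)thiocysteine
    "OCS": "CYS",  # cysteine sulfonic acid
    "HYP": "PRO",  # hydroxyproline
    "HID": "HIS",
    "HIE": "HIS",
    "HIP": "HIS",
    "CYX": "CYS",
    "ASH": "ASP",
    "GLH": "GLU",
    "LYN": "LYS",
}


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM record after altloc collapsing."""

    serial: int
    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain: str
    number: int
    icode: str
    aa: str  # canonical three-letter code
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.aa not in AA3:
            raise ValueError(f"non-canonical residue code {self.aa!r}")
        if not self.atoms:
            raise ValueError(f"residue {self.key} has no atoms")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode)

    @property
    def aa1(self) -> str:
        return AA3_TO_1[self.aa]

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        sel = [a.position for a in self.atoms if not (heavy_only and a.element == "H")]
        return np.array(sel, dtype=float).reshape(-1, 3)


@dataclass
class ProteinStructure:
    """An ordered single-chain (or merged multi-chain) list of residues."""

    id: str
    residues: list[Residue]

    def __post_init__(self):
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue keys")
        self.residues = sorted(self.residues, key=lambda r: (r.chain, r.number, r.icode))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def keys(self) -> list[tuple[str, int, str]]:
        return [r.key for r in self.residues]

    @property
    def sequence(self) -> str:
        return "".join(r.aa1 for r in self.residues)

    def get(self, key: tuple[str, int, str]) -> Residue | None:
        for r in self.residues:
            if r.key == key:
                return r
        return None


@dataclass
class ComplexStructure:
    """Two chain groups of one structure, A (target) and B (partner)."""

    part_a: ProteinStructure
    part_b: ProteinStructure
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        chains_a = {r.chain for r in self.part_a.residues}
        chains_b = {r.chain for r in self.part_b.residues}
        if chains_a & chains_b:
            raise ValueError(f"chain groups overlap: {sorted(chains_a & chains_b)}")


@dataclass
class ProbeCluster:
    """A cluster of small-molecule probe atoms (e.g. one docking cluster)."""

    id: int
    coords: np.ndarray  # (n, 3)
    elements: list[str]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.coords) == 0:
            raise ValueError(f"probe cluster {self.id} has no atoms")

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


# ---------------------------------------------------------------------------
# parsing


def _collapse_altlocs(atoms: list[tuple[str, AtomRecord]]) -> list[AtomRecord]:
    """Keep, per atom name, the altloc with highest occupancy (tie: first in
    the alphabet)."""
    by_name: dict[str, list[AtomRecord]] = {}
    order: list[str] = []
    for name, rec in atoms:
        if name not in by_name:
            by_name[name] = []
            order.append(name)
        by_name[name].append(rec)
    out = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.altloc))
        out.append(best)
    return out


def _convert_residue(res: gemmi.Residue, chain_name: str, include_het: bool) -> Residue | None:
    name = res.name.strip().upper()
    aa = name if name in AA3 else NONCANONICAL_MAP.get(name)
    if aa is None:
        if res.het_flag == "A" or name in ("HOH", "WAT") or not include_het:
            if name not in ("HOH", "WAT"):
                logger.warning("skipping non-canonical residue %s %s%d", name, chain_name, res.seqid.num)
        return None
    raw = []
    for atom in res:
        rec = AtomRecord(
            serial=atom.serial,
            name=atom.name,
            element=atom.element.name,
            position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
            occupancy=min(max(float(atom.occ), 0.0), 1.0),
            altloc=atom.altloc.strip(),
        )
        raw.append((atom.name, rec))
    collapsed = _collapse_altlocs(raw)
    if not collapsed:
        return None
    icode = res.seqid.icode.strip()
    return Residue(chain=chain_name, number=res.seqid.num, icode=icode, aa=aa, atoms=collapsed)


def _read_model(pdb_text: str) -> gemmi.Model:
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("empty structure: no models in input")
    return st[0]  # multi-model entries: first model only


def parse_structure(pdb_text: str, chain: str, include_het: bool = False) -> ProteinStructure:
    """Parse one chain of a PDB file into a :class:`ProteinStructure`.

    Altlocs are collapsed to the highest-occupancy location, modified residues
    are mapped to canonical parents where known, and waters/ligands are
    dropped.  Raises ``ValueError`` if the chain is absent or holds no
    canonical residues.
    """
    model = _read_model(pdb_text)
    names = [ch.name for ch in model]
    if chain not in names:
        raise ValueError(f"chain not found: {chain!r} (have {names})")
    residues = []
    for ch in model:
        if ch.name != chain:
            continue
        for res in ch:
            conv = _convert_residue(res, ch.name, include_het)
            if conv is not None:
                residues.append(conv)
    if not residues:
        raise ValueError(f"empty structure: chain {chain!r} has no canonical residues")
    return ProteinStructure(id=f"{(st_name(pdb_text) or 'structure')}_{chain}", residues=residues)


def st_name(pdb_text: str) -> str:
    for line in pdb_text.splitlines():
        if line.startswith("HEADER") and len(line) >= 66:
            code = line[62:66].strip()
            if code:
                return code.lower()
    return ""


def parse_complex(pdb_text: str, chains_a: set[str], chains_b: set[str]) -> ComplexStructure:
    """Split a multi-chain PDB into target (A) and partner (B) chain groups."""
    chains_a, chains_b = set(chains_a), set(chains_b)
    if chains_a & chains_b:
        raise ValueError(f"chain groups overlap: {sorted(chains_a & chains_b)}")
    model = _read_model(pdb_text)
    present = {ch.name for ch in model}
    for label, group in (("A", chains_a), ("B", chains_b)):
        missing = group - present
        if missing:
            raise ValueError(f"side {label}: chains missing from file: {sorted(missing)}")

    def collect(group: set[str], tag: str) -> ProteinStructure:
        residues = []
        for ch in model:
            if ch.name not in group:
                continue
            for res in ch:
                conv = _convert_residue(res, ch.name, include_het=False)
                if conv is not None:
                    residues.append(conv)
        if not residues:
            raise ValueError(f"side {tag}: no canonical residues")
        return ProteinStructure(id=tag, residues=residues)

    return ComplexStructure(part_a=collect(chains_a, "A"), part_b=collect(chains_b, "B"))


def parse_probe_clusters(pdb_text: str, cluster_map: dict[int, int] | None = None) -> list[ProbeCluster]:
    """Parse probe atoms grouped into clusters.

    Grouping dialects: MODEL blocks (one cluster per MODEL), or a sidecar
    mapping ``atom serial -> cluster id``; a single un-grouped probe set is
    one cluster.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("empty probe file")
    groups: dict[int, tuple[list[np.ndarray], list[str]]] = {}
    for midx, model in enumerate(st):
        for ch in model:
            for res in ch:
                for atom in res:
                    if atom.element.name == "H":
                        continue
                    if cluster_map is not None:
                        cid = cluster_map.get(atom.serial)
                        if cid is None:
                            continue
                    else:
                        cid = midx
                    coords, elems = groups.setdefault(cid, ([], []))
                    coords.append(np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
                    elems.append(atom.element.name)
    clusters = [
        ProbeCluster(id=cid, coords=np.array(coords), elements=elems)
        for cid, (coords, elems) in sorted(groups.items())
    ]
    if not clusters:
        raise ValueError("empty probe file: no probe atoms found")
    return clusters


# ---------------------------------------------------------------------------
# writing


def write_pdb(structure: ProteinStructure) -> str:
    """Serialize a structure back to PDB text (fixed-width, 3 decimals)."""
    lines = []
    serial = 0
    last_chain = None
    for res in structure.residues:
        if last_chain is not None and res.chain != last_chain:
            lines.append("TER")
        last_chain = res.chain
        for a in res.atoms:
            serial += 1
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            x, y, z = a.position
            if any(abs(v) >= 10000 or math.isnan(v) for v in (x, y, z)):
                raise ValueError("coordinates out of PDB fixed-width range")
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{'':1s}{res.aa:<3s} {res.chain:1s}"
                f"{res.number:4d}{res.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
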