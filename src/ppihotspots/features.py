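"""Feature-table assembly and synthetic test-data generation.

The classifier consumes four per-residue features: the conservation grade
``k_C`` (1..9, 9 = most conserved), the amino-acid type, the solvent-
accessible surface area ``sasa`` (A^2) and the gas-phase energy ``e_gas``
(kcal/mol).  :func:`assemble_features` inner-joins the three computed sources
on the residue key; the synthetic generators produce idealized structures,
alignments with controlled column variability, and labeled feature tables
whose hot-spot probability follows a documented logistic model -- they exist
so that every downstream stage can be exercised and recovered end-to-end
without external data.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conservation import ConservationProfile, MultipleAlignment
from .energetics import EnergyDecomposition
from .geometry import SasaResult
from .residues import nerf_place
from .structure import AA3_TO_1, ProteinStructure

logger = logging.getLogger(__name__)

AA1 = "ACDEFGHIKLMNPQRSTVWY"
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

FEATURE_COLUMNS = ["protein", "chain", "number", "icode", "aa", "k_C", "sasa", "e_gas"]
CORE_FEATURES = ["k_C", "aa", "sasa", "e_gas"]


# ---------------------------------------------------------------------------
# assembly


def assemble_features(
    structure: ProteinStructure,
    profile: ConservationProfile,
    sasa: SasaResult,
    energies: EnergyDecomposition,
    protein_id: str | None = None,
) -> pd.DataFrame:
    """One row per residue covered by all three feature sources.

    The conservation profile is indexed by position along the chain; SASA and
    energies are keyed by residue.  Residues flagged as incomplete by the
    energy decomposition, or missing from any source, are dropped with a
    warning.  An empty intersection is an error.
    """
    if len(profile.grade) != len(structure.residues):
        raise ValueError(
            f"conservation profile length {len(profile.grade)} != "
            f"{len(structure.residues)} residues"
        )
    pid = protein_id or structure.id
    rows, dropped = [], []
    for pos, res in enumerate(structure.residues):
        key = res.key
        if key not in sasa.per_residue or key not in energies.e_int or key in energies.incomplete:
            dropped.append(key)
            continue
        e_gas = energies.e_int[key] + energies.e_vdw[key] + energies.e_ele[key]
        rows.append(
            {
                "protein": pid,
                "chain": res.chain,
                "number": res.number,
                "icode": res.icode,
                "aa": res.aa1,
                "k_C": int(profile.grade[pos]),
                "sasa": float(sasa.per_residue[key]),
                "e_gas": float(e_gas),
            }
        )
    if dropped:
        logger.warning("dropped %d residues missing a feature source: %s", len(dropped), dropped)
    if not rows:
        raise ValueError("no residue is covered by all feature sources")
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return df.sort_values(["protein", "chain", "number", "icode"]).reset_index(drop=True)


def write_feature_table(df: pd.DataFrame) -> str:
    return df.to_csv(sep="\t", index=False)


def read_feature_table(text: str) -> pd.DataFrame:
    df = pd.read_csv(io.StringIO(text), sep="\t", keep_default_na=False,
                     dtype={"icode": str, "chain": str})
    return df


# ---------------------------------------------------------------------------
# synthetic structures


_GEOMETRY = {
    # (phi, psi) backbone dihedrals, degrees
    "helix": (-57.0, -47.0),
    "strand": (-135.0, 135.0),
}


def make_synthetic_structure(
    sequence: str,
    geometry: str = "strand",
    seed: int = 0,
    chain: str = "A",
    jitter: float = 0.01,
) -> str:
    """PDB text for an idealized backbone (N, CA, C, O + CB) of ``sequence``.

    Backbone dihedrals are the canonical helix or strand values; a small
    seeded Gaussian jitter (sd ``jitter`` A) breaks exact degeneracies while
    keeping the construction deterministic per seed.
    """
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("empty sequence")
    for c in sequence:
        if c not in AA1_TO_3:
            raise ValueError(f"non-canonical residue letter {c!r}")
    if geometry not in _GEOMETRY:
        raise ValueError(f"geometry must be one of {sorted(_GEOMETRY)}")
    phi, psi = _GEOMETRY[geometry]
    rng = np.random.default_rng(seed)

    n_ca, ca_c, c_n = 1.458, 1.525, 1.329
    ang_ncac, ang_cacn, ang_cnca = 111.2, 116.2, 121.7
    omega = 180.0

    coords: list[dict[str, np.ndarray]] = []
    # first residue backbone in a fixed frame
    first = {
        "N": np.array([0.0, 0.0, 0.0]),
        "CA": np.array([n_ca, 0.0, 0.0]),
    }
    a = math.radians(180.0 - ang_ncac)
    first["C"] = first["CA"] + ca_c * np.array([math.cos(a), math.sin(a), 0.0])
    coords.append(first)
    for i in range(1, len(sequence)):
        prev = coords[-1]
        cur: dict[str, np.ndarray] = {}
        cur["N"] = nerf_place(prev["C"], prev["CA"], prev["N"], c_n, ang_cacn, psi)
        cur["CA"] = nerf_place(cur["N"], prev["C"], prev["CA"], n_ca, ang_cnca, omega)
        cur["C"] = nerf_place(cur["CA"], cur["N"], prev["C"], ca_c, ang_ncac, phi)
        coords.append(cur)
    # carbonyl O and CB placed off the completed backbone
    for i, cur in enumerate(coords):
        nxt_n = coords[i + 1]["N"] if i + 1 < len(coords) else None
        if nxt_n is not None:
            # O roughly anti to the next amide nitrogen
            cur["O"] = nerf_place(cur["C"], cur["CA"], nxt_n, 1.231, 120.5, 180.0)
        else:
            cur["O"] = nerf_place(cur["C"], cur["CA"], cur["N"], 1.231, 120.5, -45.0)
        if sequence[i] != "G":
            cur["CB"] = nerf_place(cur["CA"], cur["C"], cur["N"], 1.53, 110.5, 122.6)

    lines = []
    serial = 0
    for i, cur in enumerate(coords):
        aa3 = AA1_TO_3[sequence[i]]
        for name in ("N", "CA", "C", "O", "CB"):
            if name not in cur:
                continue
            serial += 1
            pos = cur[name] + rng.normal(0.0, jitter, size=3)
            elem = name[0]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {aa3:<3s} {chain}{i + 1:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {elem:>2s}"
            )
    lines += ["TER", "END"]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# synthetic alignments


def make_synthetic_msa(
    target: str,
    n_rows: int,
    column_variability: float | np.ndarray = 0.2,
    seed: int = 0,
) -> MultipleAlignment:
    """Rows drawn i.i.d. per column: with probability ``column_variability[p]``
    the target letter at position ``p`` is substituted by one of the other 19
    amino acids (uniformly); otherwise it is copied."""
    target = target.upper()
    p = np.broadcast_to(np.asarray(column_variability, dtype=float), (len(target),))
    if ((p < 0) | (p > 1)).any():
        raise ValueError("column variabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_rows):
        chars = []
        for pos, c in enumerate(target):
            if rng.random() < p[pos]:
                alt = AA1.replace(c, "")
                chars.append(alt[rng.integers(len(alt))])
            else:
                chars.append(c)
        rows.append("".join(chars))
    return MultipleAlignment(target=target, rows=rows,
                             ids=[f"synth{r}" for r in range(n_rows)])


# ---------------------------------------------------------------------------
# synthetic labeled datasets


@dataclass
class SyntheticSpec:
    """Conditions for the synthetic labeled-residue generator.

    The logistic model is
    ``logit P(hotspot) = b0 + b1*z(k_C) + b2*z(sasa) + b3*z(e_gas)
    + aa_offset[aa] + noise`` with features standardized by their theoretical
    moments.  The defaults emulate the real benchmark's shape: ~45% hot-spot
    prevalence in the labeled table, conservation as the strongest signal,
    then amino-acid type (aromatic/charged enrichment), SASA and gas-phase
    energy.
    """

    n_proteins: int = 60
    residues_per_protein: int = 40
    beta0: float = -0.2
    beta_kc: float = 1.0
    beta_sasa: float = 0.6
    beta_egas: float = 0.4
    aa_offsets: dict[str, float] = field(
        default_factory=lambda: {"W": 0.8, "Y": 0.6, "R": 0.5}
    )
    noise_sd: float = 0.5
    seed: int = 0


# theoretical moments of the feature marginals used for standardization
_KC_MEAN, _KC_SD = 5.0, math.sqrt(80.0 / 12.0)  # uniform on 1..9
_SASA_SHAPE, _SASA_SCALE = 2.0, 40.0  # gamma; truncated at 300 A^2
_SASA_MEAN, _SASA_SD = 80.0, math.sqrt(2.0) * 40.0
_EGAS_MEAN, _EGAS_SD = 0.0, 5.0


def make_labeled_dataset(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.Series]:
    """(feature table, binary labels) drawn from the documented model."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins * spec.residues_per_protein
    k_c = rng.integers(1, 10, size=n)
    sasa = np.minimum(rng.gamma(_SASA_SHAPE, _SASA_SCALE, size=n), 300.0)
    e_gas = rng.normal(_EGAS_MEAN, _EGAS_SD, size=n)
    aa = rng.choice(list(AA1), size=n)

    z_kc = (k_c - _KC_MEAN) / _KC_SD
    z_sasa = (sasa - _SASA_MEAN) / _SASA_SD
    z_egas = (e_gas - _EGAS_MEAN) / _EGAS_SD
    offsets = np.array([spec.aa_offsets.get(a, 0.0) for a in aa])
    logit = (
        spec.beta0
        + spec.beta_kc * z_kc
        + spec.beta_sasa * z_sasa
        + spec.beta_egas * z_egas
        + offsets
        + rng.normal(0.0, spec.noise_sd, size=n)
    )
    prob = 1.0 / (1.0 + np.exp(-logit))
    labels = (rng.random(n) < prob).astype(int)

    proteins = np.repeat([f"P{i:03d}" for i in range(spec.n_proteins)],
                         spec.residues_per_protein)
    numbers = np.tile(np.arange(1, spec.residues_per_protein + 1), spec.n_proteins)
    df = pd.DataFrame(
        {
            "protein": proteins,
            "chain": "A",
            "number": numbers,
            "icode": "",
            "aa": aa,
            "k_C": k_c,
            "sasa": sasa,
            "e_gas": e_gas,
        },
        columns=FEATURE_COLUMNS,
    )
    return df, pd.Series(labels, name="label")


def split_by_protein(
    table: pd.DataFrame,
    labels: pd.Series,
    holdout_ids: list[str],
) -> tuple[tuple[pd.DataFrame, pd.Series], tuple[pd.DataFrame, pd.Series]]:
    """Protein-level holdout split; no protein appears on both sides."""
    known = set(table["protein"])
    unknown = set(holdout_ids) - known
    if unknown:
        raise ValueError(f"unknown protein ids: {sorted(unknown)}")
    mask = table["protein"].isin(set(holdout_ids)).to_numpy()
    train = (table[~mask].reset_index(drop=True), labels[~mask].reset_index(drop=True))
    test = (table[mask].reset_index(drop=True), labels[mask].reset_index(drop=True))
    return train, test


def write_labels(table: pd.DataFrame, labels: pd.Series) -> str:
    out = table[["protein", "chain", "number", "icode"]].copy()
    out["label"] = np.where(np.asarray(labels) == 1, "hotspot", "nonhotspot")
    return out.to_csv(sep="\t", index=False)


def read_labels(text: str) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(io.StringIO(text), sep="\t", keep_default_na=False,
                     dtype={"icode": str, "chain": str})
    labels = (df.pop("label") == "hotspot").astype(int)
    return df, labels
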