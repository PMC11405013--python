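"""Per-residue evolutionary conservation grades from homolog hit sets.

The pipeline mirrors the standard practice for conservation scoring from a
sequence search: near-duplicate removal, coverage/identity filtering, a cap on
the number of hits, target-anchored alignment, position-specific rate
estimation, and discretization into nine conservation grades (9 = most
conserved, 1 = most variable).

The rate estimator is pluggable.  The built-in default is a sequence-weighted
column heterogeneity (Henikoff position-based weights, weighted Shannon
entropy over the 20 amino-acid letters, gaps excluded); externally computed
per-position rates (e.g. from an empirical-Bayes phylogenetic program) can be
substituted through :func:`read_rate_file`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class HomologHit:
    id: str
    sequence: str
    target_interval: tuple[int, int]  # half-open on target, 0-based
    identity: float  # fraction vs. target over the aligned region
    score: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"hit {self.id}: identity {self.identity} outside [0, 1]")
        s, e = self.target_interval
        if s < 0 or e < s:
            raise ValueError(f"hit {self.id}: bad target interval {self.target_interval}")

    @property
    def aligned_length(self) -> int:
        return self.target_interval[1] - self.target_interval[0]


@dataclass
class MultipleAlignment:
    """Target-anchored alignment: every row has exactly one column per target
    position (insertions relative to the target are dropped)."""

    target: str
    rows: list[str]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        for row in self.rows:
            if len(row) != len(self.target):
                raise ValueError("alignment rows must match target length")
        if not self.ids:
            self.ids = [f"row{i}" for i in range(len(self.rows))]

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class ConservationProfile:
    rate: np.ndarray
    zscore: np.ndarray
    grade: np.ndarray  # int, 1..9

    def __post_init__(self):
        self.rate = np.asarray(self.rate, dtype=float)
        self.zscore = np.asarray(self.zscore, dtype=float)
        self.grade = np.asarray(self.grade, dtype=int)
        if not ((self.grade >= 1) & (self.grade <= 9)).all():
            raise ValueError("grades must lie in 1..9")


# ---------------------------------------------------------------------------
# pairwise alignment helpers (Biopython)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.mode = "global"
    return al


def _align_pair(seq_a: str, seq_b: str):
    """Best global alignment of two sequences; returns aligned index blocks."""
    al = _aligner()
    aln = al.align(seq_a.upper(), seq_b.upper())[0]
    return aln.aligned  # pair of block arrays


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical positions over aligned (non-gap) columns."""
    blocks_a, blocks_b = _align_pair(seq_a, seq_b)
    matches = aligned = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for i in range(a1 - a0):
            aligned += 1
            if seq_a[a0 + i].upper() == seq_b[b0 + i].upper():
                matches += 1
    return matches / aligned if aligned else 0.0


def hits_from_fasta(target: str, fasta_text: str) -> list[HomologHit]:
    """Build hit records from raw FASTA sequences by aligning each to the
    target (interval = aligned span on target, identity over aligned region)."""
    hits = []
    for hid, seq in _iter_fasta(fasta_text):
        blocks_t, blocks_h = _align_pair(target, seq)
        if len(blocks_t) == 0:
            continue
        start, end = int(blocks_t[0][0]), int(blocks_t[-1][1])
        matches = aligned = 0
        for (a0, a1), (b0, b1) in zip(blocks_t, blocks_h):
            for i in range(a1 - a0):
                aligned += 1
                if target[a0 + i].upper() == seq[b0 + i].upper():
                    matches += 1
        ident = matches / aligned if aligned else 0.0
        hits.append(HomologHit(id=hid, sequence=seq, target_interval=(start, end), identity=ident))
    return hits


def _iter_fasta(text: str):
    hid, chunks = None, []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if hid is not None:
                yield hid, "".join(chunks)
            hid, chunks = line[1:].split()[0], []
        else:
            chunks.append(line)
    if hid is not None:
        yield hid, "".join(chunks)


# ---------------------------------------------------------------------------
# hit filtering


def dedup_hits(hits: list[HomologHit], threshold: float = 0.95) -> list[HomologHit]:
    """Greedy near-duplicate clustering in input order; the first member of
    each cluster (pairwise identity >= ``threshold``) is kept."""
    reps: list[HomologHit] = []
    for hit in hits:
        if any(pairwise_identity(hit.sequence, rep.sequence) >= threshold for rep in reps):
            continue
        reps.append(hit)
    return reps


def filter_hits(
    hits: list[HomologHit],
    target: str,
    max_hits: int = 300,
    min_overlap: float = 0.60,
    min_identity: float = 0.35,
    max_identity: float = 0.95,
    pair_overlap: float = 0.10,
    apply_pair_overlap: bool = True,
) -> list[HomologHit]:
    """Coverage/identity filtering of homolog hits.

    In order: (a) drop hits covering <= ``min_overlap`` of the target length;
    (b) drop hits with identity <= ``min_identity`` (too dissimilar) or
    >= ``max_identity`` (near-identical); (c) among survivors, if two hits'
    target intervals overlap by more than ``pair_overlap`` of the target
    length, drop the shorter hit (this ambiguous step can be disabled);
    (d) cap at ``max_hits`` ranked by score, then identity, then input order.

    Raises ``ValueError`` when nothing survives, so callers can fall back to
    a prebuilt alignment.
    """
    n = len(target)
    surv = [h for h in hits if h.aligned_length > min_overlap * n]
    surv = [h for h in surv if min_identity < h.identity < max_identity]
    if apply_pair_overlap:
        rejected: set[int] = set()
        for i in range(len(surv)):
            if i in rejected:
                continue
            for j in range(i + 1, len(surv)):
                if j in rejected:
                    continue
                a, b = surv[i], surv[j]
                ov = min(a.target_interval[1], b.target_interval[1]) - max(
                    a.target_interval[0], b.target_interval[0]
                )
                if ov > pair_overlap * n:
                    # drop the shorter; tie -> the later hit
                    if a.aligned_length < b.aligned_length:
                        rejected.add(i)
                        break
                    rejected.add(j)
        surv = [h for k, h in enumerate(surv) if k not in rejected]
    if not surv:
        raise ValueError("no usable homologs after filtering")
    if len(surv) > max_hits:
        order = sorted(
            range(len(surv)),
            key=lambda k: (-(surv[k].score if surv[k].score is not None else -np.inf),
                           -surv[k].identity, k),
        )
        keep = set(order[:max_hits])
        surv = [h for k, h in enumerate(surv) if k in keep]
    return surv


# ---------------------------------------------------------------------------
# alignment to target


def align_to_target(hits: list[HomologHit], target: str) -> MultipleAlignment:
    """Stack each hit's pairwise global alignment onto target columns."""
    if not hits:
        raise ValueError("need at least one hit")
    rows, ids = [], []
    for hit in hits:
        blocks_t, blocks_h = _align_pair(target, hit.sequence)
        row = ["-"] * len(target)
        for (a0, a1), (b0, b1) in zip(blocks_t, blocks_h):
            for i in range(a1 - a0):
                row[a0 + i] = hit.sequence[b0 + i].upper()
        rows.append("".join(row))
        ids.append(hit.id)
    return MultipleAlignment(target=target.upper(), rows=rows, ids=ids)


def read_a3m(text: str, target: str | None = None) -> MultipleAlignment:
    """Read an A3M/FASTA alignment; lowercase letters (insertions relative to
    the master sequence) are dropped so columns index target positions."""
    entries = list(_iter_fasta_keepcase(text))
    if not entries:
        raise ValueError("empty alignment")
    rows = []
    ids = []
    for hid, seq in entries:
        rows.append("".join(c for c in seq if not c.islower()).replace(".", "-"))
        ids.append(hid)
    master = rows[0].replace("-", "")
    tgt = target.upper() if target is not None else master
    if len(rows[0]) != len(tgt):
        # master row may carry gap columns; project all rows onto master positions
        keep = [i for i, c in enumerate(rows[0]) if c != "-"]
        rows = ["".join(r[i] for i in keep) for r in rows]
    if len(rows[0]) != len(tgt):
        raise ValueError("alignment does not match target length")
    return MultipleAlignment(target=tgt, rows=rows[1:] if target is None else rows, ids=ids)


def _iter_fasta_keepcase(text: str):
    hid, chunks = None, []
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith(">"):
            if hid is not None:
                yield hid, "".join(chunks)
            hid, chunks = line[1:].split()[0], []
        else:
            chunks.append(line.strip())
    if hid is not None:
        yield hid, "".join(chunks)


# ---------------------------------------------------------------------------
# rate estimation and grading


def _position_weights(rows: list[str]) -> np.ndarray:
    """Henikoff & Henikoff position-based sequence weights (gap = own type)."""
    n_rows = len(rows)
    n_cols = len(rows[0])
    w = np.zeros(n_rows)
    for c in range(n_cols):
        col = [r[c] for r in rows]
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        k = len(counts)
        for i, ch in enumerate(col):
            w[i] += 1.0 / (k * counts[ch])
    total = w.sum()
    return w / total if total > 0 else np.full(n_rows, 1.0 / n_rows)


def estimate_column_rates(msa: MultipleAlignment, include_target: bool = True) -> np.ndarray:
    """Weighted Shannon entropy per target column (gaps excluded); higher
    means more variable.  All-gap columns get the maximum observed rate."""
    rows = ([msa.target] if include_target else []) + list(msa.rows)
    if len(rows) < 2:
        raise ValueError("need at least 2 rows to estimate rates")
    weights = _position_weights(rows)
    n_cols = len(msa.target)
    rates = np.zeros(n_cols)
    undefined = []
    for c in range(n_cols):
        mass: dict[str, float] = {}
        for i, r in enumerate(rows):
            ch = r[c]
            if ch in ("-", ".", "X"):
                continue
            mass[ch] = mass.get(ch, 0.0) + weights[i]
        tot = sum(mass.values())
        if tot <= 0:
            undefined.append(c)
            rates[c] = np.nan
            continue
        p = np.array(list(mass.values())) / tot
        rates[c] = float(-(p * np.log(p)).sum())
    if undefined:
        fill = np.nanmax(rates) if np.isfinite(np.nanmax(rates)) else 0.0
        logger.warning("all-gap columns %s assigned max rate %.3f", undefined, fill)
        rates[undefined] = fill
    return rates


#: z-score bin edges: nine equal-width bins spanning [-2.25, 2.25], clamped.
GRADE_SPAN = 2.25
N_GRADES = 9


def grade_from_z(z: np.ndarray) -> np.ndarray:
    """Map normalized rates to grades: nine equal-width bins on
    [-GRADE_SPAN, GRADE_SPAN] with clamping; low z (conserved) -> grade 9."""
    width = 2 * GRADE_SPAN / N_GRADES
    idx = np.clip(np.floor((np.asarray(z, float) + GRADE_SPAN) / width), 0, N_GRADES - 1)
    return (N_GRADES - idx).astype(int)


def grade_rates(rates: np.ndarray) -> ConservationProfile:
    """Normalize rates to z-scores and discretize into grades 1..9.

    Low rate (conserved) maps to grade 9, high rate (variable) to grade 1;
    a zero-variance profile degenerates to grade 5 everywhere.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0 or not np.all(np.isfinite(rates)):
        raise ValueError("rates must be non-empty and finite")
    sd = rates.std()
    if sd <= 1e-12 * max(1.0, float(np.abs(rates).max())):
        z = np.zeros_like(rates)
        grade = np.full(rates.shape, 5, dtype=int)
        return ConservationProfile(rate=rates, zscore=z, grade=grade)
    z = (rates - rates.mean()) / sd
    return ConservationProfile(rate=rates, zscore=z, grade=grade_from_z(z))


def conservation_profile(
    target: str,
    hits: list[HomologHit],
    max_hits: int = 300,
    prebuilt_msa: MultipleAlignment | None = None,
    external_rates: np.ndarray | None = None,
) -> ConservationProfile:
    """Full pipeline: dedup -> filter -> align -> rates -> grades.

    A prebuilt alignment or externally computed rates short-circuit the
    corresponding stages.
    """
    if external_rates is not None:
        return grade_rates(np.asarray(external_rates, dtype=float))
    if prebuilt_msa is None:
        kept = dedup_hits(hits)
        kept = filter_hits(kept, target, max_hits=max_hits)
        prebuilt_msa = align_to_target(kept, target)
    rates = estimate_column_rates(prebuilt_msa)
    return grade_rates(rates)


# ---------------------------------------------------------------------------
# file adapters


def read_rate_file(text: str) -> np.ndarray:
    """TSV adapter (position<TAB>rate, 0-based positions, '#' comments) for
    externally computed per-position rates."""
    pairs = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pos, rate = line.split("\t")[:2]
        pairs.append((int(pos), float(rate)))
    if not pairs:
        raise ValueError("empty rate file")
    pairs.sort()
    positions = [p for p, _ in pairs]
    if positions != list(range(len(positions))):
        raise ValueError("rate file must cover positions 0..n-1 exactly once")
    return np.array([r for _, r in pairs])


def write_profile(profile: ConservationProfile) -> str:
    lines = ["position\trate\tzscore\tgrade"]
    for i in range(len(profile.rate)):
        lines.append(f"{i}\t{profile.rate[i]:.6f}\t{profile.zscore[i]:.6f}\t{profile.grade[i]}")
    return "\n".join(lines) + "\n"
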