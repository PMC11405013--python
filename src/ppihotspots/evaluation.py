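"""Confusion counts, benchmark metrics, and geometric hot-spot callers.

The metric arithmetic is the standard binary-classification quartet reported
for hot-spot benchmarks:

    sensitivity = TP / (TP + FN)        (recall over true hot spots)
    precision   = TP / (TP + FP)
    F1          = 2 * sens * prec / (sens + prec) = 2TP / (2TP + FP + FN)
    specificity = TN / (TN + FP)        (recall over true non-hot spots)

Also housed here: the probe-consensus caller (residues in vdW contact with
probe molecules of the largest consensus site), the predicted-interface
caller (interface residues of a modeled complex called as hot spots), the
union combination of two prediction sets, and Venn overlap reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .geometry import interface_residues, vdw_radius
from .structure import ComplexStructure, ProbeCluster, ProteinStructure

ResidueKey = tuple[str, int, str]


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is zero (e.g. no predicted
    positives for precision)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_hotspots(self) -> int:
        return self.tp + self.fn

    @property
    def n_nonhotspots(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    precision: float
    f1: float
    specificity: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Display rounding, half-up (so 0.675 prints as 0.68)."""
        q = Decimal(10) ** -ndigits
        return {
            name: float(Decimal(repr(getattr(self, name))).quantize(q, rounding=ROUND_HALF_UP))
            for name in ("sensitivity", "precision", "f1", "specificity")
        }


def confusion(predicted: set[ResidueKey], truth: dict[ResidueKey, int]) -> ConfusionCounts:
    """Tally predictions against binary truth labels (1 = hot spot).

    Counted over labeled keys only; predictions outside the labeled universe
    are an error (they are neither verifiable positives nor negatives).
    """
    stray = set(predicted) - set(truth)
    if stray:
        raise ValueError(f"predicted keys outside the labeled universe: {sorted(stray)}")
    tp = fp = tn = fn = 0
    for key, label in truth.items():
        called = key in predicted
        if label and called:
            tp += 1
        elif label:
            fn += 1
        elif called:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(counts: ConfusionCounts, undefined_as_zero: bool = False) -> MetricsReport:
    """Sensitivity/precision/F1/specificity from confusion counts.

    A zero denominator raises :class:`UndefinedMetricError` unless
    ``undefined_as_zero`` coerces the undefined value to 0 with a warning
    (needed for degenerate cross-validation folds).
    """

    def ratio(num: int, den: int, what: str) -> float:
        if den == 0:
            if undefined_as_zero:
                warnings.warn(f"{what} undefined (zero denominator); coerced to 0")
                return 0.0
            raise UndefinedMetricError(f"{what} undefined: zero denominator")
        return num / den

    sens = ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    prec = ratio(counts.tp, counts.tp + counts.fp, "precision")
    spec = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    denom = 2 * counts.tp + counts.fp + counts.fn
    f1 = ratio(2 * counts.tp, denom, "F1") if denom else (0.0 if undefined_as_zero else 0.0)
    return MetricsReport(sensitivity=sens, precision=prec, f1=f1, specificity=spec)


# ---------------------------------------------------------------------------
# probe-consensus caller


@dataclass
class ConsensusSite:
    member_ids: tuple[int, ...]
    centroid: np.ndarray

    @property
    def size(self) -> int:
        return len(self.member_ids)


def group_consensus_sites(
    clusters: list[ProbeCluster], merge_distance: float = 4.0
) -> list[ConsensusSite]:
    """Single-linkage grouping of probe-cluster centroids into consensus
    sites; two clusters join a site when their centroids are within
    ``merge_distance`` A (transitively)."""
    if not clusters:
        raise ValueError("no probe clusters")
    cents = np.array([c.centroid for c in clusters])
    if len(clusters) == 1:
        labels = np.array([1])
    else:
        Z = linkage(pdist(cents), method="single")
        labels = fcluster(Z, t=merge_distance, criterion="distance")
    sites = []
    for lab in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == lab]
        member_ids = tuple(clusters[i].id for i in idx)
        centroid = cents[idx].mean(axis=0)
        sites.append(ConsensusSite(member_ids=member_ids, centroid=centroid))
    return sites


def ftmap_mode_hotspots(
    structure: ProteinStructure,
    clusters: list[ProbeCluster],
    merge_distance: float = 4.0,
    tolerance: float = 0.5,
) -> set[ResidueKey]:
    """Residues in vdW contact with probe atoms of the largest consensus site.

    The site with the most member clusters wins; ties break deterministically
    toward the site containing the smallest member cluster id.
    """
    sites = group_consensus_sites(clusters, merge_distance)
    best = max(sites, key=lambda s: (s.size, -min(s.member_ids)))
    members = [c for c in clusters if c.id in best.member_ids]
    probe_coords = np.vstack([c.coords for c in members])
    probe_radii = np.array([vdw_radius(e) for c in members for e in c.elements])

    out: set[ResidueKey] = set()
    for res in structure.residues:
        for atom in res.atoms:
            if atom.element == "H":
                continue
            ra = vdw_radius(atom.element)
            d = np.linalg.norm(probe_coords - atom.position, axis=1)
            if np.any(d <= ra + probe_radii + tolerance + 1e-9):
                out.add(res.key)
                break
    return out


# ---------------------------------------------------------------------------
# interface-mode caller and combination


def interface_mode_hotspots(model_complex: ComplexStructure, cutoff: float = 5.0) -> set[ResidueKey]:
    """Interface residues of a (modeled) complex called as hot spots."""
    return set(interface_residues(model_complex, cutoff=cutoff).interface)


def combine_union(pred_a: set[ResidueKey], pred_b: set[ResidueKey]) -> set[ResidueKey]:
    """Union combination of two prediction sets (a residue called by either
    method is called by the combination)."""
    return set(pred_a) | set(pred_b)


def venn(sets: list[set[ResidueKey]]) -> dict[tuple[int, ...], int]:
    """Exclusive-region counts for 2 or 3 prediction sets.

    Keys are the sorted tuples of set indices defining each non-empty
    exclusive region; values sum to the size of the union.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn supports 2 or 3 sets")
    out: dict[tuple[int, ...], int] = {}
    universe = set().union(*sets)
    for r in range(1, len(sets) + 1):
        for combo in combinations(range(len(sets)), r):
            region = set(universe)
            for i in range(len(sets)):
                region = region & sets[i] if i in combo else region - sets[i]
            out[combo] = len(region)
    return out
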