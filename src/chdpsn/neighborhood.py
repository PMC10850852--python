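"""Similarity-group retrieval (KNN or distance threshold) and vote-based
outcome prediction.

A similarity group is the neighbourhood of an index patient in the fused
distance space: either the k nearest training patients (ties at the k-th
distance broken by ascending patient id, so retrieval is deterministic)
or every training patient within a distance threshold.

Votes follow the interactive protocol: a binary outcome is predicted True
when *strictly more than* 50% of the group experienced it; a multiclass
outcome takes the class with the highest group proportion, ties resolved
toward the class more prevalent in the full training cohort and then by
class order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import PredictionError
from .similarity import DistanceMatrix

__all__ = [
    "SimilarityGroup",
    "knn_neighbors",
    "threshold_neighbors",
    "group_from_distances",
    "vote_binary",
    "vote_multiclass",
    "bin_ventilation",
    "VENTILATION_CLASSES",
]

VENTILATION_CLASSES = ("I", "II", "III", "IV")
_VENT_EDGES = (12.0, 24.0, 48.0)


@dataclass
class SimilarityGroup:
    """Neighbour set of one index patient, sorted by ascending distance."""

    index_id: str
    member_ids: list[str]
    distances: list[float]
    criterion: str  # e.g. "k=20" or "t=0.15"

    def __len__(self) -> int:
        return len(self.member_ids)


def _sorted_order(ids: Sequence[str], dists: np.ndarray) -> np.ndarray:
    """Ascending distance, ties broken by ascending patient id."""
    return np.lexsort((np.asarray(ids, dtype=object), dists))


def group_from_distances(
    index_id: str,
    ids: Sequence[str],
    dists: np.ndarray,
    k: int | None = None,
    threshold: float | None = None,
) -> SimilarityGroup:
    """Form a similarity group from a vector of candidate distances.

    ``ids``/``dists`` are the candidate pool; the index itself (matched by
    id) is excluded.  Exactly one of ``k`` / ``threshold`` must be given.
    """
    if (k is None) == (threshold is None):
        raise ValueError("give exactly one of k or threshold")
    ids = list(ids)
    dists = np.asarray(dists, dtype=float)
    keep = [i for i, pid in enumerate(ids) if pid != index_id]
    ids = [ids[i] for i in keep]
    dists = dists[keep]
    order = _sorted_order(ids, dists)

    if k is not None:
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        if k > len(ids):
            warnings.warn(
                f"k={k} exceeds cohort size {len(ids)}; returning all",
                stacklevel=2,
            )
            k = len(ids)
        sel = order[:k]
        criterion = f"k={k}"
    else:
        if not 0.0 <= threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {threshold}")
        sel = order[dists[order] <= threshold]
        criterion = f"t={threshold}"
    return SimilarityGroup(
        index_id=index_id,
        member_ids=[ids[i] for i in sel],
        distances=[float(dists[i]) for i in sel],
        criterion=criterion,
    )


def knn_neighbors(index_id: str, dm: DistanceMatrix, k: int) -> SimilarityGroup:
    """The k nearest neighbours of a patient already in the matrix."""
    return group_from_distances(index_id, dm.ids, dm.row(index_id), k=k)


def threshold_neighbors(index_id: str, dm: DistanceMatrix,
                        t: float) -> SimilarityGroup:
    """All patients within distance ``t`` of a patient in the matrix; may
    be empty."""
    return group_from_distances(index_id, dm.ids, dm.row(index_id),
                                threshold=t)


def vote_binary(group: SimilarityGroup,
                outcomes: Mapping[str, bool]) -> tuple[bool, float]:
    """Majority vote with the strict >50% rule.

    Returns ``(label, score)`` where score is the fraction of group members
    with the outcome and label is True only when score > 0.5 — an exact
    50/50 split votes False.
    """
    if len(group) == 0:
        raise PredictionError(
            f"empty similarity group for {group.index_id}; widen the criterion"
        )
    positives = sum(bool(outcomes[m]) for m in group.member_ids)
    score = positives / len(group)
    return score > 0.5, score


def vote_multiclass(
    group: SimilarityGroup,
    outcomes: Mapping[str, str],
    classes: Sequence[str],
    cohort_prevalence: Mapping[str, float] | None = None,
) -> tuple[str, dict[str, float]]:
    """Plurality vote: per-class member proportions (summing to 1) and the
    argmax class; ties resolved by higher full-cohort prevalence, then by
    position in ``classes``."""
    if len(group) == 0:
        raise PredictionError(
            f"empty similarity group for {group.index_id}; widen the criterion"
        )
    counts = {c: 0 for c in classes}
    for m in group.member_ids:
        c = outcomes[m]
        if c not in counts:
            raise KeyError(f"outcome class {c!r} not in {tuple(classes)}")
        counts[c] += 1
    n = len(group)
    scores = {c: counts[c] / n for c in classes}
    prev = cohort_prevalence or {}
    label = min(
        classes,
        key=lambda c: (-scores[c], -prev.get(c, 0.0), list(classes).index(c)),
    )
    return label, scores


def bin_ventilation(hours: float) -> str:
    """Ventilation-duration class: I [0,12) h, II [12,24) h, III [24,48) h,
    IV [48, inf) h."""
    if hours < 0:
        raise ValueError(f"ventilation hours must be >= 0, got {hours}")
    for cls, edge in zip(VENTILATION_CLASSES, _VENT_EDGES):
        if hours < edge:
            return cls
    return "IV"
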