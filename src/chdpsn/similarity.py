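"""Fusion of the four feature-group distances into a single patient
distance, the pairwise distance matrix, and clinical-phase sub-maps.

The patient distance is a weighted combination of four group distances —
echocardiographic indicators, diagnosis lists, preoperative clinical
features and surgical features:

    d_patient = (w1*d_indicator + w2*d_diag + w3*d_pre + w4*d_surg) / sum(w)

Dividing by the sum of the *active* weights keeps the fused distance in
[0, 1] and makes it invariant to rescaling all weights by a positive
constant, so user-adjusted weights need not be normalised.  Per-group
component matrices are cached on the :class:`DistanceMatrix` so that a
weight change re-fuses without recomputing group distances.

The four clinical-phase maps restrict the fusion to the feature groups
available at that stage of care: the screening map uses diagnoses only,
the echo map adds indicators, the patient map adds preoperative clinical
features, and the surgery map uses all four groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataAvailabilityError
from .feature_space import (
    CohortScaling,
    IndicatorSchema,
    IndicatorTransform,
    PatientRecord,
    clinical_distance,
    gower_cross,
    gower_matrix,
    surgical_distance,
)
from .ontology import Ontology, diagnosis_list_distance

__all__ = [
    "WeightVector",
    "DistanceMatrix",
    "PhaseMap",
    "PHASE_GROUPS",
    "fuse_distances",
    "build_distance_matrix",
    "phase_submap",
    "PipelineState",
    "fit_pipeline",
]

GROUPS = ("indicator", "diag", "pre", "surg")

PHASE_GROUPS: dict[str, tuple[str, ...]] = {
    "screening": ("diag",),
    "echo": ("diag", "indicator"),
    "patient": ("diag", "indicator", "pre"),
    "surgery": ("diag", "indicator", "pre", "surg"),
}


@dataclass(frozen=True)
class WeightVector:
    """Non-negative weights w1..w4 over the four feature groups."""

    indicator: float = 1.0
    diag: float = 1.0
    pre: float = 1.0
    surg: float = 1.0

    def __post_init__(self) -> None:
        vals = self.as_dict()
        if any(v < 0 for v in vals.values()):
            raise ConfigurationError(f"negative weight in {vals}")
        if all(v == 0 for v in vals.values()):
            raise ConfigurationError("at least one weight must be positive")

    def as_dict(self) -> dict[str, float]:
        return {"indicator": self.indicator, "diag": self.diag,
                "pre": self.pre, "surg": self.surg}

    def restricted_to(self, groups: Sequence[str]) -> "WeightVector":
        """Zero the weights of groups not in ``groups``."""
        vals = {g: (w if g in groups else 0.0)
                for g, w in self.as_dict().items()}
        if all(v == 0 for v in vals.values()):
            raise ConfigurationError(
                f"no active group left after restricting to {tuple(groups)}"
            )
        return WeightVector(**vals)


@dataclass
class DistanceMatrix:
    """Symmetric n x n fused patient distances plus the per-group
    component matrices they were fused from."""

    ids: list[str]
    values: np.ndarray
    components: dict[str, np.ndarray] = field(default_factory=dict)
    weights: WeightVector | None = None

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")

    def index_of(self, patient_id: str) -> int:
        return self.ids.index(patient_id)

    def row(self, patient_id: str) -> np.ndarray:
        return self.values[self.index_of(patient_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def refuse(self, w: WeightVector) -> "DistanceMatrix":
        """Re-fuse the cached component matrices under new weights."""
        if not self.components:
            raise ConfigurationError("component matrices were not retained")
        values = _fuse_arrays(self.components, w)
        return DistanceMatrix(self.ids, values, dict(self.components), w)


@dataclass
class PhaseMap:
    """A distance matrix restricted to the feature groups of one clinical
    phase."""

    phase: str
    active_groups: tuple[str, ...]
    matrix: DistanceMatrix


def fuse_distances(
    d_indicator: float | None,
    d_diag: float | None,
    d_pre: float | None,
    d_surg: float | None,
    w: WeightVector,
) -> float:
    """Weighted mean of the available group distances.

    A component may be None only if its weight is zero; the result is the
    weighted sum divided by the sum of active (positive-weight) weights.
    """
    comps = {"indicator": d_indicator, "diag": d_diag,
             "pre": d_pre, "surg": d_surg}
    weights = w.as_dict()
    total = 0.0
    wsum = 0.0
    for g in GROUPS:
        wg = weights[g]
        if wg == 0:
            continue
        if comps[g] is None:
            raise ConfigurationError(
                f"weight {wg} on missing component {g!r}"
            )
        d = comps[g]
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"component distance {g}={d} outside [0, 1]")
        total += wg * d
        wsum += wg
    if wsum == 0:
        raise ConfigurationError("all weights are zero")
    return total / wsum


def _fuse_arrays(components: Mapping[str, np.ndarray],
                 w: WeightVector) -> np.ndarray:
    weights = w.as_dict()
    total = None
    wsum = 0.0
    for g, wg in weights.items():
        if wg == 0:
            continue
        if g not in components:
            raise ConfigurationError(f"weight {wg} on missing component {g!r}")
        arr = wg * components[g]
        total = arr if total is None else total + arr
        wsum += wg
    if total is None:
        raise ConfigurationError("all weights are zero")
    return total / wsum


# -- component matrices ----------------------------------------------------


def _diagnosis_profile(rec: PatientRecord) -> tuple:
    return tuple(sorted((d.term_id, d.is_primary) for d in rec.diagnoses))


def diagnosis_distance_matrix(
    cohort: Sequence[PatientRecord],
    onto: Ontology,
    mode: str = "ungrade",
    alpha: float = 0.7,
) -> np.ndarray:
    """Pairwise diagnosis-list distances, computed once per unique
    diagnosis profile (cohorts share a small number of lesion patterns)."""
    profiles = [_diagnosis_profile(r) for r in cohort]
    rep: dict[tuple, list] = {}
    for r, p in zip(cohort, profiles):
        rep.setdefault(p, r.diagnoses)
    uniq = sorted(rep)
    pidx = {p: i for i, p in enumerate(uniq)}
    lists = [rep[p] for p in uniq]
    m = len(uniq)
    U = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            U[i, j] = U[j, i] = diagnosis_list_distance(
                lists[i], lists[j], onto, mode=mode, alpha=alpha
            )
    idx = np.array([pidx[p] for p in profiles])
    D = U[np.ix_(idx, idx)]
    np.fill_diagonal(D, 0.0)
    return D


def _clinical_array(cohort: Sequence[PatientRecord],
                    scaling: CohortScaling) -> tuple[np.ndarray, np.ndarray]:
    """Numeric matrix + ranges for the preoperative clinical group; sex is
    encoded 0/1 with range 1 so a mismatch contributes exactly 1."""
    cols = []
    ranges = []
    for f, (lo, hi) in scaling.clinical_ranges.items():
        cols.append([getattr(r, f) for r in cohort])
        ranges.append(hi - lo)
    cols.append([0.0 if r.sex == "male" else 1.0 for r in cohort])
    ranges.append(1.0)
    return np.array(cols, dtype=float).T, np.array(ranges)


def _surgical_array(cohort: Sequence[PatientRecord],
                    scaling: CohortScaling) -> tuple[np.ndarray, np.ndarray]:
    cols = []
    ranges = []
    for f, (lo, hi) in scaling.surgical_ranges.items():
        cols.append([getattr(r, f) for r in cohort])
        ranges.append(hi - lo)
    return np.array(cols, dtype=float).T, np.array(ranges)


# -- pipeline --------------------------------------------------------------


@dataclass
class PipelineState:
    """Everything fitted on the training cohort that an index patient
    needs: the indicator transform, the cohort scalings, the ontology, the
    mode/weights, and the cached distance matrix."""

    cohort: list[PatientRecord]
    onto: Ontology
    schema: IndicatorSchema
    transform: IndicatorTransform
    scaling: CohortScaling
    mode: str
    alpha: float
    weights: WeightVector
    matrix: DistanceMatrix
    feature_table: pd.DataFrame

    @property
    def ids(self) -> list[str]:
        return self.matrix.ids

    def distances_to(self, index: PatientRecord,
                     w: WeightVector | None = None) -> np.ndarray:
        """Fused distances from an unseen index patient to every training
        patient, using training-fitted transforms only."""
        w = w or self.weights
        feat_names = self.transform.feature_names_
        ranges = np.array([hi - lo for lo, hi in
                           (self.transform.feature_ranges_[f]
                            for f in feat_names)])
        x = self.transform.transform(index).iloc[0].to_numpy()
        X = self.feature_table[feat_names].to_numpy()
        comps: dict[str, np.ndarray] = {}
        if w.indicator > 0:
            comps["indicator"] = gower_cross(x, X, ranges)
        if w.diag > 0:
            comps["diag"] = np.array([
                diagnosis_list_distance(index.diagnoses, r.diagnoses,
                                        self.onto, mode=self.mode,
                                        alpha=self.alpha)
                for r in self.cohort
            ])
        if w.pre > 0:
            comps["pre"] = np.array([
                clinical_distance(index, r, self.scaling)
                for r in self.cohort
            ])
        if w.surg > 0:
            comps["surg"] = np.array([
                surgical_distance(index, r, self.scaling)
                for r in self.cohort
            ])
        weights = w.as_dict()
        wsum = sum(weights[g] for g in comps)
        total = np.zeros(len(self.cohort))
        for g, arr in comps.items():
            total += weights[g] * arr
        return total / wsum


def build_distance_matrix(
    cohort: Sequence[PatientRecord],
    onto: Ontology,
    schema: IndicatorSchema,
    method: str = "origin",
    mode: str = "ungrade",
    weights: WeightVector | None = None,
    alpha: float = 0.7,
) -> DistanceMatrix:
    """All pairwise fused distances for a preprocessed cohort (n >= 2),
    retaining the per-group component matrices."""
    cohort = list(cohort)
    if len(cohort) < 2:
        raise ValueError("need at least two patients")
    ids = [r.patient_id for r in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient_id in cohort")
    w = weights or WeightVector()
    tf = IndicatorTransform(schema, method)
    table = tf.fit_transform(cohort)
    scaling = CohortScaling.fit(cohort)

    ranges = np.array([hi - lo for lo, hi in
                       (tf.feature_ranges_[f] for f in tf.feature_names_)])
    components = {
        "indicator": gower_matrix(table.to_numpy(), ranges),
        "diag": diagnosis_distance_matrix(cohort, onto, mode, alpha),
    }
    X_pre, r_pre = _clinical_array(cohort, scaling)
    components["pre"] = gower_matrix(X_pre, r_pre)
    X_surg, r_surg = _surgical_array(cohort, scaling)
    components["surg"] = gower_matrix(X_surg, r_surg)

    values = _fuse_arrays(components, w)
    dm = DistanceMatrix(ids, values, components, w)
    dm._pipeline = PipelineState(  # type: ignore[attr-defined]
        cohort=cohort, onto=onto, schema=schema, transform=tf,
        scaling=scaling, mode=mode, alpha=alpha, weights=w,
        matrix=dm, feature_table=table,
    )
    return dm


def fit_pipeline(
    cohort: Sequence[PatientRecord],
    onto: Ontology,
    schema: IndicatorSchema,
    method: str = "origin",
    mode: str = "ungrade",
    weights: WeightVector | None = None,
    alpha: float = 0.7,
) -> PipelineState:
    """Fit the full similarity pipeline on a training cohort."""
    dm = build_distance_matrix(cohort, onto, schema, method, mode,
                               weights, alpha)
    return dm._pipeline  # type: ignore[attr-defined]


def phase_submap(dm: DistanceMatrix, phase: str,
                 weights: WeightVector | None = None) -> PhaseMap:
    """Restrict a built matrix to the feature groups of a clinical phase
    by zeroing the weights of inactive groups and re-fusing the cached
    component matrices."""
    if phase not in PHASE_GROUPS:
        raise ConfigurationError(
            f"unknown phase {phase!r}; expected one of {sorted(PHASE_GROUPS)}"
        )
    groups = PHASE_GROUPS[phase]
    missing = [g for g in groups if g not in dm.components]
    if missing:
        raise DataAvailabilityError(
            f"phase {phase!r} requires unavailable group(s) {missing}"
        )
    base = weights or dm.weights or WeightVector()
    w = base.restricted_to(groups)
    return PhaseMap(phase=phase, active_groups=groups, matrix=dm.refuse(w))
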