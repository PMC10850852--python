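"""Locally trained logistic models: KNN+LR and the size-matched random
baseline k-Random+LR.

The idea under test is that a conventional, interpretable model fitted on
the index patient's similarity group personalises prediction better than
the same model fitted on a random subset of equal size.  The estimator is
deliberately plain: L2-regularised logistic regression (multinomial for
the four ventilation-duration classes), with a constant-probability
fallback when the neighbourhood is single-class in the target — frequent
at small k, and then identical to the neighbourhood vote.

Feature handling for the local fits: transformed indicator columns plus
the clinical and surgical numerics and 0/1-encoded sex.  Missing indicator
values are mean-imputed and all columns standardised with *training*
cohort statistics (small local fits need comparable scales for the L2
penalty to be meaningful); the distance computations never see these
imputed values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .errors import PredictionError
from .feature_space import CLINICAL_NUMERIC, SURGICAL_NUMERIC, PatientRecord
from .neighborhood import (
    SimilarityGroup,
    VENTILATION_CLASSES,
    bin_ventilation,
    group_from_distances,
    vote_binary,
    vote_multiclass,
)
from .similarity import PipelineState

log = logging.getLogger(__name__)

__all__ = [
    "LocalModelSpec",
    "PredictionResult",
    "LocalFeatureSpace",
    "ConstantModel",
    "fit_local_model",
    "fit_random_baseline",
    "predict_case",
]


@dataclass
class LocalModelSpec:
    """Configuration of the local logistic fit."""

    target: str = "complication"  # or "ventilation_class"
    features: list[str] | None = None  # None -> all numeric features
    C: float = 1.0  # inverse L2 strength
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target not in ("complication", "ventilation_class"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.C <= 0:
            raise ValueError("regularization strength must be positive")


@dataclass
class PredictionResult:
    """One per-case prediction with full provenance."""

    index_id: str
    task: str
    label: bool | str
    score: float | dict[str, float]
    provenance: str  # vote | knn_lr | random_lr
    criterion: str
    group_ids: list[str] = field(default_factory=list)


class ConstantModel:
    """Fallback emitting a single class with probability 1; API-compatible
    with the sklearn estimator for the methods we use."""

    def __init__(self, label: bool | str, classes: Sequence):
        self.label = label
        self.classes_ = np.asarray(list(classes))

    def predict(self, X) -> np.ndarray:
        return np.asarray([self.label] * len(X), dtype=self.classes_.dtype)

    def predict_proba(self, X) -> np.ndarray:
        proba = (self.classes_ == self.label).astype(float)
        return np.tile(proba, (len(X), 1))


class LocalFeatureSpace:
    """Design-matrix builder fitted on the training cohort.

    Columns: transformed indicators, clinical numerics, surgical numerics,
    sex (0 male / 1 female).  NaNs are filled with training column means;
    columns unobserved in training are dropped; everything is standardised
    with training mean/sd (sd 0 -> column left centred).
    """

    def __init__(self, state: PipelineState,
                 features: list[str] | None = None):
        self.state = state
        raw = self._raw_frame(state.cohort)
        if features is not None:
            missing = set(features) - set(raw.columns)
            if missing:
                raise KeyError(f"unknown feature(s) {sorted(missing)}")
            raw = raw[features]
        raw = raw.dropna(axis=1, how="all")
        self.columns = list(raw.columns)
        self.means_ = raw.mean()
        sds = raw.std(ddof=0)
        self.sds_ = sds.where(sds > 0, 1.0)
        self.X_train = self._finish(raw)

    def _raw_frame(self, cohort: Sequence[PatientRecord]) -> pd.DataFrame:
        tf = self.state.transform
        ind = tf.transform(cohort)
        extra = pd.DataFrame(
            {
                **{f: [getattr(r, f) for r in cohort]
                   for f in CLINICAL_NUMERIC + SURGICAL_NUMERIC},
                "sex": [0.0 if r.sex == "male" else 1.0 for r in cohort],
            },
            index=ind.index,
        )
        return pd.concat([ind, extra], axis=1)

    def _finish(self, raw: pd.DataFrame) -> pd.DataFrame:
        filled = raw.fillna(self.means_)
        return (filled - self.means_) / self.sds_

    def rows(self, ids: Sequence[str]) -> np.ndarray:
        return self.X_train.loc[list(ids)].to_numpy()

    def row_for(self, record: PatientRecord) -> np.ndarray:
        raw = self._raw_frame([record])[self.columns]
        return self._finish(raw).to_numpy()[0]


def _target_values(state: PipelineState, ids: Sequence[str],
                   target: str) -> np.ndarray:
    by_id = {r.patient_id: r for r in state.cohort}
    if target == "complication":
        return np.array([bool(by_id[i].outcome.complication) for i in ids])
    return np.array(
        [bin_ventilation(by_id[i].outcome.ventilation_hours) for i in ids],
        dtype=object,
    )


def _classes_for(target: str) -> list:
    return [False, True] if target == "complication" else list(VENTILATION_CLASSES)


def fit_local_model(
    group: SimilarityGroup,
    state: PipelineState,
    spec: LocalModelSpec,
    fspace: LocalFeatureSpace | None = None,
):
    """Fit the local logistic model on the similarity-group members only.

    Single-class groups yield a :class:`ConstantModel` (logged); groups of
    size < 2 fall back to the constant model as well, with a warning.
    """
    if len(group) == 0:
        raise PredictionError("cannot fit a local model on an empty group")
    y = _target_values(state, group.member_ids, spec.target)
    uniq = sorted(set(y.tolist()), key=str)
    if len(uniq) == 1 or len(group) < 2:
        if len(group) < 2:
            log.warning("group of size %d for %s: constant-model fallback",
                        len(group), group.index_id)
        else:
            log.debug("single-class group for %s: constant-model fallback",
                      group.index_id)
        return ConstantModel(uniq[0] if len(uniq) == 1 else y[0],
                             _classes_for(spec.target))
    fspace = fspace or LocalFeatureSpace(state, spec.features)
    X = fspace.rows(group.member_ids)
    # default penalty is L2 with strength 1/C
    model = LogisticRegression(C=spec.C, max_iter=spec.max_iter,
                               solver="lbfgs")
    model.fit(X, y)
    return model


def fit_random_baseline(
    k: int,
    state: PipelineState,
    spec: LocalModelSpec,
    seed: int,
    exclude_id: str | None = None,
    fspace: LocalFeatureSpace | None = None,
):
    """Fit the same estimator on ``k`` patients drawn uniformly without
    replacement from the training cohort (excluding the index), seeded."""
    ids = [r.patient_id for r in state.cohort if r.patient_id != exclude_id]
    if k > len(ids):
        raise ValueError(f"k={k} exceeds available cohort size {len(ids)}")
    rng = np.random.default_rng(seed)
    sample = sorted(rng.choice(np.asarray(ids, dtype=object), size=k,
                               replace=False).tolist())
    group = SimilarityGroup(index_id=exclude_id or "", member_ids=sample,
                            distances=[float("nan")] * k,
                            criterion=f"random k={k}")
    return fit_local_model(group, state, spec, fspace=fspace)


def predict_case(
    index: PatientRecord,
    state: PipelineState,
    method: str = "vote",
    k: int | None = None,
    threshold: float | None = None,
    spec: LocalModelSpec | None = None,
    fspace: LocalFeatureSpace | None = None,
    seed: int = 0,
) -> PredictionResult:
    """End-to-end prediction for one index patient.

    Distances to all training patients are computed with the training
    fitted transforms, the similarity group is formed under the given
    criterion, and the chosen method produces the prediction:

    * ``vote`` — neighbourhood vote (strict >50% / plurality);
    * ``knn_lr`` — logistic model fitted on the group;
    * ``random_lr`` — logistic model fitted on a size-matched random
      subset (baseline).

    The index patient's own outcome is never read.
    """
    if method not in ("vote", "knn_lr", "random_lr"):
        raise ValueError(f"unknown prediction method {method!r}")
    spec = spec or LocalModelSpec()
    dists = state.distances_to(index)
    group = group_from_distances(index.patient_id, state.ids, dists,
                                 k=k, threshold=threshold)
    if len(group) == 0:
        raise PredictionError(
            f"empty similarity group for {index.patient_id}; widen the criterion"
        )
    task = spec.target

    if method == "vote":
        if task == "complication":
            outcomes = {r.patient_id: bool(r.outcome.complication)
                        for r in state.cohort}
            label, score = vote_binary(group, outcomes)
            return PredictionResult(index.patient_id, task, label, score,
                                    "vote", group.criterion, group.member_ids)
        outcomes = {r.patient_id: bin_ventilation(r.outcome.ventilation_hours)
                    for r in state.cohort}
        prev_vals = list(outcomes.values())
        prevalence = {c: prev_vals.count(c) / len(prev_vals)
                      for c in VENTILATION_CLASSES}
        label, scores = vote_multiclass(group, outcomes, VENTILATION_CLASSES,
                                        prevalence)
        return PredictionResult(index.patient_id, task, label, scores,
                                "vote", group.criterion, group.member_ids)

    fspace = fspace or LocalFeatureSpace(state, spec.features)
    if method == "knn_lr":
        model = fit_local_model(group, state, spec, fspace=fspace)
        provenance = "knn_lr"
    else:
        model = fit_random_baseline(len(group), state, spec, seed,
                                    exclude_id=index.patient_id,
                                    fspace=fspace)
        provenance = "random_lr"
    x = fspace.row_for(index)[None, :]
    proba = model.predict_proba(x)[0]
    classes = list(model.classes_)
    if task == "complication":
        p_pos = float(proba[classes.index(True)]) if True in classes else 0.0
        return PredictionResult(index.patient_id, task, p_pos > 0.5, p_pos,
                                provenance, group.criterion, group.member_ids)
    scores = {c: 0.0 for c in VENTILATION_CLASSES}
    for c, p in zip(classes, proba):
        scores[c] = float(p)
    label = max(VENTILATION_CLASSES, key=lambda c: scores[c])
    return PredictionResult(index.patient_id, task, label, scores,
                            provenance, group.criterion, group.member_ids)
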