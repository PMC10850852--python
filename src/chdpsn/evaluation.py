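"""Evaluation harness: confusion metrics, rank-based AUC, population-level
k selection, the benchmark grid, and outcome-view group-contrast tests.

Metric definitions (binary):

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1        = 2 * recall * precision / (recall + precision)

Undefined ratios (zero denominator) are reported as None with a reason,
never silently as 0.  The AUC is the rank-based (Mann-Whitney) statistic
with mid-rank tie handling; for the four ventilation classes a one-vs-rest
AUC is computed per class and macro-averaged.

The population-level k is chosen by leave-one-out neighbourhood voting on
the training cohort over a k grid, maximising F1 (binary) or macro-F1
(multiclass); ties go to the smallest k.  The benchmark grid mirrors the
evaluation protocol: {origin, zscore, combination} x {grade, ungrade} for
the KNN vote and KNN+LR, plus one size-matched k-Random+LR baseline row,
for each prediction task.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EvaluationError, LeakageError
from .feature_space import IndicatorSchema, Outcome, PatientRecord
from .local_model import LocalFeatureSpace, LocalModelSpec, predict_case
from .neighborhood import VENTILATION_CLASSES, bin_ventilation
from .ontology import Ontology
from .similarity import PipelineState, WeightVector, fit_pipeline

log = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_metrics",
    "auc_score",
    "auc_multiclass",
    "binary_report",
    "multiclass_report",
    "optimize_k",
    "run_benchmark",
    "GroupTestResult",
    "group_outcome_tests",
    "DEFAULT_K_GRID",
]

DEFAULT_K_GRID = (3, 5, 10, 15, 20, 30, 50, 75, 100, 150, 200)

PREPROCESSINGS = ("origin", "zscore", "combination")
DIAG_MODES = ("ungrade", "grade")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Metrics of one prediction run; None marks an undefined ratio, with
    the reason recorded in ``undefined``."""

    accuracy: float | None
    recall: float | None
    precision: float | None
    f1: float | None
    auc: float | None = None
    counts: ConfusionCounts | None = None
    task: str = ""
    method: str = ""
    undefined: dict[str, str] = field(default_factory=dict)


def confusion_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, recall, precision and F1 from confusion counts."""
    if c.total == 0:
        raise EvaluationError("no evaluated cases (all counts zero)")
    rep = MetricsReport(accuracy=(c.tp + c.tn) / c.total, recall=None,
                        precision=None, f1=None, counts=c)
    if c.tp + c.fn > 0:
        rep.recall = c.tp / (c.tp + c.fn)
    else:
        rep.undefined["recall"] = "no positive cases (TP + FN = 0)"
    if c.tp + c.fp > 0:
        rep.precision = c.tp / (c.tp + c.fp)
    else:
        rep.undefined["precision"] = "no positive predictions (TP + FP = 0)"
    if rep.recall is not None and rep.precision is not None:
        if rep.recall + rep.precision > 0:
            rep.f1 = (2 * rep.recall * rep.precision
                      / (rep.recall + rep.precision))
        else:
            rep.undefined["f1"] = "recall + precision = 0"
    else:
        rep.undefined["f1"] = "recall or precision undefined"
    return rep


def auc_score(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Rank-based (Mann-Whitney) AUC with mid-rank tie handling."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC undefined: only one class present")
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_multiclass(
    score_table: Mapping[str, Sequence[float]] | pd.DataFrame,
    labels: Sequence[str],
    classes: Sequence[str] = VENTILATION_CLASSES,
) -> tuple[float, dict[str, float | None]]:
    """One-vs-rest AUC per class plus the macro average over the classes
    for which it is defined (both one-vs-rest classes present)."""
    labels = list(labels)
    per_class: dict[str, float | None] = {}
    for c in classes:
        y = [lab == c for lab in labels]
        try:
            per_class[c] = auc_score(list(score_table[c]), y)
        except EvaluationError:
            per_class[c] = None
    defined = [v for v in per_class.values() if v is not None]
    if not defined:
        raise EvaluationError("AUC undefined for every class")
    return float(np.mean(defined)), per_class


def binary_report(y_true: Sequence[bool], y_pred: Sequence[bool],
                  scores: Sequence[float] | None = None) -> MetricsReport:
    yt = np.asarray(y_true, dtype=bool)
    yp = np.asarray(y_pred, dtype=bool)
    c = ConfusionCounts(
        tp=int((yt & yp).sum()), tn=int((~yt & ~yp).sum()),
        fp=int((~yt & yp).sum()), fn=int((yt & ~yp).sum()),
    )
    rep = confusion_metrics(c)
    if scores is not None:
        try:
            rep.auc = auc_score(scores, yt)
        except EvaluationError as exc:
            rep.undefined["auc"] = str(exc)
    return rep


def multiclass_report(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    score_table: pd.DataFrame | None = None,
    classes: Sequence[str] = VENTILATION_CLASSES,
) -> MetricsReport:
    """Accuracy plus macro recall / precision / F1 over the classes with
    support; macro one-vs-rest AUC when scores are given."""
    yt = np.asarray(y_true, dtype=object)
    yp = np.asarray(y_pred, dtype=object)
    n = len(yt)
    if n == 0:
        raise EvaluationError("no evaluated cases")
    acc = float((yt == yp).mean())
    recalls, precisions, f1s = [], [], []
    for c in classes:
        support = int((yt == c).sum())
        if support == 0:
            continue
        tp = int(((yt == c) & (yp == c)).sum())
        fp = int(((yt != c) & (yp == c)).sum())
        rec = tp / support
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        recalls.append(rec)
        precisions.append(prec)
        f1s.append(2 * rec * prec / (rec + prec) if rec + prec > 0 else 0.0)
    rep = MetricsReport(accuracy=acc, recall=float(np.mean(recalls)),
                        precision=float(np.mean(precisions)),
                        f1=float(np.mean(f1s)))
    if score_table is not None:
        try:
            rep.auc, _ = auc_multiclass(score_table, list(yt), classes)
        except EvaluationError as exc:
            rep.undefined["auc"] = str(exc)
    return rep


# -- leave-one-out k selection --------------------------------------------


def _loo_sorted_neighbors(state: PipelineState) -> list[np.ndarray]:
    """For each training patient, the indices of the others sorted by
    ascending distance with the documented id tie-break."""
    ids = np.asarray(state.ids, dtype=object)
    n = len(ids)
    out = []
    for i in range(n):
        row = state.matrix.values[i]
        order = np.lexsort((ids, row))
        out.append(order[order != i])
    return out


def loo_vote(
    state: PipelineState, task: str, ks: Sequence[int]
) -> dict[int, tuple[np.ndarray, object]]:
    """Leave-one-out neighbourhood votes on the training cohort for every
    k in ``ks`` (one shared sorted-neighbour pass).

    Returns per k a ``(labels, scores)`` pair: for the binary task the
    scores are the positive vote proportions; for the multiclass task a
    DataFrame of per-class proportions.
    """
    n = len(state.ids)
    neighbors = _loo_sorted_neighbors(state)
    if task == "complication":
        y = np.array([bool(r.outcome.complication) for r in state.cohort])
        out: dict[int, tuple[np.ndarray, object]] = {}
        for k in ks:
            kk = min(k, n - 1)
            scores = np.array([y[order[:kk]].mean() for order in neighbors])
            out[k] = (scores > 0.5, scores)
        return out
    y = np.array([bin_ventilation(r.outcome.ventilation_hours)
                  for r in state.cohort], dtype=object)
    prevalence = {c: float((y == c).mean()) for c in VENTILATION_CLASSES}
    cls_idx = {c: i for i, c in enumerate(VENTILATION_CLASSES)}
    onehot = np.zeros((n, len(VENTILATION_CLASSES)))
    for i, c in enumerate(y):
        onehot[i, cls_idx[c]] = 1.0
    out = {}
    order_key = [(-prevalence[c], i) for i, c in enumerate(VENTILATION_CLASSES)]
    for k in ks:
        kk = min(k, n - 1)
        props = np.stack([onehot[order[:kk]].mean(axis=0)
                          for order in neighbors])
        labels = np.empty(n, dtype=object)
        for i in range(n):
            best = min(range(len(VENTILATION_CLASSES)),
                       key=lambda j: (-props[i, j], order_key[j]))
            labels[i] = VENTILATION_CLASSES[best]
        out[k] = (labels, pd.DataFrame(props, columns=VENTILATION_CLASSES))
    return out


def optimize_k(
    state: PipelineState,
    task: str = "complication",
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    metric: str = "f1",
) -> int:
    """Population-level k: leave-one-out vote over the training cohort at
    each k of the grid, maximising the selection metric; ties go to the
    smallest k.

    ``metric`` is ``"f1"`` (default; macro-F1 for the multiclass task) or
    ``"auc"`` (rank AUC of the vote proportions; macro one-vs-rest for the
    multiclass task).
    """
    if metric not in ("f1", "auc"):
        raise ValueError(f"unknown k-selection metric {metric!r}")
    n = len(state.ids)
    grid = sorted({k for k in k_grid if 1 <= k <= n - 1})
    if not grid:
        raise EvaluationError(f"empty k grid after clipping to [1, {n - 1}]")
    if task == "complication":
        y = np.array([bool(r.outcome.complication) for r in state.cohort])
        if y.all() or not y.any():
            raise EvaluationError("training cohort has a single outcome class")
    else:
        y = np.array([bin_ventilation(r.outcome.ventilation_hours)
                      for r in state.cohort], dtype=object)
        if len(set(y.tolist())) < 2:
            raise EvaluationError("training cohort has a single outcome class")
    votes = loo_vote(state, task, grid)
    best_k, best_val = None, -1.0
    for k in grid:
        pred, scores = votes[k]
        if task == "complication":
            if metric == "auc":
                val = auc_score(scores, y)
            else:
                rep = binary_report(y, pred)
                val = rep.f1 if rep.f1 is not None else 0.0
        else:
            if metric == "auc":
                val, _ = auc_multiclass(scores, list(y))
            else:
                val = multiclass_report(y, pred).f1
        if val > best_val + 1e-12:
            best_k, best_val = k, val
    return int(best_k)


# -- benchmark grid --------------------------------------------------------


def _evaluate_predictions(task, y_true, preds) -> MetricsReport:
    if task == "complication":
        y_pred = [p.label for p in preds]
        scores = [float(p.score) for p in preds]
        return binary_report(y_true, y_pred, scores)
    y_pred = [p.label for p in preds]
    score_table = pd.DataFrame(
        {c: [p.score[c] for p in preds] for c in VENTILATION_CLASSES}
    )
    return multiclass_report(y_true, y_pred, score_table)


def run_benchmark(
    train: Sequence[PatientRecord],
    test: Sequence[PatientRecord],
    onto: Ontology,
    schema: IndicatorSchema,
    tasks: Sequence[str] = ("complication", "ventilation_class"),
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    weights: WeightVector | None = None,
    alpha: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """The full evaluation grid on a train/test cohort pair.

    For each of the six preprocessing x diagnosis-mode configurations the
    pipeline is fitted on the training cohort, the population-level k is
    selected per task, and every test case is predicted by the KNN vote
    and by KNN+LR.  One k-Random+LR baseline row per task (size-matched to
    the origin+ungrade optimized k) completes the 13-method-row structure.
    """
    train_ids = {r.patient_id for r in train}
    overlap = train_ids & {r.patient_id for r in test}
    if overlap:
        raise LeakageError(
            f"train and test cohorts share {len(overlap)} patient id(s), "
            f"e.g. {sorted(overlap)[:3]}"
        )
    for r in test:
        if r.outcome is None:
            raise EvaluationError(f"test case {r.patient_id} lacks outcomes")

    rows = []
    truth = {
        "complication": [bool(r.outcome.complication) for r in test],
        "ventilation_class": [bin_ventilation(r.outcome.ventilation_hours)
                              for r in test],
    }
    first_state: PipelineState | None = None
    first_k: dict[str, int] = {}
    rng = np.random.default_rng(seed)

    for prep in PREPROCESSINGS:
        for mode in DIAG_MODES:
            state = fit_pipeline(train, onto, schema, method=prep, mode=mode,
                                 weights=weights, alpha=alpha)
            config = f"{prep}+{mode}"
            for task in tasks:
                k = optimize_k(state, task, k_grid)
                spec = LocalModelSpec(target=task)
                fspace = LocalFeatureSpace(state)
                votes, lrs = [], []
                for rec in test:
                    votes.append(predict_case(rec, state, "vote", k=k,
                                              spec=spec, fspace=fspace))
                    lrs.append(predict_case(rec, state, "knn_lr", k=k,
                                            spec=spec, fspace=fspace))
                for family, preds in (("KNN", votes), ("KNN+LR", lrs)):
                    rep = _evaluate_predictions(task, truth[task], preds)
                    rows.append(_row(task, family, config, k, rep, len(test)))
                if first_state is None or task not in first_k:
                    first_k[task] = k
                if first_state is None:
                    first_state = state
            if first_state is None:
                first_state = state

    # one size-matched random baseline row per task
    for task in tasks:
        spec = LocalModelSpec(target=task)
        fspace = LocalFeatureSpace(first_state)
        k = first_k[task]
        preds = [
            predict_case(rec, first_state, "random_lr", k=k, spec=spec,
                         fspace=fspace, seed=int(rng.integers(2**31)))
            for rec in test
        ]
        rep = _evaluate_predictions(task, truth[task], preds)
        rows.append(_row(task, "k-Random+LR", "origin+ungrade", k, rep,
                         len(test)))

    df = pd.DataFrame(rows)
    order = {"KNN": 0, "KNN+LR": 1, "k-Random+LR": 2}
    df = df.sort_values(
        ["task", "family", "config"],
        key=lambda s: s.map(order) if s.name == "family" else s,
        kind="stable",
    ).reset_index(drop=True)
    return df


def _row(task, family, config, k, rep: MetricsReport, n_test) -> dict:
    return {
        "task": task, "family": family, "config": config, "k": k,
        "accuracy": rep.accuracy, "recall": rep.recall,
        "precision": rep.precision, "f1": rep.f1, "auc": rep.auc,
        "n_test": n_test,
    }


def benchmark_to_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# -- outcome-view group contrasts -----------------------------------------


@dataclass
class GroupTestResult:
    outcome: str
    test: str
    statistic: float | None
    p_value: float | None
    significant: bool | None
    reason: str = ""


CONTINUOUS_OUTCOMES = ("ventilation_hours", "icu_los_days",
                       "hospital_los_days")
BINARY_OUTCOMES = ("complication", "survived")


def group_outcome_tests(
    members: Sequence[Outcome],
    others: Sequence[Outcome],
    alpha: float = 0.05,
    yates: bool = False,
) -> dict[str, GroupTestResult]:
    """Outcome-view contrasts between a similarity group and the rest of
    the cohort: two-sided Mann-Whitney U for the continuous outcomes
    (exact when both sides have <= 8 cases, otherwise the tie-corrected
    normal approximation) and a 1-df chi-square for the binary ones
    (Pearson by default, Yates continuity correction optional).  The
    significance flag at ``alpha`` is the "check box turns red" signal.
    """
    if not members or not others:
        raise ValueError("both groups must be non-empty")
    out: dict[str, GroupTestResult] = {}
    for name in CONTINUOUS_OUTCOMES:
        a = np.array([getattr(o, name) for o in members], dtype=float)
        b = np.array([getattr(o, name) for o in others], dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            out[name] = GroupTestResult(name, "mannwhitneyu", None, None,
                                        None, "all values identical")
            continue
        method = "exact" if max(len(a), len(b)) <= 8 else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        out[name] = GroupTestResult(name, "mannwhitneyu",
                                    float(res.statistic), float(res.pvalue),
                                    bool(res.pvalue < alpha))
    for name in BINARY_OUTCOMES:
        a = [bool(getattr(o, name)) for o in members]
        b = [bool(getattr(o, name)) for o in others]
        table = np.array([
            [sum(a), len(a) - sum(a)],
            [sum(b), len(b) - sum(b)],
        ])
        if (table.sum(axis=0) == 0).any():
            out[name] = GroupTestResult(name, "chi2", None, None, None,
                                        "a column margin is zero")
            continue
        res = stats.chi2_contingency(table, correction=yates)
        out[name] = GroupTestResult(name, "chi2", float(res.statistic),
                                    float(res.pvalue),
                                    bool(res.pvalue < alpha))
    return out
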