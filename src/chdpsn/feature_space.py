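"""Patient records, indicator schema, quality filtering, indicator
preprocessing, and the per-group Gower-style distances.

Echocardiographic indicators are *sparse*: a measurement (defect diameter,
shunt velocity, pressure gradient, ...) exists only when the corresponding
malformation is present, so missingness is structural and is never imputed
for distance purposes.  All per-group distances are Gower-style means of
range-normalised absolute differences restricted to features observed in
both records; a pair with no shared observed feature gets the maximal
distance 1.

Three indicator preprocessings are supported:

* ``origin`` — raw values;
* ``zscore`` — per-indicator standardisation with cohort sample statistics
  (ddof=1);
* ``combination`` — the origin table augmented with configured ratio
  columns (numerator / denominator), computed only where both members are
  observed.

A transform is *fitted* on a training cohort; an unseen index patient is
transformed with the training statistics only, so there is no leakage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, TransformError
from .ontology import DiagnosisAssignment

log = logging.getLogger(__name__)

__all__ = [
    "Outcome",
    "PatientRecord",
    "RatioPair",
    "IndicatorSchema",
    "range_filter",
    "IndicatorTransform",
    "preprocess_indicators",
    "indicator_distance",
    "clinical_distance",
    "surgical_distance",
    "CohortScaling",
    "gower_matrix",
    "gower_cross",
]

CLINICAL_NUMERIC = ("age_months", "height_cm", "weight_kg", "preop_spo2_pct")
SURGICAL_NUMERIC = ("surgery_min", "cpb_min", "clamp_min")


@dataclass(frozen=True)
class Outcome:
    """Postoperative outcomes of one surgical case."""

    complication: bool
    ventilation_hours: float
    icu_los_days: float
    hospital_los_days: float
    survived: bool = True


@dataclass
class PatientRecord:
    """One surgical CHD case.

    ``indicators`` maps indicator name -> value; absent keys mean the
    measurement was not made (never encoded as 0 or a sentinel).
    ``outcome`` is None for an index (query) patient.
    """

    patient_id: str
    sex: str
    age_months: float
    height_cm: float
    weight_kg: float
    preop_spo2_pct: float
    indicators: dict[str, float] = field(default_factory=dict)
    diagnoses: list[DiagnosisAssignment] = field(default_factory=list)
    surgery_min: float = 0.0
    cpb_min: float = 0.0
    clamp_min: float = 0.0
    outcome: Outcome | None = None


@dataclass(frozen=True)
class RatioPair:
    """A configured indicator-combination ratio column."""

    numerator: str
    denominator: str
    name: str


@dataclass
class IndicatorSchema:
    """Plausible ranges and ratio pairs for the indicator space.

    ``ranges`` gives, per indicator, the physiologically plausible
    [low, high] interval used by quality control.
    """

    ranges: dict[str, tuple[float, float]]
    ratio_pairs: list[RatioPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, (low, high) in self.ranges.items():
            if not low < high:
                raise SchemaError(f"indicator {name!r}: low {low} >= high {high}")
        for rp in self.ratio_pairs:
            for member in (rp.numerator, rp.denominator):
                if member not in self.ranges:
                    raise SchemaError(
                        f"ratio pair {rp.name!r} references unknown "
                        f"indicator {member!r}"
                    )

    @property
    def names(self) -> list[str]:
        return list(self.ranges)


def range_filter(
    cohort: Sequence[PatientRecord],
    schema: IndicatorSchema,
    policy: str = "null",
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Quality control: remove indicator values outside their plausible range.

    ``policy='null'`` sets the offending value missing; ``policy='drop'``
    removes the whole record.  Returns the filtered cohort and a report
    with one row per action (patient_id, indicator, value, action).
    Missing values are not out-of-range and produce no report row.
    """
    if policy not in ("drop", "null"):
        raise ValueError(f"unknown range_filter policy {policy!r}")
    rows: list[dict] = []
    out: list[PatientRecord] = []
    for rec in cohort:
        bad: list[tuple[str, float]] = []
        for name, value in rec.indicators.items():
            if name not in schema.ranges:
                raise SchemaError(
                    f"indicator {name!r} (patient {rec.patient_id}) "
                    "is absent from the schema"
                )
            low, high = schema.ranges[name]
            if not (low <= value <= high):
                bad.append((name, value))
        if not bad:
            out.append(rec)
            continue
        if policy == "drop":
            for name, value in bad:
                rows.append({"patient_id": rec.patient_id, "indicator": name,
                             "value": value, "action": "record_dropped"})
            continue
        cleaned = dict(rec.indicators)
        for name, value in bad:
            del cleaned[name]
            rows.append({"patient_id": rec.patient_id, "indicator": name,
                         "value": value, "action": "value_nulled"})
        out.append(replace(rec, indicators=cleaned))
    report = pd.DataFrame(rows, columns=["patient_id", "indicator", "value",
                                         "action"])
    return out, report


class IndicatorTransform:
    """Fitted indicator preprocessing (origin / zscore / combination).

    Fitting records, per output feature, the training statistics needed to
    transform an unseen record (means and sds for zscore, nothing for
    origin) and the observed training min–max used to scale distances.
    Applying the fitted transform to the training cohort twice is
    idempotent by construction.
    """

    def __init__(self, schema: IndicatorSchema, method: str = "origin"):
        if method not in ("origin", "zscore", "combination"):
            raise ValueError(f"unknown preprocessing method {method!r}")
        self.schema = schema
        self.method = method
        self.means_: dict[str, float] = {}
        self.sds_: dict[str, float] = {}
        self.feature_ranges_: dict[str, tuple[float, float]] = {}
        self.feature_names_: list[str] = []
        self._fitted = False

    # -- fitting ----------------------------------------------------------

    def fit(self, cohort: Sequence[PatientRecord]) -> "IndicatorTransform":
        table = self._raw_table(cohort)
        if self.method == "zscore":
            for name in table.columns:
                col = table[name].dropna()
                if len(col) < 2:
                    # unusable for standardisation; keep but flag at transform
                    self.means_[name] = float(col.mean()) if len(col) else 0.0
                    self.sds_[name] = float("nan")
                    continue
                sd = float(col.std(ddof=1))
                if sd == 0.0:
                    raise TransformError(
                        f"zscore undefined for constant indicator {name!r}"
                    )
                self.means_[name] = float(col.mean())
                self.sds_[name] = sd
        out = self._apply(table)
        self.feature_names_ = list(out.columns)
        for name in out.columns:
            col = out[name].dropna()
            if len(col):
                self.feature_ranges_[name] = (float(col.min()), float(col.max()))
            else:
                self.feature_ranges_[name] = (0.0, 0.0)
        self._fitted = True
        return self

    def _raw_table(self, cohort: Sequence[PatientRecord]) -> pd.DataFrame:
        names = self.schema.names
        data = {
            name: [rec.indicators.get(name, np.nan) for rec in cohort]
            for name in names
        }
        return pd.DataFrame(data, index=[rec.patient_id for rec in cohort],
                            dtype=float)

    # -- application ------------------------------------------------------

    def _apply(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.method == "origin":
            return table.copy()
        if self.method == "zscore":
            out = table.copy()
            for name in out.columns:
                sd = self.sds_.get(name, float("nan"))
                if math.isnan(sd):
                    continue  # left on the original scale (flagged at fit)
                out[name] = (out[name] - self.means_[name]) / sd
            return out
        out = table.copy()
        for rp in self.schema.ratio_pairs:
            num = table[rp.numerator]
            den = table[rp.denominator]
            ratio = num / den
            zero_den = den == 0
            if bool((zero_den & num.notna()).any()):
                log.warning("ratio %s: zero denominator for %d record(s); "
                            "value set missing", rp.name,
                            int((zero_den & num.notna()).sum()))
            ratio[zero_den] = np.nan
            out[rp.name] = ratio
        return out

    def transform(
        self, cohort: Sequence[PatientRecord] | PatientRecord
    ) -> pd.DataFrame:
        """Transform records with the *training* statistics."""
        if not self._fitted:
            raise TransformError("transform used before fit")
        single = isinstance(cohort, PatientRecord)
        recs = [cohort] if single else list(cohort)
        return self._apply(self._raw_table(recs))

    def fit_transform(self, cohort: Sequence[PatientRecord]) -> pd.DataFrame:
        return self.fit(cohort).transform(cohort)


def preprocess_indicators(
    cohort: Sequence[PatientRecord],
    schema: IndicatorSchema,
    method: str = "origin",
) -> tuple[pd.DataFrame, IndicatorTransform]:
    """Fit the chosen preprocessing on ``cohort`` and return the feature
    table plus the fitted transform (for index patients)."""
    tf = IndicatorTransform(schema, method)
    return tf.fit_transform(cohort), tf


# -- Gower-style distances -------------------------------------------------


def _gower_pair(
    x: Mapping[str, float],
    y: Mapping[str, float],
    ranges: Mapping[str, tuple[float, float]],
) -> float:
    """Mean normalised absolute difference over features observed in both
    rows; 1.0 when nothing is shared."""
    total = 0.0
    count = 0
    for name, (lo, hi) in ranges.items():
        xv = x.get(name)
        yv = y.get(name)
        if xv is None or yv is None:
            continue
        if isinstance(xv, float) and math.isnan(xv):
            continue
        if isinstance(yv, float) and math.isnan(yv):
            continue
        rng = hi - lo
        if rng <= 0:
            contrib = 0.0 if xv == yv else 1.0
            if contrib:
                log.debug("zero-range feature %s with unequal values", name)
        else:
            contrib = min(abs(xv - yv) / rng, 1.0)
        total += contrib
        count += 1
    if count == 0:
        return 1.0
    return total / count


def indicator_distance(
    x: Mapping[str, float] | pd.Series,
    y: Mapping[str, float] | pd.Series,
    scaling: Mapping[str, tuple[float, float]],
) -> float:
    """Distance in [0, 1] between two preprocessed indicator rows."""
    if isinstance(x, pd.Series):
        x = x.to_dict()
    if isinstance(y, pd.Series):
        y = y.to_dict()
    return _gower_pair(x, y, scaling)


@dataclass
class CohortScaling:
    """Training-cohort min–max ranges for the clinical and surgical
    numerics; fitted once and reused for index patients."""

    clinical_ranges: dict[str, tuple[float, float]]
    surgical_ranges: dict[str, tuple[float, float]]

    @classmethod
    def fit(cls, cohort: Sequence[PatientRecord]) -> "CohortScaling":
        def rng(fields: tuple[str, ...]) -> dict[str, tuple[float, float]]:
            out = {}
            for f in fields:
                vals = [getattr(rec, f) for rec in cohort
                        if getattr(rec, f) is not None]
                vals = [v for v in vals if not math.isnan(v)]
                out[f] = (min(vals), max(vals)) if vals else (0.0, 0.0)
            return out

        return cls(rng(CLINICAL_NUMERIC), rng(SURGICAL_NUMERIC))


def clinical_distance(a: PatientRecord, b: PatientRecord,
                      scaling: CohortScaling) -> float:
    """Gower mean over age, height, weight, SpO2 and sex (0/1 mismatch)."""
    x = {f: getattr(a, f) for f in CLINICAL_NUMERIC}
    y = {f: getattr(b, f) for f in CLINICAL_NUMERIC}
    ranges: dict[str, tuple[float, float]] = dict(scaling.clinical_ranges)
    x["sex"] = 0.0 if a.sex == b.sex else 1.0
    y["sex"] = 0.0
    ranges["sex"] = (0.0, 1.0)
    return _gower_pair(x, y, ranges)


def surgical_distance(a: PatientRecord, b: PatientRecord,
                      scaling: CohortScaling) -> float:
    """Gower mean over surgery, cardiopulmonary-bypass and cross-clamp
    durations."""
    x = {f: getattr(a, f) for f in SURGICAL_NUMERIC}
    y = {f: getattr(b, f) for f in SURGICAL_NUMERIC}
    return _gower_pair(x, y, scaling.surgical_ranges)


# -- vectorised pairwise machinery (used by the distance-matrix builder) ---


def gower_matrix(X: np.ndarray, ranges: np.ndarray) -> np.ndarray:
    """Pairwise Gower distance over the rows of ``X`` (NaN = unobserved).

    ``ranges[j]`` is the scaling range of column j; zero-range columns
    contribute 0 for equal values and 1 otherwise.  Pairs with no shared
    observed column get distance 1.  The diagonal is forced to 0.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for j in range(p):
        col = X[:, j]
        obs = ~np.isnan(col)
        if not obs.any():
            continue
        shared = obs[:, None] & obs[None, :]
        diff = np.abs(col[:, None] - col[None, :])
        if ranges[j] > 0:
            contrib = np.clip(diff / ranges[j], 0.0, 1.0)
        else:
            contrib = (diff != 0).astype(float)
        num += np.where(shared, np.nan_to_num(contrib), 0.0)
        den += shared
    D = np.where(den > 0, num / np.maximum(den, 1), 1.0)
    np.fill_diagonal(D, 0.0)
    return D


def gower_cross(x: np.ndarray, X: np.ndarray, ranges: np.ndarray) -> np.ndarray:
    """Gower distances from one row ``x`` to every row of ``X``."""
    x = np.asarray(x, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    num = np.zeros(n)
    den = np.zeros(n)
    for j in range(p):
        if np.isnan(x[j]):
            continue
        col = X[:, j]
        obs = ~np.isnan(col)
        diff = np.abs(col - x[j])
        if ranges[j] > 0:
            contrib = np.clip(diff / ranges[j], 0.0, 1.0)
        else:
            contrib = (diff != 0).astype(float)
        num += np.where(obs, np.nan_to_num(contrib), 0.0)
        den += obs
    return np.where(den > 0, num / np.maximum(den, 1), 1.0)
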