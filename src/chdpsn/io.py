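"""Readers and writers for cohort tables, ontologies and run configs.

Cohort exchange formats:

* CSV — one row per patient; the diagnosis list is encoded in a single
  ``diagnoses`` column as ``;``-separated term ids with a trailing ``*``
  marking primary diagnoses (``VSD*;PDA``); every column not in the fixed
  demographic/surgical/outcome set is an indicator, with empty cells for
  missing measurements.
* JSON-lines — one object per patient with nested ``indicators`` and
  ``diagnoses`` maps.

Malformed rows are rejected with the offending line/field named; values
are never silently coerced.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .feature_space import Outcome, PatientRecord
from .ontology import DiagnosisAssignment, Ontology, load_obo, load_ontology

__all__ = [
    "encode_diagnoses",
    "decode_diagnoses",
    "cohort_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_cohort_jsonl",
    "read_cohort_jsonl",
    "read_cohort",
    "read_ontology_file",
    "load_config",
]

FIXED_COLUMNS = (
    "patient_id", "sex", "age_months", "height_cm", "weight_kg",
    "preop_spo2_pct", "diagnoses", "surgery_min", "cpb_min", "clamp_min",
    "complication", "ventilation_hours", "icu_los_days",
    "hospital_los_days", "survived",
)
OUTCOME_COLUMNS = ("complication", "ventilation_hours", "icu_los_days",
                   "hospital_los_days", "survived")


def encode_diagnoses(diagnoses: Sequence[DiagnosisAssignment]) -> str:
    return ";".join(
        d.term_id + ("*" if d.is_primary else "") for d in diagnoses
    )


def decode_diagnoses(text: str) -> list[DiagnosisAssignment]:
    out = []
    for token in str(text).split(";"):
        token = token.strip()
        if not token:
            continue
        if token.endswith("*"):
            out.append(DiagnosisAssignment(token[:-1], is_primary=True))
        else:
            out.append(DiagnosisAssignment(token, is_primary=False))
    return out


def _outcome_to_cells(o: Outcome | None) -> dict:
    if o is None:
        return {c: None for c in OUTCOME_COLUMNS}
    return {
        "complication": bool(o.complication),
        "ventilation_hours": o.ventilation_hours,
        "icu_los_days": o.icu_los_days,
        "hospital_los_days": o.hospital_los_days,
        "survived": bool(o.survived),
    }


def cohort_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    indicator_names = sorted({n for r in cohort for n in r.indicators})
    rows = []
    for r in cohort:
        row = {
            "patient_id": r.patient_id, "sex": r.sex,
            "age_months": r.age_months, "height_cm": r.height_cm,
            "weight_kg": r.weight_kg, "preop_spo2_pct": r.preop_spo2_pct,
            "diagnoses": encode_diagnoses(r.diagnoses),
            "surgery_min": r.surgery_min, "cpb_min": r.cpb_min,
            "clamp_min": r.clamp_min,
            **_outcome_to_cells(r.outcome),
        }
        for n in indicator_names:
            row[n] = r.indicators.get(n)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(FIXED_COLUMNS) + indicator_names)


def write_cohort_csv(cohort: Sequence[PatientRecord], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def _parse_bool(value, where: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "1.0", "yes"):
        return True
    if text in ("false", "0", "0.0", "no"):
        return False
    raise ValueError(f"{where}: cannot parse boolean from {value!r}")


def _parse_float(value, where: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{where}: cannot parse number from {value!r}") from exc


def _record_from_mapping(row: dict, indicator_names: Sequence[str],
                         where: str) -> PatientRecord:
    def cell(name):
        v = row.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return v

    pid = cell("patient_id")
    if not pid:
        raise ValueError(f"{where}: missing patient_id")
    sex = cell("sex")
    if sex not in ("male", "female"):
        raise ValueError(f"{where}: sex must be male/female, got {sex!r}")

    outcome = None
    if cell("complication") is not None:
        outcome = Outcome(
            complication=_parse_bool(cell("complication"), where),
            ventilation_hours=_parse_float(cell("ventilation_hours"), where),
            icu_los_days=_parse_float(cell("icu_los_days"), where),
            hospital_los_days=_parse_float(cell("hospital_los_days"), where),
            survived=_parse_bool(cell("survived"), where)
            if cell("survived") is not None else True,
        )
    indicators = {}
    for n in indicator_names:
        v = cell(n)
        if v is not None:
            indicators[n] = _parse_float(v, f"{where}, indicator {n}")
    diag_cell = cell("diagnoses")
    diagnoses = decode_diagnoses(diag_cell) if diag_cell is not None else (
        row.get("_diagnoses_parsed") or []
    )
    return PatientRecord(
        patient_id=str(pid), sex=sex,
        age_months=_parse_float(cell("age_months"), where),
        height_cm=_parse_float(cell("height_cm"), where),
        weight_kg=_parse_float(cell("weight_kg"), where),
        preop_spo2_pct=_parse_float(cell("preop_spo2_pct"), where),
        indicators=indicators, diagnoses=diagnoses,
        surgery_min=_parse_float(cell("surgery_min"), where),
        cpb_min=_parse_float(cell("cpb_min"), where),
        clamp_min=_parse_float(cell("clamp_min"), where),
        outcome=outcome,
    )


def read_cohort_csv(path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str, "diagnoses": str})
    indicator_names = [c for c in df.columns if c not in FIXED_COLUMNS]
    out = []
    for i, row in enumerate(df.to_dict(orient="records")):
        where = f"{path}, data row {i + 1}"
        out.append(_record_from_mapping(row, indicator_names, where))
    return out


def write_cohort_jsonl(cohort: Sequence[PatientRecord], path) -> None:
    with open(path, "w") as fh:
        for r in cohort:
            obj = {
                "patient_id": r.patient_id, "sex": r.sex,
                "age_months": r.age_months, "height_cm": r.height_cm,
                "weight_kg": r.weight_kg, "preop_spo2_pct": r.preop_spo2_pct,
                "indicators": r.indicators,
                "diagnoses": [
                    {"term_id": d.term_id, "is_primary": d.is_primary}
                    for d in r.diagnoses
                ],
                "surgery_min": r.surgery_min, "cpb_min": r.cpb_min,
                "clamp_min": r.clamp_min,
                "outcome": _outcome_to_cells(r.outcome)
                if r.outcome is not None else None,
            }
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def read_cohort_jsonl(path) -> list[PatientRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            where = f"{path}, line {lineno}"
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{where}: invalid JSON ({exc})") from exc
            flat = {k: v for k, v in obj.items()
                    if k not in ("indicators", "diagnoses", "outcome")}
            if obj.get("outcome"):
                flat.update(obj["outcome"])
            flat["diagnoses"] = None
            flat["_diagnoses_parsed"] = [
                DiagnosisAssignment(d["term_id"], bool(d.get("is_primary")))
                for d in obj.get("diagnoses", [])
            ]
            indicators = obj.get("indicators", {})
            flat.update(indicators)
            out.append(_record_from_mapping(flat, list(indicators), where))
    return out


def read_cohort(path) -> list[PatientRecord]:
    path = Path(path)
    if path.suffix in (".jsonl", ".ndjson"):
        return read_cohort_jsonl(path)
    return read_cohort_csv(path)


def read_ontology_file(path, labels_path=None) -> Ontology:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".obo" or text.lstrip().startswith(("format-version",
                                                          "[Term]")):
        return load_obo(text)
    labels = None
    if labels_path is not None:
        labels = {}
        for line in Path(labels_path).read_text().splitlines():
            if line.strip():
                tid, _, lab = line.partition("\t")
                labels[tid] = lab
    return load_ontology(text, labels)


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)
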