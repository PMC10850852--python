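"""Synthetic surgical-CHD cohorts with the statistical structure the
similarity method assumes.

The generator emulates a paediatric congenital-heart-surgery cohort: a
lesion label is drawn from a mixture whose proportions follow the common
surgical case mix (ASD+VSD ~35%, VSD ~32%, ASD ~26%, PFO ~3%, PDA ~3%,
other complex lesions ~2%); a latent *severity* score (standard normal
shifted by lesion) drives everything that should co-vary in real data —
echocardiographic indicator values, operative times, and outcomes.
Indicators are emitted only for lesions the patient actually has
(echo reports describe present malformations only), plus a small uniform
dropout.  Outcomes follow

    complication ~ Bernoulli( logistic(a + b * severity) )
    ln(ventilation hours) = c + d * severity + noise

with the intercepts ``a`` and ``c`` solved (by quadrature over the lesion
mixture, independent of any sample) so that the population complication
rate is ~25.7% and ~63% of patients fall in the shortest ventilation bin
(<12 h) — the marginal rates of the cohort being emulated.  ``b`` (default
2.0) and ``d`` (default 0.8) set the planted signal strength; ``b = d = 0``
produces the no-signal null in which neighbourhood methods cannot beat
chance.

Latent truth (severity, lesion, true probabilities) is returned separately
and is never read by the analysis pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, special, stats

from .feature_space import (
    IndicatorSchema,
    Outcome,
    PatientRecord,
    RatioPair,
)
from .io import write_cohort_csv, write_cohort_jsonl
from .ontology import (
    DiagnosisAssignment,
    Ontology,
    labels_to_tsv,
    load_ontology,
    ontology_to_tsv,
)

__all__ = [
    "SyntheticSpec",
    "LatentTruth",
    "generate_toy_ontology",
    "default_schema",
    "generate_cohort",
    "write_fixture",
]

# lesion mixture of the emulated surgical case mix
DEFAULT_MIXTURE = {
    "ASD+VSD": 0.348,
    "VSD": 0.319,
    "ASD": 0.257,
    "PFO": 0.028,
    "PDA": 0.026,
    "others": 0.022,
}

# lesion shift of the latent severity score (unit-variance noise on top)
SEVERITY_SHIFT = {
    "ASD+VSD": 0.5,
    "VSD": 0.2,
    "ASD": -0.2,
    "PFO": -0.8,
    "PDA": -0.5,
    "others": 1.5,
}

# indicator emission models: name -> (mean, sd, severity coefficient)
COMMON_INDICATORS = {
    "lvedd_mm": (28.0, 4.0, 2.0),
    "la_diameter_mm": (18.0, 3.0, 1.5),
    "aortic_annulus_mm": (11.0, 1.5, 0.5),
    "pa_diameter_mm": (12.0, 2.0, 1.0),
    "heart_rate_bpm": (115.0, 12.0, 4.0),
    "ef_pct": (66.0, 4.0, -2.0),
}
LESION_INDICATORS = {
    "VSD": {
        "vsd_diameter_mm": (6.0, 1.8, 1.2),
        "vsd_shunt_velocity_ms": (4.2, 0.6, -0.4),
        "vsd_pressure_gradient_mmhg": (70.0, 15.0, -8.0),
    },
    "ASD": {
        "asd_diameter_mm": (9.0, 3.0, 1.5),
        "asd_shunt_velocity_ms": (1.3, 0.3, 0.1),
    },
    "PFO": {
        "pfo_diameter_mm": (3.0, 0.8, 0.3),
    },
    "PDA": {
        "pda_diameter_mm": (3.5, 1.2, 0.8),
        "pda_shunt_velocity_ms": (4.0, 0.7, -0.3),
    },
    "others": {
        "rvot_gradient_mmhg": (55.0, 15.0, 10.0),
        "rv_wall_thickness_mm": (5.5, 1.2, 0.8),
    },
}

RATIO_PAIRS = [
    RatioPair("vsd_diameter_mm", "aortic_annulus_mm", "vsd_aorta_ratio"),
    RatioPair("asd_diameter_mm", "aortic_annulus_mm", "asd_aorta_ratio"),
    RatioPair("pda_diameter_mm", "pa_diameter_mm", "pda_pa_ratio"),
]

# which lesion indicator groups each mixture label switches on
LABEL_LESIONS = {
    "ASD+VSD": ("VSD", "ASD"),
    "VSD": ("VSD",),
    "ASD": ("ASD",),
    "PFO": ("PFO",),
    "PDA": ("PDA",),
    "others": ("others",),
}

VSD_SUBTYPES = ("VSD_perimembranous", "VSD_muscular", "VSD_subarterial")
ASD_SUBTYPES = ("ASD_secundum", "ASD_primum")
OTHER_LESION_TERMS = ("TOF", "TGA", "PS_valvular", "CoA")


@dataclass
class SyntheticSpec:
    """Parameters of the generated world.

    Defaults encode the emulated cohort: the lesion mixture and outcome
    marginals above, strong planted severity signal (b=2), ~5% uniform
    indicator dropout on top of the lesion-structured sparsity, and a
    default scale of 1000 patients.
    """

    n_patients: int = 1000
    seed: int = 0
    mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE))
    complication_rate: float = 0.257
    vent_under_12h_rate: float = 0.630
    signal_b: float = 2.0  # complication logit slope on severity
    signal_d: float = 0.8  # ln-ventilation slope on severity
    vent_noise_sd: float = 0.6
    missingness: float = 0.05
    secondary_dx_rate: float = 0.15
    subtype_rate: float = 0.30

    def __post_init__(self) -> None:
        total = sum(self.mixture.values())
        if not 0 < total <= 1.0 + 1e-9:
            raise ValueError(f"mixture prevalences sum to {total}")
        if any(p < 0 for p in self.mixture.values()):
            raise ValueError("negative prevalence")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class LatentTruth:
    """Per-patient generating state, kept apart from the emitted cohort."""

    patient_id: list[str]
    lesion: list[str]
    severity: np.ndarray
    p_complication: np.ndarray
    expected_ln_vent: np.ndarray


def generate_toy_ontology(seed: int = 0) -> Ontology:
    """A 3–4 level stand-in diagnosis hierarchy (~25 terms): root ->
    lesion families -> lesions -> subtypes.  The structure is fixed, hence
    trivially identical across seeds."""
    edges = [
        ("septal_defect", "CHD"),
        ("ductal_arterial", "CHD"),
        ("cyanotic_complex", "CHD"),
        ("obstructive", "CHD"),
        ("VSD", "septal_defect"),
        ("ASD", "septal_defect"),
        ("PFO", "septal_defect"),
        ("PDA", "ductal_arterial"),
        ("aortopulmonary_window", "ductal_arterial"),
        ("TOF", "cyanotic_complex"),
        ("TGA", "cyanotic_complex"),
        ("PS_valvular", "obstructive"),
        ("CoA", "obstructive"),
        ("VSD_perimembranous", "VSD"),
        ("VSD_muscular", "VSD"),
        ("VSD_subarterial", "VSD"),
        ("ASD_secundum", "ASD"),
        ("ASD_primum", "ASD"),
        ("PDA_tubular", "PDA"),
        ("PDA_window", "PDA"),
        ("TOF_classic", "TOF"),
        ("TGA_iv_septum_intact", "TGA"),
    ]
    labels = {
        "CHD": "congenital heart disease",
        "VSD": "ventricular septal defect",
        "ASD": "atrial septal defect",
        "PFO": "patent foramen ovale",
        "PDA": "patent ductus arteriosus",
        "TOF": "tetralogy of Fallot",
        "TGA": "transposition of the great arteries",
        "CoA": "coarctation of the aorta",
        "PS_valvular": "valvular pulmonary stenosis",
    }
    text = "\n".join(f"{c}\t{p}" for c, p in edges)
    return load_ontology(text, labels)


def default_schema() -> IndicatorSchema:
    """Schema with plausible ranges wide enough that values emitted at the
    default noise level are never filtered (range = mean +/- 8 sd + 6 |coef|)."""
    ranges = {}
    for models in (COMMON_INDICATORS, *LESION_INDICATORS.values()):
        for name, (mean, sd, coef) in models.items():
            half = 8.0 * sd + 6.0 * abs(coef)
            ranges[name] = (mean - half, mean + half)
    return IndicatorSchema(ranges=ranges, ratio_pairs=list(RATIO_PAIRS))


def _solve_complication_intercept(spec: SyntheticSpec) -> float:
    """a such that E[logistic(a + b*severity)] equals the target rate, by
    Gauss–Hermite quadrature over the lesion mixture (sample-free)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    probs = np.array(list(spec.mixture.values()))
    probs = probs / probs.sum()
    shifts = np.array([SEVERITY_SHIFT[l] for l in spec.mixture])

    def rate(a: float) -> float:
        total = 0.0
        for p, mu in zip(probs, shifts):
            sev = mu + nodes
            total += p * np.sum(weights * special.expit(a + spec.signal_b * sev))
        return total / np.sqrt(2 * np.pi)

    return float(optimize.brentq(lambda a: rate(a) - spec.complication_rate,
                                 -30.0, 30.0))


def _solve_vent_intercept(spec: SyntheticSpec) -> float:
    """c such that P(ventilation < 12 h) equals the target share: ln-vent
    is Gaussian given the lesion, so the mixture CDF is closed-form."""
    probs = np.array(list(spec.mixture.values()))
    probs = probs / probs.sum()
    shifts = np.array([SEVERITY_SHIFT[l] for l in spec.mixture])
    sd = float(np.hypot(spec.signal_d, spec.vent_noise_sd))

    def under12(c: float) -> float:
        z = (np.log(12.0) - c - spec.signal_d * shifts) / max(sd, 1e-9)
        return float(np.sum(probs * stats.norm.cdf(z)))

    if sd < 1e-9:  # no-signal, no-noise degenerate case
        return float(np.log(12.0) - 1e-6)
    return float(optimize.brentq(
        lambda c: under12(c) - spec.vent_under_12h_rate, -20.0, 20.0))


def _diagnoses_for(label: str, rng: np.random.Generator,
                   spec: SyntheticSpec) -> list[DiagnosisAssignment]:
    def lesion_term(lesion: str) -> str:
        if lesion == "VSD" and rng.random() < spec.subtype_rate:
            return VSD_SUBTYPES[rng.integers(len(VSD_SUBTYPES))]
        if lesion == "ASD" and rng.random() < spec.subtype_rate:
            return ASD_SUBTYPES[rng.integers(len(ASD_SUBTYPES))]
        return lesion

    if label == "ASD+VSD":
        diags = [DiagnosisAssignment(lesion_term("VSD"), True),
                 DiagnosisAssignment(lesion_term("ASD"), False)]
    elif label == "others":
        term = OTHER_LESION_TERMS[rng.integers(len(OTHER_LESION_TERMS))]
        diags = [DiagnosisAssignment(term, True)]
    else:
        diags = [DiagnosisAssignment(lesion_term(label), True)]
    present = {d.term_id.split("_")[0] for d in diags}
    if rng.random() < spec.secondary_dx_rate:
        extra = "PFO" if rng.random() < 0.5 else "PDA"
        if extra not in present:
            diags.append(DiagnosisAssignment(extra, False))
    return diags


def _lesions_present(diags: list[DiagnosisAssignment], label: str) -> set[str]:
    lesions = set(LABEL_LESIONS[label])
    for d in diags:
        base = d.term_id.split("_")[0]
        if base in LESION_INDICATORS:
            lesions.add(base)
    return lesions


def generate_cohort(
    spec: SyntheticSpec,
    onto: Ontology | None = None,
) -> tuple[list[PatientRecord], LatentTruth]:
    """Draw a cohort from the stated world; deterministic for a seed."""
    onto = onto or generate_toy_ontology(spec.seed)
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.mixture)
    probs = np.array([spec.mixture[l] for l in labels])
    probs = probs / probs.sum()
    a = _solve_complication_intercept(spec)
    c = _solve_vent_intercept(spec)

    cohort: list[PatientRecord] = []
    truth_rows = {"patient_id": [], "lesion": [], "severity": [],
                  "p_comp": [], "ln_vent": []}
    n = spec.n_patients
    width = len(str(n))
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        label = labels[rng.choice(len(labels), p=probs)]
        severity = SEVERITY_SHIFT[label] + rng.normal()
        diags = _diagnoses_for(label, rng, spec)
        for d in diags:
            assert d.term_id in onto, d.term_id

        # demographics anchored at the emulated cohort medians
        ln_age = np.log(12.0) + rng.normal(scale=1.2)
        age = float(np.exp(ln_age))
        height = float(75.0 * np.exp(0.25 * (ln_age - np.log(12.0))
                                     + rng.normal(scale=0.07)))
        weight = float(9.2 * np.exp(0.45 * (ln_age - np.log(12.0))
                                    + rng.normal(scale=0.15)))
        spo2 = float(np.clip(98.0 - 1.2 * max(severity, 0.0)
                             + rng.normal(), 70.0, 100.0))
        surgery = float(np.exp(np.log(119.0) + 0.18 * severity
                               + rng.normal(scale=0.25)))
        cpb = float(np.exp(np.log(60.0) + 0.25 * severity
                           + rng.normal(scale=0.28)))
        clamp = float(np.exp(np.log(40.0) + 0.25 * severity
                             + rng.normal(scale=0.32)))

        indicators: dict[str, float] = {}
        models = dict(COMMON_INDICATORS)
        for lesion in sorted(_lesions_present(diags, label)):
            models.update(LESION_INDICATORS[lesion])
        for name in sorted(models):
            mean, sd, coef = models[name]
            if rng.random() < spec.missingness:
                continue
            indicators[name] = float(mean + coef * severity
                                     + rng.normal(scale=sd))

        p_comp = float(special.expit(a + spec.signal_b * severity))
        complication = bool(rng.random() < p_comp)
        ln_vent = c + spec.signal_d * severity
        vent_hours = float(np.exp(ln_vent + rng.normal(scale=spec.vent_noise_sd)))
        icu = float(np.exp(np.log(3.0) + 0.35 * severity
                           + rng.normal(scale=0.5)))
        hosp = float(np.exp(np.log(9.0) + 0.25 * severity
                            + rng.normal(scale=0.35)))
        survived = bool(rng.random() > special.expit(-6.0 + severity))

        cohort.append(PatientRecord(
            patient_id=pid,
            sex="male" if rng.random() < 0.489 else "female",
            age_months=age, height_cm=height, weight_kg=weight,
            preop_spo2_pct=spo2, indicators=indicators, diagnoses=diags,
            surgery_min=surgery, cpb_min=cpb, clamp_min=clamp,
            outcome=Outcome(complication=complication,
                            ventilation_hours=vent_hours,
                            icu_los_days=icu, hospital_los_days=hosp,
                            survived=survived),
        ))
        truth_rows["patient_id"].append(pid)
        truth_rows["lesion"].append(label)
        truth_rows["severity"].append(severity)
        truth_rows["p_comp"].append(p_comp)
        truth_rows["ln_vent"].append(ln_vent)

    truth = LatentTruth(
        patient_id=truth_rows["patient_id"],
        lesion=truth_rows["lesion"],
        severity=np.array(truth_rows["severity"]),
        p_complication=np.array(truth_rows["p_comp"]),
        expected_ln_vent=np.array(truth_rows["ln_vent"]),
    )
    return cohort, truth


def write_fixture(
    cohort: list[PatientRecord],
    onto: Ontology,
    out_dir,
    spec: SyntheticSpec | None = None,
) -> dict[str, Path]:
    """Persist a cohort in the exact formats the readers consume: CSV,
    JSON-lines, ontology TSV (+labels), and an echo of the generating
    spec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort_csv": out_dir / "cohort.csv",
        "cohort_jsonl": out_dir / "cohort.jsonl",
        "ontology_tsv": out_dir / "ontology.tsv",
        "labels_tsv": out_dir / "labels.tsv",
    }
    write_cohort_csv(cohort, paths["cohort_csv"])
    write_cohort_jsonl(cohort, paths["cohort_jsonl"])
    paths["ontology_tsv"].write_text(ontology_to_tsv(onto))
    paths["labels_tsv"].write_text(labels_to_tsv(onto))
    if spec is not None:
        paths["spec_json"] = out_dir / "spec.json"
        payload = {k: v for k, v in spec.__dict__.items()}
        paths["spec_json"].write_text(json.dumps(payload, indent=2,
                                                 sort_keys=True) + "\n")
    return paths
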