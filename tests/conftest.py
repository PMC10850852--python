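import numpy as np
import pytest

from chdpsn import (
    DiagnosisAssignment,
    Outcome,
    PatientRecord,
    SyntheticSpec,
    default_schema,
    fit_pipeline,
    generate_cohort,
    generate_toy_ontology,
    load_ontology,
)

TOY_EDGES = "\n".join([
    "SeptalDefect\tCHD",
    "VSD\tSeptalDefect",
    "ASD\tSeptalDefect",
    "PDA\tCHD",
])


@pytest.fixture(scope="session")
def toy_onto():
    """CHD -> SeptalDefect -> {VSD, ASD}; PDA directly under the root.
    depth(CHD)=1, depth(SeptalDefect)=depth(PDA)=2, depth(VSD)=depth(ASD)=3."""
    return load_ontology(TOY_EDGES)


def make_record(pid, sex="male", age=12.0, height=75.0, weight=9.2,
                spo2=98.0, indicators=None, diagnoses=None, surgery=120.0,
                cpb=60.0, clamp=40.0, outcome="default"):
    if outcome == "default":
        outcome = Outcome(complication=False, ventilation_hours=6.0,
                          icu_los_days=2.0, hospital_los_days=8.0)
    return PatientRecord(
        patient_id=pid, sex=sex, age_months=age, height_cm=height,
        weight_kg=weight, preop_spo2_pct=spo2,
        indicators=dict(indicators or {}),
        diagnoses=list(diagnoses or [DiagnosisAssignment("VSD", True)]),
        surgery_min=surgery, cpb_min=cpb, clamp_min=clamp, outcome=outcome,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def syn_onto():
    return generate_toy_ontology(42)


@pytest.fixture(scope="session")
def syn_schema():
    return default_schema()


@pytest.fixture(scope="session")
def syn_world(syn_onto):
    """A 200-patient synthetic cohort with the default planted signal."""
    spec = SyntheticSpec(n_patients=200, seed=42)
    cohort, truth = generate_cohort(spec, syn_onto)
    return spec, cohort, truth


@pytest.fixture(scope="session")
def syn_state(syn_world, syn_onto, syn_schema):
    _, cohort, _ = syn_world
    return fit_pipeline(cohort, syn_onto, syn_schema,
                        method="origin", mode="ungrade")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
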