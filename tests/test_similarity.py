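"""Distance fusion, the pairwise matrix, and clinical-phase sub-maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chdpsn import (
    DiagnosisAssignment as DA,
    IndicatorSchema,
    WeightVector,
    build_distance_matrix,
    clinical_distance,
    diagnosis_list_distance,
    fuse_distances,
    indicator_distance,
    phase_submap,
    surgical_distance,
)
from chdpsn.errors import ConfigurationError, DataAvailabilityError
from chdpsn.feature_space import CohortScaling, IndicatorTransform
from tests.conftest import make_record

SCHEMA = IndicatorSchema(ranges={"lvedd_mm": (5.0, 80.0),
                                 "vsd_diameter_mm": (0.0, 30.0)})


def toy_cohort():
    return [
        make_record("P1", indicators={"lvedd_mm": 20.0, "vsd_diameter_mm": 4.0},
                    diagnoses=[DA("VSD", True)], age=6.0, surgery=90.0),
        make_record("P2", indicators={"lvedd_mm": 30.0},
                    diagnoses=[DA("ASD", True)], age=18.0, surgery=150.0,
                    sex="female"),
        make_record("P3", indicators={"vsd_diameter_mm": 8.0},
                    diagnoses=[DA("VSD", True), DA("PDA")], age=30.0,
                    surgery=120.0),
    ]


class TestFusion:
    def test_single_active_group_identity(self):
        w = WeightVector(1, 0, 0, 0)
        assert fuse_distances(0.3, None, None, None, w) == pytest.approx(0.3)

    def test_all_zero_components(self):
        assert fuse_distances(0, 0, 0, 0, WeightVector()) == 0.0

    def test_equal_weights_arithmetic_mean(self):
        w = WeightVector(0.25, 0.25, 0.25, 0.25)
        assert fuse_distances(0.2, 0.4, 0.6, 0.8, w) == pytest.approx(0.5)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            WeightVector(0, 0, 0, 0)

    def test_weight_on_missing_component_rejected(self):
        with pytest.raises(ConfigurationError):
            fuse_distances(None, 0.2, 0.3, 0.4, WeightVector())

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        d=st.tuples(*[st.floats(0, 1) for _ in range(4)]),
        w=st.tuples(*[st.floats(0, 5) for _ in range(4)]),
        scale=st.floats(0.01, 100),
        bump=st.floats(0.001, 1),
    )
    def test_scale_invariance_and_monotonicity(self, d, w, scale, bump):
        if all(x == 0 for x in w):
            w = (1.0, *w[1:])
        wv = WeightVector(*w)
        base = fuse_distances(*d, wv)
        assert 0.0 <= base <= 1.0
        scaled = fuse_distances(*d, WeightVector(*(x * scale for x in w)))
        assert scaled == pytest.approx(base, abs=1e-9)
        # increasing one positively weighted component never decreases it
        idx = next(i for i in range(4) if w[i] > 0)
        d2 = list(d)
        d2[idx] = min(1.0, d2[idx] + bump)
        assert fuse_distances(*d2, wv) >= base - 1e-12


class TestDistanceMatrix:
    def test_identical_patients_at_zero_distance(self, toy_onto):
        a = make_record("P1", indicators={"lvedd_mm": 20.0})
        b = make_record("P2", indicators={"lvedd_mm": 20.0})
        c = make_record("P3", age=40.0, surgery=200.0,
                        indicators={"lvedd_mm": 30.0})
        dm = build_distance_matrix([a, b, c], toy_onto, SCHEMA)
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matrix_invariants(self, toy_onto):
        dm = build_distance_matrix(toy_cohort(), toy_onto, SCHEMA,
                                   mode="grade")
        v = dm.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 0.0)
        assert v.min() >= 0.0 and v.max() <= 1.0
        assert set(dm.components) == {"indicator", "diag", "pre", "surg"}

    @pytest.mark.parametrize("mode", ["ungrade", "grade"])
    def test_matrix_equals_scalar_double_loop(self, toy_onto, mode):
        """Oracle: recompute every pair with the scalar per-group distance
        functions and the scalar fusion."""
        cohort = toy_cohort()
        w = WeightVector(2.0, 1.0, 0.5, 1.5)
        dm = build_distance_matrix(cohort, toy_onto, SCHEMA, method="origin",
                                   mode=mode, weights=w)
        tf = IndicatorTransform(SCHEMA, "origin").fit(cohort)
        table = tf.transform(cohort)
        scaling = CohortScaling.fit(cohort)
        for i, a in enumerate(cohort):
            for j, b in enumerate(cohort):
                if i == j:
                    continue
                expected = fuse_distances(
                    indicator_distance(table.iloc[i], table.iloc[j],
                                       tf.feature_ranges_),
                    diagnosis_list_distance(a.diagnoses, b.diagnoses,
                                            toy_onto, mode),
                    clinical_distance(a, b, scaling),
                    surgical_distance(a, b, scaling),
                    w,
                )
                assert dm.values[i, j] == pytest.approx(expected)

    def test_refuse_matches_rebuild(self, toy_onto):
        cohort = toy_cohort()
        dm = build_distance_matrix(cohort, toy_onto, SCHEMA)
        w2 = WeightVector(3.0, 1.0, 0.0, 1.0)
        direct = build_distance_matrix(cohort, toy_onto, SCHEMA, weights=w2)
        np.testing.assert_allclose(dm.refuse(w2).values, direct.values)

    def test_cohort_of_one_rejected(self, toy_onto):
        with pytest.raises(ValueError):
            build_distance_matrix([make_record("P1")], toy_onto, SCHEMA)


class TestPhaseSubmap:
    def test_screening_reduces_to_diagnosis_distance(self, toy_onto):
        dm = build_distance_matrix(toy_cohort(), toy_onto, SCHEMA)
        pm = phase_submap(dm, "screening")
        np.testing.assert_allclose(pm.matrix.values, dm.components["diag"])

    def test_surgery_with_equal_weights_is_identity(self, toy_onto):
        dm = build_distance_matrix(toy_cohort(), toy_onto, SCHEMA)
        pm = phase_submap(dm, "surgery")
        np.testing.assert_allclose(pm.matrix.values, dm.values)

    def test_echo_map_blind_to_surgical_times(self, toy_onto):
        """Two cohorts differing only in surgical durations: the echo map
        is identical, the surgery map is not."""
        base = toy_cohort()
        shifted = toy_cohort()
        shifted[0].surgery_min = 300.0
        dm1 = build_distance_matrix(base, toy_onto, SCHEMA)
        dm2 = build_distance_matrix(shifted, toy_onto, SCHEMA)
        echo1 = phase_submap(dm1, "echo").matrix.values
        echo2 = phase_submap(dm2, "echo").matrix.values
        np.testing.assert_allclose(echo1, echo2)
        assert not np.allclose(phase_submap(dm1, "surgery").matrix.values,
                               phase_submap(dm2, "surgery").matrix.values)

    def test_unknown_phase_rejected(self, toy_onto):
        dm = build_distance_matrix(toy_cohort(), toy_onto, SCHEMA)
        with pytest.raises(ConfigurationError):
            phase_submap(dm, "postop")

    def test_missing_component_is_availability_error(self, toy_onto):
        dm = build_distance_matrix(toy_cohort(), toy_onto, SCHEMA)
        del dm.components["indicator"]
        with pytest.raises(DataAvailabilityError):
            phase_submap(dm, "echo")


class TestPipelineState:
    def test_index_clone_has_zero_distance_to_original(self, syn_state):
        clone = syn_state.cohort[5]
        d = syn_state.distances_to(clone)
        assert d[5] == pytest.approx(0.0, abs=1e-12)
        assert d.min() >= 0.0 and d.max() <= 1.0

    def test_distances_match_matrix_row_for_training_patient(self, syn_state):
        # distances_to on a training record reproduces its matrix row
        i = 17
        d = syn_state.distances_to(syn_state.cohort[i])
        np.testing.assert_allclose(d, syn_state.matrix.values[i], atol=1e-9)
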