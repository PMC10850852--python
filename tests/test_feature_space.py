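"""Quality filtering, indicator preprocessing and the Gower-style
per-group distances."""

import math

import numpy as np
import pandas as pd
import pytest

from chdpsn import (
    CohortScaling,
    IndicatorSchema,
    IndicatorTransform,
    RatioPair,
    clinical_distance,
    indicator_distance,
    preprocess_indicators,
    range_filter,
    surgical_distance,
)
from chdpsn.errors import SchemaError, TransformError
from chdpsn.feature_space import gower_cross, gower_matrix
from tests.conftest import make_record

HR_SCHEMA = IndicatorSchema(ranges={"heart_rate_bpm": (0.0, 300.0),
                                    "lvedd_mm": (5.0, 80.0)})


class TestRangeFilter:
    def test_out_of_range_value_nulled_and_reported(self):
        rec = make_record("P1", indicators={"heart_rate_bpm": 9999.0})
        out, report = range_filter([rec], HR_SCHEMA, policy="null")
        assert "heart_rate_bpm" not in out[0].indicators
        assert len(report) == 1
        row = report.iloc[0]
        assert (row.patient_id, row.indicator, row.value) == ("P1", "heart_rate_bpm", 9999.0)

    def test_in_range_cohort_untouched(self):
        rec = make_record("P1", indicators={"heart_rate_bpm": 120.0})
        out, report = range_filter([rec], HR_SCHEMA)
        assert out[0].indicators == {"heart_rate_bpm": 120.0}
        assert report.empty

    def test_missing_value_is_not_out_of_range(self):
        out, report = range_filter([make_record("P1", indicators={})], HR_SCHEMA)
        assert report.empty and len(out) == 1

    def test_drop_policy_removes_record(self):
        recs = [make_record("P1", indicators={"heart_rate_bpm": -5.0}),
                make_record("P2", indicators={"heart_rate_bpm": 100.0})]
        out, report = range_filter(recs, HR_SCHEMA, policy="drop")
        assert [r.patient_id for r in out] == ["P2"]
        assert report.iloc[0].action == "record_dropped"

    def test_unknown_indicator_is_a_schema_error(self):
        rec = make_record("P1", indicators={"mystery": 1.0})
        with pytest.raises(SchemaError, match="mystery"):
            range_filter([rec], HR_SCHEMA)

    def test_schema_rejects_inverted_range(self):
        with pytest.raises(SchemaError):
            IndicatorSchema(ranges={"x": (10.0, 1.0)})


class TestPreprocessing:
    def cohort_with(self, values, name="lvedd_mm"):
        return [make_record(f"P{i}", indicators={name: v})
                for i, v in enumerate(values)]

    def test_zscore_sample_sd_convention(self):
        table, _ = preprocess_indicators(self.cohort_with([2.0, 4.0, 6.0]),
                                         HR_SCHEMA, "zscore")
        # sample sd of {2,4,6} is 2, so the value 6 maps to (6-4)/2 = 1
        assert table["lvedd_mm"].iloc[2] == pytest.approx(1.0)

    def test_zscore_columns_are_standardised(self):
        rng = np.random.default_rng(0)
        cohort = self.cohort_with(rng.normal(30, 5, size=40))
        table, _ = preprocess_indicators(cohort, HR_SCHEMA, "zscore")
        col = table["lvedd_mm"]
        assert col.mean() == pytest.approx(0.0, abs=1e-9)
        assert col.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_zscore_constant_column_rejected(self):
        with pytest.raises(TransformError, match="lvedd_mm"):
            preprocess_indicators(self.cohort_with([7.0, 7.0, 7.0]),
                                  HR_SCHEMA, "zscore")

    def test_origin_is_identity(self):
        cohort = self.cohort_with([2.0, 4.0])
        table, _ = preprocess_indicators(cohort, HR_SCHEMA, "origin")
        assert list(table["lvedd_mm"]) == [2.0, 4.0]

    def test_combination_ratio_column(self):
        schema = IndicatorSchema(
            ranges={"vsd_diameter_mm": (0.0, 30.0),
                    "aortic_annulus_mm": (0.0, 30.0)},
            ratio_pairs=[RatioPair("vsd_diameter_mm", "aortic_annulus_mm",
                                   "vsd_aorta_ratio")],
        )
        cohort = [make_record("P1", indicators={"vsd_diameter_mm": 5.0,
                                                "aortic_annulus_mm": 10.0})]
        table, _ = preprocess_indicators(cohort, schema, "combination")
        assert table["vsd_aorta_ratio"].iloc[0] == pytest.approx(0.5)

    def test_combination_zero_denominator_is_missing(self):
        schema = IndicatorSchema(
            ranges={"a": (0.0, 10.0), "b": (0.0, 10.0)},
            ratio_pairs=[RatioPair("a", "b", "ab")],
        )
        cohort = [make_record("P1", indicators={"a": 5.0, "b": 0.0})]
        table, _ = preprocess_indicators(cohort, schema, "combination")
        assert math.isnan(table["ab"].iloc[0])

    def test_index_patient_uses_training_statistics(self):
        train = self.cohort_with([2.0, 4.0, 6.0])
        tf = IndicatorTransform(HR_SCHEMA, "zscore").fit(train)
        # an unseen record is standardised with the training mean/sd (4, 2)
        new = make_record("Q", indicators={"lvedd_mm": 8.0})
        assert tf.transform(new)["lvedd_mm"].iloc[0] == pytest.approx(2.0)
        # applying to the training cohort twice is idempotent
        t1 = tf.transform(train)
        t2 = tf.transform(train)
        pd.testing.assert_frame_equal(t1, t2)


class TestIndicatorDistance:
    def test_identity(self):
        scaling = {"a": (0.0, 10.0)}
        assert indicator_distance({"a": 3.0}, {"a": 3.0}, scaling) == 0.0

    def test_single_shared_feature_hand_value(self):
        scaling = {"a": (0.0, 10.0)}
        assert indicator_distance({"a": 2.0}, {"a": 7.0}, scaling) == \
            pytest.approx(0.5)

    def test_disjoint_features_give_max_distance(self):
        scaling = {"a": (0.0, 1.0), "b": (0.0, 1.0)}
        assert indicator_distance({"a": 0.5}, {"b": 0.5}, scaling) == 1.0

    def test_zero_range_shared_feature(self):
        scaling = {"a": (5.0, 5.0)}
        assert indicator_distance({"a": 5.0}, {"a": 5.0}, scaling) == 0.0
        assert indicator_distance({"a": 5.0}, {"a": 6.0}, scaling) == 1.0

    def test_matches_brute_force_on_random_sparse_rows(self, rng):
        names = [f"f{i}" for i in range(20)]
        scaling = {n: (0.0, float(rng.uniform(0.5, 10))) for n in names}
        for _ in range(100):
            def draw():
                return {n: float(rng.uniform(-2, 12)) for n in names
                        if rng.random() < 0.4}
            x, y = draw(), draw()
            # independent per-feature loop
            shared = [n for n in names if n in x and n in y]
            if shared:
                expected = np.mean([
                    min(abs(x[n] - y[n]) / (scaling[n][1] - scaling[n][0]), 1.0)
                    for n in shared
                ])
            else:
                expected = 1.0
            got = indicator_distance(x, y, scaling)
            assert got == pytest.approx(expected)
            assert got == pytest.approx(indicator_distance(y, x, scaling))
            assert 0.0 <= got <= 1.0


class TestClinicalSurgicalDistance:
    def test_identical_records(self):
        a, b = make_record("A"), make_record("B")
        scaling = CohortScaling.fit([a, b, make_record("C", age=40.0)])
        assert clinical_distance(a, b, scaling) == 0.0
        assert surgical_distance(a, b, scaling) == 0.0

    def test_sex_only_difference_is_one_fifth(self):
        a = make_record("A", sex="male")
        b = make_record("B", sex="female")
        scaling = CohortScaling.fit([a, b, make_record("C", age=40.0)])
        assert clinical_distance(a, b, scaling) == pytest.approx(0.2)

    def test_opposite_extremes_and_sex_give_one(self):
        a = make_record("A", sex="male", age=1.0, height=50.0, weight=3.0,
                        spo2=70.0)
        b = make_record("B", sex="female", age=60.0, height=120.0,
                        weight=20.0, spo2=100.0)
        scaling = CohortScaling.fit([a, b])
        assert clinical_distance(a, b, scaling) == pytest.approx(1.0)

    def test_surgical_half_range_hand_value(self):
        a = make_record("A", surgery=100.0)
        b = make_record("B", surgery=150.0)
        c = make_record("C", surgery=200.0)  # range 100, diff(a,b)=50
        scaling = CohortScaling.fit([a, b, c])
        assert surgical_distance(a, b, scaling) == pytest.approx(1 / 6)

    def test_surgical_extremes(self):
        a = make_record("A", surgery=50.0, cpb=10.0, clamp=5.0)
        b = make_record("B", surgery=400.0, cpb=200.0, clamp=150.0)
        scaling = CohortScaling.fit([a, b])
        assert surgical_distance(a, b, scaling) == pytest.approx(1.0)


class TestVectorisedGower:
    def test_matrix_matches_scalar_double_loop(self, rng):
        n, p = 12, 6
        X = rng.uniform(0, 10, size=(n, p))
        X[rng.random((n, p)) < 0.35] = np.nan
        ranges = rng.uniform(0.5, 10, size=p)
        scaling = {f"c{j}": (0.0, float(ranges[j])) for j in range(p)}
        D = gower_matrix(X, ranges)
        for i in range(n):
            for j in range(n):
                xi = {f"c{k}": X[i, k] for k in range(p)}
                xj = {f"c{k}": X[j, k] for k in range(p)}
                expected = 0.0 if i == j else indicator_distance(xi, xj, scaling)
                assert D[i, j] == pytest.approx(expected)
        cross = gower_cross(X[0], X, ranges)
        for j in range(1, n):
            assert cross[j] == pytest.approx(D[0, j])
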