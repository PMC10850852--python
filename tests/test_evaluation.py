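"""Metrics, AUC, k selection, benchmark grid and group-contrast tests."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from chdpsn import (
    ConfusionCounts,
    Outcome,
    auc_multiclass,
    auc_score,
    confusion_metrics,
    group_outcome_tests,
    optimize_k,
    run_benchmark,
)
from chdpsn.errors import EvaluationError, LeakageError
from chdpsn.evaluation import DEFAULT_K_GRID, binary_report, multiclass_report


class TestConfusionMetrics:
    def test_hand_computed_example(self):
        rep = confusion_metrics(ConfusionCounts(tp=3, tn=4, fp=2, fn=1))
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.recall == pytest.approx(0.75)
        assert rep.precision == pytest.approx(0.6)
        assert rep.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_perfect_classifier(self):
        rep = confusion_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (rep.accuracy, rep.recall, rep.precision, rep.f1) == (1, 1, 1, 1)

    def test_undefined_recall_is_flagged_not_zero(self):
        rep = confusion_metrics(ConfusionCounts(tp=0, tn=4, fp=2, fn=0))
        assert rep.recall is None
        assert "recall" in rep.undefined

    def test_empty_counts_rejected(self):
        with pytest.raises(EvaluationError):
            confusion_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_formulas_against_independent_reimplementation(self, rng):
        """Property check of the four ratio formulas on random counts."""
        for _ in range(200):
            tp, tn, fp, fn = (int(x) for x in rng.integers(0, 20, size=4))
            if tp + tn + fp + fn == 0 or tp + fn == 0 or tp + fp == 0:
                continue
            rep = confusion_metrics(ConfusionCounts(tp, tn, fp, fn))
            assert rep.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn))
            assert rep.recall == pytest.approx(tp / (tp + fn))
            assert rep.precision == pytest.approx(tp / (tp + fp))
            if rep.recall + rep.precision > 0:
                assert rep.f1 == pytest.approx(
                    2 * rep.recall * rep.precision / (rep.recall + rep.precision))


def brute_force_auc(scores, labels):
    """All positive/negative pairs, half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc_score([0.1, 0.2, 0.8, 0.9], [False, False, True, True]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_score([0.5] * 6, [True, False] * 3) == 0.5

    def test_hand_example(self):
        got = auc_score([0.1, 0.4, 0.35, 0.8], [False, False, True, True])
        assert got == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            auc_score([0.1, 0.2], [True, True])

    def test_matches_brute_force_and_sklearn(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 1)  # coarse grid -> many ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            got = auc_score(scores, labels)
            assert got == pytest.approx(brute_force_auc(scores, labels))
            assert got == pytest.approx(roc_auc_score(labels, scores))

    def test_multiclass_macro_over_defined_classes(self):
        labels = ["I", "I", "II", "II"]
        table = pd.DataFrame({
            "I": [0.9, 0.8, 0.1, 0.2],
            "II": [0.1, 0.2, 0.9, 0.8],
            "III": [0.0, 0.0, 0.0, 0.0],
            "IV": [0.0, 0.0, 0.0, 0.0],
        })
        macro, per_class = auc_multiclass(table, labels)
        assert per_class["I"] == 1.0 and per_class["II"] == 1.0
        assert per_class["III"] is None and per_class["IV"] is None
        assert macro == 1.0


class TestOptimizeK:
    def test_singleton_grid(self, syn_state):
        assert optimize_k(syn_state, "complication", k_grid=(1,)) == 1

    def test_grid_clipped_to_cohort(self, syn_state):
        k = optimize_k(syn_state, "complication", k_grid=DEFAULT_K_GRID)
        assert 1 <= k <= len(syn_state.ids) - 1

    def test_tie_goes_to_smallest_k(self, syn_state):
        k10 = optimize_k(syn_state, "complication", k_grid=(10, 10, 10))
        assert k10 == 10

    def test_multiclass_and_auc_metric(self, syn_state):
        k = optimize_k(syn_state, "ventilation_class", k_grid=(5, 20))
        assert k in (5, 20)
        k_auc = optimize_k(syn_state, "complication", k_grid=(5, 20),
                           metric="auc")
        assert k_auc in (5, 20)

    def test_unknown_metric_rejected(self, syn_state):
        with pytest.raises(ValueError):
            optimize_k(syn_state, "complication", metric="brier")


@pytest.fixture(scope="module")
def bench(syn_onto, syn_schema):
    from chdpsn import SyntheticSpec, generate_cohort
    train, _ = generate_cohort(SyntheticSpec(n_patients=120, seed=7),
                               syn_onto)
    test, _ = generate_cohort(SyntheticSpec(n_patients=40, seed=10007),
                              syn_onto)
    for r in test:
        r.patient_id = "T" + r.patient_id
    table = run_benchmark(train, test, syn_onto, syn_schema,
                          k_grid=(5, 10, 20), seed=3)
    return train, test, table


class TestBenchmark:
    def test_grid_cardinality_matches_protocol(self, bench):
        _, _, table = bench
        # 6 KNN + 6 KNN+LR + 1 k-Random+LR rows per task
        assert len(table) == 26
        counts = table.groupby(["task", "family"]).size()
        for task in ("complication", "ventilation_class"):
            assert counts[(task, "KNN")] == 6
            assert counts[(task, "KNN+LR")] == 6
            assert counts[(task, "k-Random+LR")] == 1

    def test_metric_columns_in_range(self, bench):
        _, _, table = bench
        for col in ("accuracy", "recall", "precision", "f1", "auc"):
            vals = table[col].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()

    def test_overlapping_cohorts_rejected(self, bench, syn_onto, syn_schema):
        train, _, _ = bench
        with pytest.raises(LeakageError):
            run_benchmark(train, train[:5], syn_onto, syn_schema)

    def test_reproducible_under_fixed_seed(self, bench, syn_onto, syn_schema):
        train, test, table = bench
        again = run_benchmark(train, test, syn_onto, syn_schema,
                              k_grid=(5, 10, 20), seed=3)
        pd.testing.assert_frame_equal(table, again)


def outcomes(values, complication=False):
    return [Outcome(complication=complication, ventilation_hours=v,
                    icu_los_days=v, hospital_los_days=v) for v in values]


class TestGroupOutcomeTests:
    def test_exact_mann_whitney_hand_case(self):
        res = group_outcome_tests(outcomes([1, 2, 3]), outcomes([4, 5, 6]))
        vent = res["ventilation_hours"]
        assert vent.statistic == 0.0
        assert vent.p_value == pytest.approx(0.1)  # 2/20 rank assignments
        assert vent.significant is False

    def test_identical_distributions_not_significant(self):
        res = group_outcome_tests(outcomes([1, 2, 3, 4] * 5),
                                  outcomes([1, 2, 3, 4] * 5))
        assert res["ventilation_hours"].significant is False

    def test_chi_square_hand_case(self):
        members = outcomes([1] * 10, complication=True)
        others = outcomes([1] * 10, complication=False)
        res = group_outcome_tests(members, others)
        comp = res["complication"]
        assert comp.statistic == pytest.approx(20.0)
        assert comp.significant is True

    def test_degenerate_outcomes_flagged(self):
        res = group_outcome_tests(outcomes([2, 2]), outcomes([2, 2]))
        assert res["ventilation_hours"].p_value is None
        assert res["ventilation_hours"].reason
        # nobody has a complication anywhere -> chi2 margin is zero
        assert res["complication"].p_value is None
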