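"""Metric primitives, CV harness, model selection and final-rule testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from elderwatch.evaluate import (
    ConfusionMatrix,
    ExperimentPlan,
    ExperimentSuite,
    accuracy_error,
    confusion,
    evaluate_final_rules,
    hit_rates,
    initial_rule_frame,
    kfold_split,
    roc_auc,
    select_models,
)
from elderwatch.reference import (
    CONFUSION_MATRICES,
    EXPECTED_SELECTED,
    reference_evaluations,
    verify_tables,
)
from elderwatch.tree import FINAL_ALERT_RULES, Condition, Rule


class TestKFold:
    def test_equal_fold_sizes(self):
        folds = kfold_split(6050, k=10, seed=0)
        assert all(len(te) == 605 for _, te in folds)

    def test_partition_property(self):
        folds = kfold_split(103, k=10, seed=1)
        seen = np.concatenate([te for _, te in folds])
        assert sorted(seen) == list(range(103))
        for tr, te in folds:
            assert set(tr) | set(te) == set(range(103))
            assert not set(tr) & set(te)

    def test_seed_determinism(self):
        a = kfold_split(50, seed=9)
        b = kfold_split(50, seed=9)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert (tra == trb).all() and (tea == teb).all()

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            kfold_split(5, k=10)


class TestConfusion:
    def test_perfect_predictions(self):
        truth = [1] * 10 + [0] * 90
        cm = confusion(truth, truth)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (10, 0, 0, 90)

    def test_all_negative_predictions(self):
        cm = confusion([0] * 20, [1] * 5 + [0] * 15)
        assert cm.tp == 0 and cm.fp == 0 and cm.fn == 5 and cm.tn == 15

    def test_random_case_matches_hand_tally(self):
        rng = np.random.default_rng(2)
        p = rng.integers(0, 2, 30)
        t = rng.integers(0, 2, 30)
        cm = confusion(p, t)
        tally = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
        for pi, ti in zip(p, t):
            key = ("t" if pi == ti else "f") + ("p" if pi == 1 else "n")
            tally[key] += 1
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (
            tally["tp"], tally["fn"], tally["fp"], tally["tn"],
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])


class TestHitRatesAndAccuracy:
    def test_high_profile_model_rates(self):
        hit_true, hit_false = hit_rates(ConfusionMatrix(tp=24, fn=3, fp=19, tn=1769))
        assert round(hit_true, 3) == 0.889
        assert round(hit_false, 3) == 0.989

    def test_cost_variant_rates(self):
        hit_true, hit_false = hit_rates(ConfusionMatrix(tp=27, fn=0, fp=56, tn=1732))
        assert hit_true == 1.0
        assert round(hit_false, 3) == 0.969

    def test_perfect_matrix(self):
        assert hit_rates(ConfusionMatrix(5, 0, 0, 5)) == (1.0, 1.0)

    def test_empty_class_gives_missing(self):
        hit_true, hit_false = hit_rates(ConfusionMatrix(0, 0, 3, 7))
        assert hit_true is None and hit_false is not None

    def test_full_dataset_rule_matrix(self):
        correct, incorrect, acc, err = accuracy_error(
            ConfusionMatrix(tp=615, fn=277, fp=621, tn=4537)
        )
        assert (correct, incorrect) == (5152, 898)
        assert round(acc, 2) == 0.85 and round(err, 2) == 0.15

    def test_low_profile_matrix(self):
        correct, incorrect, acc, _ = accuracy_error(
            ConfusionMatrix(tp=445, fn=26, fp=105, tn=634)
        )
        assert (correct, incorrect) == (1079, 131)
        assert round(acc, 2) == 0.89

    def test_all_correct_negatives(self):
        _, _, acc, err = accuracy_error(ConfusionMatrix(0, 0, 0, 42))
        assert acc == 1.0 and err == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            accuracy_error(ConfusionMatrix(0, 0, 0, 0))


def _pairwise_auc(scores, truth):
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_constant_scores(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_missing(self):
        assert roc_auc([0.1, 0.9], [1, 1]) is None

    def test_six_point_example_matches_pairwise_oracle(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.35, 0.9]
        truth = [0, 0, 1, 1, 0, 1]
        assert roc_auc(scores, truth) == pytest.approx(_pairwise_auc(scores, truth))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_pairwise_oracle_and_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        truth = rng.integers(0, 2, n)
        if truth.min() == truth.max():
            truth[0] = 1 - truth[0]
        scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], n)
        auc = roc_auc(scores, truth)
        assert auc == pytest.approx(_pairwise_auc(scores, truth))
        assert auc == pytest.approx(1.0 - roc_auc(-scores, truth))


class TestModelSelection:
    def test_reference_pattern_reproduced(self):
        assert select_models(reference_evaluations()) == list(EXPECTED_SELECTED)

    def test_low_auc_dropped_high_kept(self):
        evs = reference_evaluations()
        by_id = {e.model_id: e for e in evs}
        assert by_id["M5"].auc == 0.254
        assert "M5" not in select_models(evs)
        assert by_id["M8"].auc == 0.986
        assert "M8" in select_models(evs)

    def test_empty_input(self):
        assert select_models([]) == []


class TestReferenceTables:
    def test_all_cells_reproduced_exactly(self):
        checks = verify_tables()
        assert checks and all(c.ok for c in checks)

    def test_corrupted_cell_detected(self, monkeypatch):
        import elderwatch.reference as ref

        broken = dict(CONFUSION_MATRICES)
        broken["M7"] = ConfusionMatrix(tp=25, fn=2, fp=19, tn=1769)
        monkeypatch.setattr(ref, "CONFUSION_MATRICES", broken)
        bad = [c for c in ref.verify_tables() if not c.ok]
        assert bad
        assert any("M7" in c.cell for c in bad)


class TestFinalRules:
    def test_rules_that_never_fire(self):
        df = pd.DataFrame(
            {"time_session_max": [10.0, 20.0], "age": [60.0, 65.0],
             "atmospheric_conditions": [0.0, 1.0], "is_alert": [0, 1]}
        )
        cm, _ = evaluate_final_rules(FINAL_ALERT_RULES, df)
        assert cm.tp == 0 and cm.fp == 0

    def test_ground_truth_rules_are_perfect(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "time_session_max": rng.choice([60, 150, 200], 300).astype(float),
                "age": rng.integers(55, 95, 300).astype(float),
                "atmospheric_conditions": rng.choice([0, 2, 4], 300).astype(float),
            }
        )
        from elderwatch.tree import classify_with_rules

        df["is_alert"] = classify_with_rules(FINAL_ALERT_RULES, df)
        _, report = evaluate_final_rules(FINAL_ALERT_RULES, df)
        assert report["accuracy"] == 1.0

    def test_schema_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lacks columns"):
            evaluate_final_rules(FINAL_ALERT_RULES, pd.DataFrame({"is_alert": [0]}))

    def test_column_totals_invariant_across_classifiers(self, sim_bundle):
        frame = initial_rule_frame(sim_bundle["corrupted"])
        cm_rules, _ = evaluate_final_rules(FINAL_ALERT_RULES, frame)
        always_no = [Rule((Condition("age", ">=", 1000.0),), True)]
        cm_none, _ = evaluate_final_rules(always_no, frame)
        assert cm_rules.tp + cm_rules.fn == cm_none.tp + cm_none.fn
        assert cm_rules.fp + cm_rules.tn == cm_none.fp + cm_none.tn


@pytest.fixture(scope="module")
def small_suite_results(sim_bundle):
    prepared = sim_bundle["prepared"].sample(n=900, random_state=0).reset_index(drop=True)
    plan = [ExperimentPlan("A1", "all", False), ExperimentPlan("A2", "all", True)]
    suite = ExperimentSuite(prepared, plan=plan, k=5)
    return suite, suite.run(seed=11)


class TestExperimentSuite:
    def test_one_evaluation_and_rule_set_per_plan_row(self, small_suite_results):
        _, res = small_suite_results
        assert [e.model_id for e in res.evaluations] == ["A1", "A2"]
        assert set(res.rule_sets) == {"A1", "A2"}
        assert all(res.rule_sets.values())

    def test_pooled_counts_sum_to_subset_size(self, small_suite_results):
        _, res = small_suite_results
        for ev in res.evaluations:
            assert ev.correct + ev.incorrect == ev.n_records == 900

    def test_deterministic_given_seed(self, small_suite_results):
        suite, res = small_suite_results
        res2 = suite.run(seed=11)
        for a, b in zip(res.evaluations, res2.evaluations):
            assert a.__dict__ == b.__dict__

    def test_cost_matrix_raises_alert_recall(self, small_suite_results):
        _, res = small_suite_results
        plain, costed = res.evaluations
        assert costed.hit_rate_true >= plain.hit_rate_true

    def test_empty_subset_reported_missing(self, sim_bundle):
        prepared = sim_bundle["prepared"][sim_bundle["prepared"]["profile"] == "low"]
        plan = [ExperimentPlan("X", "high", False)]
        res = ExperimentSuite(prepared.reset_index(drop=True), plan=plan).run(seed=0)
        ev = res.evaluations[0]
        assert ev.auc is None and "too small" in ev.notes

    def test_report_frames_shapes(self, small_suite_results):
        _, res = small_suite_results
        assert list(res.evaluation_frame().columns) == [
            "model", "hit_rate_false", "hit_rate_true", "auc",
        ]
        assert list(res.results_frame().columns) == [
            "model", "correct", "incorrect", "error_rate", "accuracy",
        ]
        cmf = res.confusion_frame(["A1"])
        assert len(cmf) == 2
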