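"""Evaluation harness: k-fold CV, hit rates, ROC AUC, the 8-model grid.

The experiment grid crosses three record subsets (all records, plus each
clustered usage profile) with and without a false-negative-averse cost
matrix, giving eight models M1–M8.  Each is assessed by seeded 10-fold
cross-validation: per-class hit rates (recall), accuracy/error, and the
area under the ROC curve, averaged over folds; confusion counts are pooled
over folds so they sum to the subset size.  After CV each model is refitted
on its full subset and its conjunctive rules extracted.

Alert is the positive class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .tree import (
    CostMatrix,
    DecisionTreeModel,
    DecisionTreeResults,
    Rule,
    classify_with_rules,
)

#: Default false-negative-averse costs: a missed alert costs five times a
#: false alarm.
DEFAULT_COST = CostMatrix(fn=5.0, fp=1.0)

#: Attributes the trees induce over (prepared-table columns minus target).
DEFAULT_TREE_FEATURES = [
    "age",
    "age_band",
    "marital_status",
    "num_accesses",
    "num_accesses_holidays_weekends",
    "num_accesses_morning",
    "time_session_max",
    "time_session_max_band",
    "time_session_min_band",
    "time_offline_max_band",
    "time_offline_min_band",
    "atmospheric_conditions",
    "profile_code",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with alert as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fn + other.fn,
            self.fp + other.fp, self.tn + other.tn,
        )


@dataclass(frozen=True)
class ExperimentPlan:
    """One experiment-grid row: which records, and whether costs apply."""

    model_id: str
    subset: str          # 'all' | 'low' | 'average' | 'high'
    cost_matrix: bool


DEFAULT_PLAN: tuple[ExperimentPlan, ...] = (
    ExperimentPlan("M1", "all", False),
    ExperimentPlan("M2", "all", True),
    ExperimentPlan("M3", "low", False),
    ExperimentPlan("M4", "low", True),
    ExperimentPlan("M5", "average", False),
    ExperimentPlan("M6", "average", True),
    ExperimentPlan("M7", "high", False),
    ExperimentPlan("M8", "high", True),
)


@dataclass
class ModelEvaluation:
    """CV evaluation of one grid model (hit rates/accuracy/AUC are fold
    means; counts are pooled over folds)."""

    model_id: str
    n_records: int
    hit_rate_false: float | None
    hit_rate_true: float | None
    auc: float | None
    correct: int
    incorrect: int
    error_rate: float
    accuracy: float
    confusion: ConfusionMatrix | None = None
    notes: str = ""


# --------------------------------------------------------------------------
# metric primitives
# --------------------------------------------------------------------------


def kfold_split(
    n_or_records, k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded random partition into k folds (sizes differ by at most one)."""
    n = n_or_records if isinstance(n_or_records, (int, np.integer)) else len(n_or_records)
    if n < k:
        raise ValueError(f"need at least k={k} records, got {n}")
    kf = KFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    return [(tr, te) for tr, te in kf.split(np.arange(n))]


def confusion(preds: Iterable[int], truth: Iterable[int]) -> ConfusionMatrix:
    p = np.asarray(list(preds), dtype=int)
    t = np.asarray(list(truth), dtype=int)
    if p.shape != t.shape:
        raise ValueError("predictions and truth must have equal length")
    return ConfusionMatrix(
        tp=int(((p == 1) & (t == 1)).sum()),
        fn=int(((p == 0) & (t == 1)).sum()),
        fp=int(((p == 1) & (t == 0)).sum()),
        tn=int(((p == 0) & (t == 0)).sum()),
    )


def hit_rates(cm: ConfusionMatrix) -> tuple[float | None, float | None]:
    """(hit rate of the alert class, hit rate of the no-alert class).

    Per-class recall; an empty class yields None rather than an error.
    """
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp
    hit_true = cm.tp / pos if pos else None
    hit_false = cm.tn / neg if neg else None
    return hit_true, hit_false


def accuracy_error(cm: ConfusionMatrix) -> tuple[int, int, float, float]:
    """(correct, incorrect, accuracy, error rate)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    correct = cm.tp + cm.tn
    incorrect = cm.fn + cm.fp
    acc = correct / cm.total
    return correct, incorrect, acc, 1.0 - acc


def roc_auc(scores: Iterable[float], truth: Iterable[int]) -> float | None:
    """AUC = P(random alert outscores random non-alert), ties counting 1/2.

    Returns None when only one class is present.
    """
    t = np.asarray(list(truth), dtype=int)
    s = np.asarray(list(scores), dtype=float)
    if len(set(t.tolist())) < 2:
        return None
    return float(roc_auc_score(t, s))


def select_models(
    evaluations: Sequence[ModelEvaluation],
    auc_floor: float = 0.6,
    hit_floor: float = 0.6,
) -> list[str]:
    """Drop models with small AUC or poor alert hit rate; keep the rest."""
    keep = []
    for ev in evaluations:
        if ev.auc is None or ev.auc <= auc_floor:
            continue
        if ev.hit_rate_true is None or ev.hit_rate_true <= hit_floor:
            continue
        keep.append(ev.model_id)
    return keep


def evaluate_final_rules(
    rules: Sequence[Rule], dataset: pd.DataFrame, target: str = "is_alert"
) -> tuple[ConfusionMatrix, dict]:
    """Apply a rule set to every record of the full dataset (single pass).

    Returns the confusion matrix and a report dict with correct/incorrect
    counts, accuracy and error rate.
    """
    needed = {c.attr for r in rules for c in r.conditions} | {target}
    missing = needed - set(dataset.columns)
    if missing:
        raise ValueError(f"dataset lacks columns required by the rules: {sorted(missing)}")
    preds = classify_with_rules(rules, dataset)
    cm = confusion(preds, dataset[target].astype(int))
    correct, incorrect, acc, err = accuracy_error(cm)
    return cm, {
        "correct": correct,
        "incorrect": incorrect,
        "accuracy": acc,
        "error_rate": err,
    }


# --------------------------------------------------------------------------
# experiment suite (Model/Results pair)
# --------------------------------------------------------------------------


class ExperimentSuite:
    """The 8-model experiment grid over a prepared dataset.

    Parameters
    ----------
    prepared : DataFrame
        Prepared modelling table with ``profile`` and ``is_alert`` columns.
    plan : sequence of ExperimentPlan
        Grid rows; defaults to the canonical M1–M8 grid.
    cost_matrix : CostMatrix
        Costs applied where the plan says so (default FN=5, FP=1).
    k : int
        Number of CV folds.
    """

    def __init__(
        self,
        prepared: pd.DataFrame,
        plan: Sequence[ExperimentPlan] = DEFAULT_PLAN,
        cost_matrix: CostMatrix = DEFAULT_COST,
        features: Sequence[str] | None = None,
        target: str = "is_alert",
        k: int = 10,
    ):
        self.prepared = prepared.reset_index(drop=True)
        self.plan = list(plan)
        self.cost_matrix = cost_matrix
        self.target = target
        self.k = k
        if features is None:
            features = [c for c in DEFAULT_TREE_FEATURES if c in prepared.columns]
        self.features = list(features)

    def _subset(self, name: str) -> pd.DataFrame:
        if name == "all":
            return self.prepared
        return self.prepared[self.prepared["profile"] == name].reset_index(drop=True)

    def run(self, seed: int = 0, pooled_rates: bool = False) -> "SuiteResults":
        """Run CV for every plan row, then refit on the full subset.

        With ``pooled_rates`` the rates are recomputed from the pooled
        confusion counts instead of averaged over folds.
        """
        evaluations: list[ModelEvaluation] = []
        rule_sets: dict[str, list[Rule]] = {}
        full_fits: dict[str, DecisionTreeResults] = {}

        for plan in self.plan:
            data = self._subset(plan.subset)
            cost = self.cost_matrix if plan.cost_matrix else CostMatrix.unit()
            if len(data) < self.k:
                evaluations.append(
                    ModelEvaluation(
                        plan.model_id, len(data), None, None, None, 0, 0,
                        float("nan"), float("nan"),
                        notes=f"subset {plan.subset!r} too small for {self.k}-fold CV",
                    )
                )
                continue
            # one seed for every grid row: models over the same subset are
            # compared on identical fold partitions
            y = data[self.target].astype(int).to_numpy()
            folds = kfold_split(len(data), k=self.k, seed=seed)
            cms: list[ConfusionMatrix] = []
            fold_ht, fold_hf, fold_acc, fold_auc = [], [], [], []
            for tr, te in folds:
                fit = DecisionTreeModel(
                    data.iloc[tr],
                    target=self.target,
                    features=self.features,
                    cost_matrix=cost,
                ).fit()
                labels, scores = fit.predict(data.iloc[te])
                cm = confusion(labels, y[te])
                cms.append(cm)
                ht, hf = hit_rates(cm)
                if ht is not None:
                    fold_ht.append(ht)
                if hf is not None:
                    fold_hf.append(hf)
                fold_acc.append(accuracy_error(cm)[2])
                auc = roc_auc(scores, y[te])
                if auc is not None:
                    fold_auc.append(auc)
            pooled = sum(cms[1:], cms[0])
            correct, incorrect, pooled_acc, _ = accuracy_error(pooled)
            if pooled_rates:
                ht, hf = hit_rates(pooled)
                acc = pooled_acc
            else:
                ht = float(np.mean(fold_ht)) if fold_ht else None
                hf = float(np.mean(fold_hf)) if fold_hf else None
                acc = float(np.mean(fold_acc))
            auc = float(np.mean(fold_auc)) if fold_auc else None
            evaluations.append(
                ModelEvaluation(
                    plan.model_id, len(data), hf, ht, auc,
                    correct, incorrect, 1.0 - acc, acc, pooled,
                    notes="" if fold_auc else "AUC undefined (single-class folds)",
                )
            )
            full = DecisionTreeModel(
                data, target=self.target, features=self.features, cost_matrix=cost
            ).fit()
            full_fits[plan.model_id] = full
            rule_sets[plan.model_id] = full.rules()

        return SuiteResults(self, evaluations, rule_sets, full_fits, seed)


class SuiteResults:
    """Results of the experiment grid: evaluations, rules, report tables."""

    def __init__(self, suite, evaluations, rule_sets, full_fits, seed):
        self.suite = suite
        self.evaluations: list[ModelEvaluation] = evaluations
        self.rule_sets: dict[str, list[Rule]] = rule_sets
        self.full_fits: dict[str, DecisionTreeResults] = full_fits
        self.seed = seed

    def select(self, auc_floor: float = 0.6, hit_floor: float = 0.6) -> list[str]:
        return select_models(self.evaluations, auc_floor, hit_floor)

    # -- report frames (3-decimal rates, 2-decimal accuracy) --------------

    def plan_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [p.model_id for p in self.suite.plan],
                "records": [
                    "All records" if p.subset == "all" else f"{p.subset.capitalize()} usage profile"
                    for p in self.suite.plan
                ],
                "cost_matrix": ["Yes" if p.cost_matrix else "No" for p in self.suite.plan],
            }
        )

    def evaluation_frame(self) -> pd.DataFrame:
        rows = []
        for ev in self.evaluations:
            rows.append(
                {
                    "model": ev.model_id,
                    "hit_rate_false": None if ev.hit_rate_false is None else round(ev.hit_rate_false, 3),
                    "hit_rate_true": None if ev.hit_rate_true is None else round(ev.hit_rate_true, 3),
                    "auc": None if ev.auc is None else round(ev.auc, 3),
                }
            )
        return pd.DataFrame(rows)

    def confusion_frame(self, model_ids: Sequence[str] | None = None) -> pd.DataFrame:
        rows = []
        for ev in self.evaluations:
            if model_ids is not None and ev.model_id not in model_ids:
                continue
            if ev.confusion is None:
                continue
            cm = ev.confusion
            rows.append({"model": ev.model_id, "actual": "true",
                         "predicted_true": cm.tp, "predicted_false": cm.fn})
            rows.append({"model": ev.model_id, "actual": "false",
                         "predicted_true": cm.fp, "predicted_false": cm.tn})
        return pd.DataFrame(rows)

    def results_frame(self) -> pd.DataFrame:
        rows = []
        for ev in self.evaluations:
            rows.append(
                {
                    "model": ev.model_id,
                    "correct": ev.correct,
                    "incorrect": ev.incorrect,
                    "error_rate": round(ev.error_rate, 2),
                    "accuracy": round(ev.accuracy, 2),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Experiment suite results",
            "=" * 64,
            f"{self.suite.k}-fold CV, seed {self.seed}; "
            f"cost matrix FN={self.suite.cost_matrix.fn:g} FP={self.suite.cost_matrix.fp:g}",
            "",
            self.evaluation_frame().to_string(index=False),
            "",
            self.results_frame().to_string(index=False),
            "",
            f"Selected models: {', '.join(self.select()) or '(none)'}",
        ]
        return "\n".join(lines)

    def plot_roc(self, model_id: str, ax=None):
        """Single full-fit ROC curve for one grid model (matplotlib)."""
        import matplotlib.pyplot as plt
        from sklearn.metrics import roc_curve

        fit = self.full_fits[model_id]
        data = self.suite._subset(
            next(p.subset for p in self.suite.plan if p.model_id == model_id)
        )
        _, scores = fit.predict(data)
        y = data[self.suite.target].astype(int)
        fpr, tpr, _ = roc_curve(y, scores)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(fpr, tpr, label=model_id)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate (alert hit rate)")
        ax.legend()
        return ax


def initial_rule_frame(initial: pd.DataFrame) -> pd.DataFrame:
    """Columns needed to test the final alert rules on the full initial
    dataset: raw session maximum and age, plus the atmospheric-conditions
    score derived after sentinel cleaning."""
    from .features import clean_outliers, derive_atmospheric_conditions

    cleaned = clean_outliers(initial)
    return pd.DataFrame(
        {
            "time_session_max": cleaned["time_session_max"].astype(float),
            "age": cleaned["age"].astype(float),
            "atmospheric_conditions": derive_atmospheric_conditions(
                cleaned["temperature_max"], cleaned["condition"]
            ),
            "is_alert": cleaned["is_alert"].astype(int),
        }
    )


def run_experiment_suite(
    prepared_records: pd.DataFrame,
    plan: Sequence[ExperimentPlan] = DEFAULT_PLAN,
    seed: int = 0,
    **kwargs,
) -> SuiteResults:
    """Functional wrapper over :class:`ExperimentSuite`."""
    return ExperimentSuite(prepared_records, plan=plan, **kwargs).run(seed=seed)
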