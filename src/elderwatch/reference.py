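"""Reference metric tables from the original case study.

The pipeline mirrors a published proof-of-concept whose evaluation is
reported as a grid of eight models (M1–M8), per-model hit rates and AUC,
confusion matrices for the four surviving models, and a final confusion
matrix obtained by applying the two selected alert rules to the full
initial dataset.  Those printed values are embedded here so that the
metric arithmetic of :mod:`elderwatch.evaluate` can be checked against
them cell by cell (``verify_tables``) and so the model-selection pattern
can be replayed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evaluate import ConfusionMatrix, ModelEvaluation, accuracy_error, hit_rates

#: Hit rates and AUC of the eight grid models, as published
#: (columns: hit rate of the no-alert class, hit rate of the alert class,
#: area under the ROC curve).
MODEL_EVALUATIONS: dict[str, tuple[float, float, float]] = {
    "M1": (0.98, 0.499, 0.551),
    "M2": (0.98, 0.499, 0.551),
    "M3": (0.858, 0.945, 0.814),
    "M4": (0.85, 0.955, 0.823),
    "M5": (0.983, 0.244, 0.254),
    "M6": (0.983, 0.244, 0.254),
    "M7": (0.989, 0.889, 0.881),
    "M8": (0.969, 1.0, 0.986),
}

#: Confusion matrices of the surviving models (alert = positive class).
CONFUSION_MATRICES: dict[str, ConfusionMatrix] = {
    "M3": ConfusionMatrix(tp=445, fn=26, fp=105, tn=634),
    "M4": ConfusionMatrix(tp=450, fn=21, fp=111, tn=628),
    "M7": ConfusionMatrix(tp=24, fn=3, fp=19, tn=1769),
    "M8": ConfusionMatrix(tp=27, fn=0, fp=56, tn=1732),
}

#: Correct/incorrect counts, error and accuracy for the surviving models.
MODEL_RESULTS: dict[str, tuple[int, int, float, float]] = {
    "M3": (1079, 131, 0.11, 0.89),
    "M4": (1078, 132, 0.11, 0.89),
    "M7": (1793, 22, 0.01, 0.99),
    "M8": (1759, 56, 0.03, 0.97),
}

#: Confusion matrix of the two final alert rules on the full initial dataset.
FINAL_RULES_CONFUSION = ConfusionMatrix(tp=615, fn=277, fp=621, tn=4537)

#: Reported headline figures for the final rules.
FINAL_RULES_RESULTS = {"correct": 5152, "incorrect": 898,
                       "accuracy": 0.85, "error_rate": 0.15}

#: Model ids expected to survive selection (low-AUC / low-hit-rate dropped).
EXPECTED_SELECTED = ("M3", "M4", "M7", "M8")


def reference_evaluations() -> list[ModelEvaluation]:
    """The published per-model metrics wrapped as ModelEvaluation objects
    (counts filled in where a confusion matrix is available)."""
    out = []
    for mid, (hit_false, hit_true, auc) in MODEL_EVALUATIONS.items():
        cm = CONFUSION_MATRICES.get(mid)
        if cm is not None:
            correct, incorrect, acc, err = accuracy_error(cm)
        else:
            correct = incorrect = 0
            acc = err = float("nan")
        out.append(
            ModelEvaluation(
                mid, cm.total if cm else 0, hit_false, hit_true, auc,
                correct, incorrect, err, acc, cm,
            )
        )
    return out


@dataclass(frozen=True)
class TableCheck:
    table: str
    cell: str
    expected: float
    computed: float

    @property
    def ok(self) -> bool:
        return abs(self.expected - self.computed) < 1e-9


def verify_tables() -> list[TableCheck]:
    """Recompute every derivable reference cell from the embedded
    confusion matrices and compare with the printed value.

    Hit rates are compared at 3 decimals, accuracy/error at 2, counts
    exactly — the precision the reference tables print.
    """
    checks: list[TableCheck] = []
    for mid, cm in CONFUSION_MATRICES.items():
        hit_true, hit_false = hit_rates(cm)
        exp_false, exp_true, _ = MODEL_EVALUATIONS[mid]
        checks.append(TableCheck("evaluations", f"{mid}.hit_rate_false",
                                 exp_false, round(hit_false, 3)))
        checks.append(TableCheck("evaluations", f"{mid}.hit_rate_true",
                                 exp_true, round(hit_true, 3)))
        correct, incorrect, acc, err = accuracy_error(cm)
        e_corr, e_inc, e_err, e_acc = MODEL_RESULTS[mid]
        checks.append(TableCheck("results", f"{mid}.correct", e_corr, correct))
        checks.append(TableCheck("results", f"{mid}.incorrect", e_inc, incorrect))
        checks.append(TableCheck("results", f"{mid}.error_rate", e_err, round(err, 2)))
        checks.append(TableCheck("results", f"{mid}.accuracy", e_acc, round(acc, 2)))

    correct, incorrect, acc, err = accuracy_error(FINAL_RULES_CONFUSION)
    checks.append(TableCheck("final_rules", "correct",
                             FINAL_RULES_RESULTS["correct"], correct))
    checks.append(TableCheck("final_rules", "incorrect",
                             FINAL_RULES_RESULTS["incorrect"], incorrect))
    checks.append(TableCheck("final_rules", "accuracy",
                             FINAL_RULES_RESULTS["accuracy"], round(acc, 2)))
    checks.append(TableCheck("final_rules", "error_rate",
                             FINAL_RULES_RESULTS["error_rate"], round(err, 2)))
    return checks
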