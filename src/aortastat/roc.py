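"""ROC analysis of EAT parameters as predictors of dichotomized aortic
mechanical status.

The outcome is the cohort's own median split of an aortic index: "stiff"
(stiffness index >= median) or "inelastic" (strain or distensibility <
median). A positive call is ``score >= threshold``, matching the ">= cutoff"
reporting convention. The operating point defaults to the accuracy-maximal
threshold; Youden's J is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics

from .analysis import AO_VARIABLES, EAT_VARIABLES, median_split
from .errors import DomainError

OPERATING_CRITERIA = ("max_accuracy", "youden")

#: Outcome direction per aortic variable: the "adverse" side of the median.
DEFAULT_OUTCOME_DIRECTIONS = {
    "ao_stiffness_index": "ge_median",
    "ao_strain": "lt_median",
    "ao_distensibility": "lt_median",
}


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass(frozen=True)
class RocCurve:
    """ROC curve points plus the raw scores/labels they came from."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # descending; first entry is the +inf sentinel
    auc: float
    scores: np.ndarray
    labels: np.ndarray


@dataclass(frozen=True)
class RocResult:
    predictor: str
    outcome_variable: str
    outcome_direction: str
    outcome_median: float
    curve: RocCurve
    operating_point: OperatingPoint


def dichotomize_outcome(values, direction: str) -> tuple[np.ndarray, float]:
    """Binary outcome labels relative to the sample median.

    ``ge_median``: label 1 where value >= median (e.g. high stiffness);
    ``lt_median``: label 1 where value < median (e.g. low strain).
    Returns (labels, median). Raises on a degenerate split.
    """
    if direction not in ("ge_median", "lt_median"):
        raise ValueError("direction must be 'ge_median' or 'lt_median'")
    values = np.asarray(values, float)
    ge, lt, med = median_split(values)  # raises DegenerateSplitError if one-sided
    labels = values >= med if direction == "ge_median" else values < med
    return labels.astype(int), med


def roc_curve(scores, labels) -> RocCurve:
    """Full ROC curve (no point dropping) with trapezoidal AUC.

    Thresholds are the descending unique scores preceded by an infinite
    sentinel; a positive call is score >= threshold, so the curve runs from
    (0, 0) to (1, 1).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise DomainError("ROC undefined: only one class present in labels")
    fpr, tpr, thr = metrics.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc, scores=scores, labels=labels)


def _confusion_at(scores: np.ndarray, labels: np.ndarray, threshold: float):
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tp, fp, tn, fn


def select_operating_point(curve: RocCurve, criterion: str = "max_accuracy") -> OperatingPoint:
    """Pick the threshold optimizing the criterion; ties go to the smallest
    (most sensitive) threshold. The infinite sentinel competes as the
    'call nothing positive' rule."""
    if criterion not in OPERATING_CRITERIA:
        raise ValueError(f"criterion must be one of {OPERATING_CRITERIA}")
    best = None
    # thresholds descend; iterate ascending so ties keep the smallest
    for t in curve.thresholds[::-1]:
        tp, fp, tn, fn = _confusion_at(curve.scores, curve.labels, t)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        acc = (tp + tn) / (tp + fp + tn + fn)
        value = acc if criterion == "max_accuracy" else sens + spec - 1.0
        if best is None or value > best[0] + 1e-12:
            best = (value, OperatingPoint(float(t), sens, spec, acc, tp, fp, tn, fn))
    return best[1]


def predict_outcome(
    derived: pd.DataFrame,
    predictor: str,
    outcome_variable: str,
    direction: str | None = None,
    criterion: str = "max_accuracy",
) -> RocResult:
    """ROC analysis of one EAT predictor against one dichotomized outcome."""
    if direction is None:
        direction = DEFAULT_OUTCOME_DIRECTIONS.get(outcome_variable, "ge_median")
    labels, med = dichotomize_outcome(derived[outcome_variable].to_numpy(), direction)
    curve = roc_curve(derived[predictor].to_numpy(), labels)
    op = select_operating_point(curve, criterion)
    return RocResult(
        predictor=predictor,
        outcome_variable=outcome_variable,
        outcome_direction=direction,
        outcome_median=med,
        curve=curve,
        operating_point=op,
    )


def prediction_report(
    derived: pd.DataFrame,
    predictors=EAT_VARIABLES,
    outcomes=AO_VARIABLES,
    criterion: str = "max_accuracy",
) -> list[RocResult]:
    """The full predictor-grid report: each aortic outcome (in its adverse
    direction) predicted by each EAT variable — 12 ROC analyses by default,
    outcome-major order."""
    results = []
    for outcome in outcomes:
        for pred in predictors:
            results.append(predict_outcome(derived, pred, outcome, criterion=criterion))
    return results


def report_to_frame(results: list[RocResult]) -> pd.DataFrame:
    """Flatten RocResults into the sensitivity/specificity/accuracy table
    (rates at 3 decimals, counts retained)."""
    rows = []
    for r in results:
        op = r.operating_point
        rows.append(
            {
                "predictor": r.predictor,
                "threshold": op.threshold,
                "outcome_variable": r.outcome_variable,
                "outcome_direction": r.outcome_direction,
                "outcome_median": r.outcome_median,
                "auc": round(r.curve.auc, 3),
                "sensitivity": round(op.sensitivity, 3),
                "specificity": round(op.specificity, 3),
                "accuracy": round(op.accuracy, 3),
                "tp": op.tp,
                "fp": op.fp,
                "tn": op.tn,
                "fn": op.fn,
            }
        )
    return pd.DataFrame(rows)


def accuracy_from_rates(
    sensitivity: float, specificity: float, n_positive: int, n_negative: int
) -> float:
    """Prevalence-weighted accuracy identity:
    accuracy = (sens * n_pos + spec * n_neg) / (n_pos + n_neg)."""
    return (sensitivity * n_positive + specificity * n_negative) / (n_positive + n_negative)


__all__ = [
    "OPERATING_CRITERIA",
    "DEFAULT_OUTCOME_DIRECTIONS",
    "OperatingPoint",
    "RocCurve",
    "RocResult",
    "dichotomize_outcome",
    "roc_curve",
    "select_operating_point",
    "predict_outcome",
    "prediction_report",
    "report_to_frame",
    "accuracy_from_rates",
]
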