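"""Confusion-matrix metrics, threshold curves, and sensitivity-targeted tuning.

Metric definitions follow the screening-literature convention: sensitivity
and specificity are the positive- and negative-class recalls, PPV and NPV
the positive- and negative-class precisions, and the macro F1 is the
unweighted mean of the per-class F1 scores.  A classification is positive
when the score is at or above the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Derived proportions; ratios with zero denominators are None."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1_positive: float | None
    f1_macro: float | None
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "f1_positive": self.f1_positive,
            "f1_macro": self.f1_macro,
        }


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def _f1(precision: float | None, recall: float | None) -> float | None:
    if precision is None or recall is None:
        return None
    if precision + recall == 0:
        return None
    return 2 * precision * recall / (precision + recall)


def confusion_at(
    labels: Sequence[int], scores: Sequence[float], threshold: float
) -> ConfusionMatrix:
    """Tabulate the confusion matrix at a score threshold (positive iff >=)."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have the same length")
    pred = s >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """All reported metrics from one confusion matrix.

    accuracy    = (TP + TN) / n
    sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)
    PPV         = TP / (TP + FP)        NPV         = TN / (TN + FN)
    F1(+)       = harmonic mean of PPV and sensitivity
    F1 macro    = mean of F1(+) and F1(-), where F1(-) uses NPV/specificity
    """
    accuracy = _ratio(cm.tp + cm.tn, cm.n)
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    f1_pos = _f1(ppv, sensitivity)
    f1_neg = _f1(npv, specificity)
    f1_macro = None if (f1_pos is None or f1_neg is None) else (f1_pos + f1_neg) / 2
    undefined = tuple(
        name
        for name, value in [
            ("accuracy", accuracy), ("sensitivity", sensitivity),
            ("specificity", specificity), ("ppv", ppv), ("npv", npv),
            ("f1_positive", f1_pos), ("f1_macro", f1_macro),
        ]
        if value is None
    )
    return MetricsReport(
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        ppv=ppv, npv=npv, f1_positive=f1_pos, f1_macro=f1_macro,
        undefined=undefined,
    )


def tune_threshold(
    labels: Sequence[int], scores: Sequence[float], target_sensitivity: float = 0.93
) -> float:
    """Largest threshold whose sensitivity meets the target.

    Maximizes specificity subject to sensitivity >= target on the supplied
    (validation) vectors.  Candidate thresholds are the positive-class
    scores; classification uses score >= threshold, so the minimum positive
    score always attains sensitivity 1.
    """
    if not 0 < target_sensitivity <= 1:
        raise ValueError("target sensitivity must be in (0, 1]")
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    pos_scores = np.sort(s[y == 1])[::-1]
    n_pos = pos_scores.shape[0]
    if n_pos == 0:
        raise ValueError("no positive cases in the tuning data")
    # at threshold pos_scores[i-1], sensitivity >= i / n_pos
    candidates = pos_scores[np.arange(1, n_pos + 1) / n_pos >= target_sensitivity]
    if candidates.size == 0:  # pragma: no cover - unreachable for target <= 1
        warnings.warn("target sensitivity unattainable; using min positive score")
        return float(pos_scores[-1])
    threshold = float(candidates[0])
    achieved = np.mean(s[y == 1] >= threshold)
    assert achieved >= target_sensitivity
    return threshold


def threshold_curve(
    labels: Sequence[int], scores: Sequence[float],
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-threshold operating characteristics, ordered by threshold."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if thresholds is None:
        thresholds = np.unique(np.concatenate([[0.0], np.unique(s), [1.0]]))
    rows = []
    for t in np.sort(np.asarray(thresholds, dtype=float)):
        cm = confusion_at(y, s, t)
        m = compute_metrics(cm)
        rows.append({
            "threshold": t, "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
            "sensitivity": m.sensitivity, "specificity": m.specificity,
            "ppv": m.ppv, "npv": m.npv,
        })
    return pd.DataFrame(rows)


def evaluate_scores(
    labels: Sequence[int], scores: Sequence[float], threshold: float
) -> tuple[MetricsReport, pd.DataFrame]:
    """Metrics report at a pre-tuned threshold plus the full curve."""
    report = compute_metrics(confusion_at(labels, scores, threshold))
    return report, threshold_curve(labels, scores)


def percentage(count: int, total: int, digits: int = 1) -> float:
    """Proportion as a percentage, rounded as printed in cohort reporting."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, digits)


def imbalance_ratio(n_negative: int, n_positive: int, digits: int = 2) -> float:
    """Majority:minority class ratio (the '1:x' figure in cohort reporting)."""
    if n_positive <= 0:
        raise ValueError("positive count must be positive")
    return round(n_negative / n_positive, digits)
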