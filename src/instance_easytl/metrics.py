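"""Confusion-matrix metrics and the leave-one-subject-out protocol.

The drowsy condition (label 1) is the positive class: recall is the fraction
of drowsy windows recovered, precision the fraction of drowsy calls that are
right, and F1 their harmonic mean.  All metrics are reported in percent.

Leave-one-subject-out (LOSO): each subject in turn is the target domain, all
other subjects pooled form the source domain; only the target's untouched
test split S is scored (borrowed samples are training data, never test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boosting import fit_predict
from .domains import LabeledDomain

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "precision_recall_f1",
    "loso_evaluate",
]


@dataclass
class ConfusionCounts:
    """2x2 tally with a declared positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(
    y_true: np.ndarray, y_pred: np.ndarray, positive: int = 1
) -> ConfusionCounts:
    """Tally TP/FP/FN/TN with ``positive`` as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: y_true {y_true.shape} vs y_pred {y_pred.shape}"
        )
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting 0", RuntimeWarning)
        return 0.0
    return num / den


def precision_recall_f1(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, recall, precision and F1 in percent from a 2x2 tally.

    Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 = 2PR/(P+R).  A zero
    denominator yields 0 with a warning.
    """
    precision = _safe_ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = _safe_ratio(counts.tp, counts.tp + counts.fn, "recall")
    f1 = _safe_ratio(2 * precision * recall, precision + recall, "f1")
    accuracy = _safe_ratio(counts.tp + counts.tn, counts.total, "accuracy")
    return {
        "accuracy": 100.0 * accuracy,
        "recall": 100.0 * recall,
        "precision": 100.0 * precision,
        "f1": 100.0 * f1,
    }


def loso_evaluate(
    cohort: list[LabeledDomain],
    lam: float = 0.3,
    N: int = 30,
    seed: int | None = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Leave-one-subject-out evaluation of the transfer classifier.

    For each held-out subject the remaining subjects are pooled into the
    source domain and :func:`~instance_easytl.boosting.fit_predict` labels
    the held-out subject's test split; predictions are scored against the
    true labels of that split only.  Returns one row per subject plus an
    unweighted ``average`` row (all values in percent).
    """
    if len(cohort) < 2:
        raise ValueError("LOSO needs at least two subjects")
    rows = []
    for held_out in range(len(cohort)):
        target = cohort[held_out]
        others = [d for i, d in enumerate(cohort) if i != held_out]
        source = LabeledDomain(
            np.vstack([d.X for d in others]),
            np.concatenate([d.y for d in others]),
        )
        result = fit_predict(source, target, lam=lam, N=N, seed=seed, **fit_kwargs)
        y_true = target.y[result.idx_test]
        metrics = precision_recall_f1(confusion_counts(y_true, result.hf))
        rows.append({"subject": held_out, "n_test": len(y_true), **metrics})
    report = pd.DataFrame(rows)
    avg = report[["accuracy", "recall", "precision", "f1"]].mean()
    avg_row = {"subject": "average", "n_test": int(report["n_test"].sum()), **avg}
    return pd.concat([report, pd.DataFrame([avg_row])], ignore_index=True)
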