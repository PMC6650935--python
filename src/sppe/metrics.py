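"""Confusion-matrix metrics and report assembly."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Class treated as positive in binary reports.
DEFAULT_POSITIVE = "naked"


@dataclass
class ConfusionMatrix:
    """Binary confusion counts with a designated positive class."""

    tp: int
    tn: int
    fp: int
    fn: int
    positive: str = DEFAULT_POSITIVE

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(
        cls, truth, prediction, positive: str = DEFAULT_POSITIVE
    ) -> "ConfusionMatrix":
        t = np.asarray(truth) == positive
        p = np.asarray(prediction) == positive
        return cls(
            tp=int((t & p).sum()),
            tn=int((~t & ~p).sum()),
            fp=int((~t & p).sum()),
            fn=int((t & ~p).sum()),
            positive=positive,
        )


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / n — the main-diagonal fraction."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.n


def _safe_ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); returning NaN")
        return float("nan")
    return num / den


def recall(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN); NaN with a warning when no positives exist."""
    return _safe_ratio(cm.tp, cm.tp + cm.fn, "recall")


def precision(cm: ConfusionMatrix) -> float:
    """TP / (TP + FP); NaN with a warning when nothing was predicted positive."""
    return _safe_ratio(cm.tp, cm.tp + cm.fp, "precision")


def classification_report(
    truth, prediction, positive: str = DEFAULT_POSITIVE
) -> dict:
    """Accuracy plus per-class and macro-averaged precision/recall."""
    truth = np.asarray(truth)
    prediction = np.asarray(prediction)
    classes = sorted(set(truth) | set(prediction))
    per_class = {}
    for c in classes:
        cm_c = ConfusionMatrix.from_predictions(truth, prediction, positive=c)
        per_class[c] = {"precision": precision(cm_c), "recall": recall(cm_c)}
    cm = ConfusionMatrix.from_predictions(truth, prediction, positive=positive)
    macro_p = float(np.mean([v["precision"] for v in per_class.values()]))
    macro_r = float(np.mean([v["recall"] for v in per_class.values()]))
    return {
        "accuracy": accuracy(cm),
        "positive_class": positive,
        "precision": precision(cm),
        "recall": recall(cm),
        "macro_precision": macro_p,
        "macro_recall": macro_r,
        "per_class": per_class,
        "n": int(cm.n),
    }


def report_from_predictions(pred_df: pd.DataFrame, positive: str = DEFAULT_POSITIVE) -> dict:
    """Report from a prediction table with ``truth``/``prediction`` columns."""
    return classification_report(
        pred_df["truth"], pred_df["prediction"], positive=positive
    )
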