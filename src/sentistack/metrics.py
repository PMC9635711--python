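"""Classification metrics and inter-rater agreement.

Positive class is non-Negative sentiment throughout: sensitivity is the
probability of correctly predicting a non-Negative message, specificity of
correctly predicting a Negative one.  Undefined ratios (empty denominator)
are reported as NaN, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionTable", "confusion_table", "classification_metrics", "agreement"]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts with positive class = non-Negative."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_table(y_true, y_pred) -> ConfusionTable:
    """Build the confusion table from 0/1 vectors (1 = non-Negative)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionTable(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(ct: ConfusionTable) -> dict:
    """CAR, F1, sensitivity, specificity and PPV from a confusion table.

    F1 is the harmonic mean of sensitivity and PPV (the same value whether
    the pair is called precision/recall in the standard sense or in the
    study's swapped sense, since harmonic means are symmetric).
    """
    if ct.total == 0:
        raise ValueError("empty confusion table")
    sens = _ratio(ct.tp, ct.tp + ct.fn)
    spec = _ratio(ct.tn, ct.tn + ct.fp)
    ppv = _ratio(ct.tp, ct.tp + ct.fp)
    if np.isnan(sens) or np.isnan(ppv) or sens + ppv == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * sens * ppv / (sens + ppv)
    return {
        "car": _ratio(ct.tp + ct.tn, ct.total),
        "f1": f1,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
    }


def agreement(labels_a, labels_b) -> dict:
    """Raw agreement rate and Cohen's kappa between two raters.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    product of the two raters' marginal label distributions.  When both
    raters are constant and identical, p_e = 1 and kappa is undefined (NaN).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("need two equal-length, nonempty label vectors")
    p_o = float(np.mean(a == b))
    cats = np.union1d(np.unique(a), np.unique(b))
    p_e = float(sum(np.mean(a == c) * np.mean(b == c) for c in cats))
    kappa = float("nan") if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return {"agreement": p_o, "kappa": kappa}
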