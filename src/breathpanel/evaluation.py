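"""Classifier evaluation: ROC / precision-recall curves, operating points, PPV.

The study's recurring operating point anchors specificity at 70%: among all
thresholds the one whose specificity is closest to the target *from above*
is chosen, ties broken toward higher sensitivity, and sensitivity / PPV /
confusion counts are reported there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve


@dataclass
class ClassifierReport:
    """Binary-classification summary at a specificity-anchored threshold."""

    sensitivity: float
    specificity: float
    auc_roc: float
    auc_pr: float
    ppv: float
    threshold: float
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]
    roc_points: np.ndarray = field(repr=False, default=None)  # (fpr, tpr) rows
    pr_points: np.ndarray = field(repr=False, default=None)  # (recall, precision) rows

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr,
            "ppv": self.ppv,
            "threshold": self.threshold,
            "confusion": self.confusion.tolist(),
        }


def evaluate(scores: np.ndarray, y_true: np.ndarray, spec_target: float = 0.70) -> ClassifierReport:
    """Score a binary contrast: full ROC and PR curves plus the anchored point.

    ``scores`` are higher-for-positive; ``y_true`` is 0/1.  AUCs are
    trapezoidal.  The operating threshold is the one whose specificity is
    closest to ``spec_target`` from above (ties toward higher sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    if scores.shape != y_true.shape:
        raise ValueError("scores and labels must align")
    if len(np.unique(y_true)) < 2:
        raise ValueError("evaluation needs both classes present")

    fpr, tpr, thresholds = roc_curve(y_true, scores)
    auc_roc = float(np.trapezoid(tpr, fpr))
    precision, recall, _ = precision_recall_curve(y_true, scores)
    # precision_recall_curve returns recall descending; integrate over recall
    auc_pr = float(np.trapezoid(precision[::-1], recall[::-1]))

    specs = 1.0 - fpr
    ok = specs >= spec_target
    if ok.any():
        cand = np.flatnonzero(ok)
        # closest to the target from above, then highest sensitivity
        best = cand[np.lexsort((-tpr[cand], specs[cand]))][0]
    else:
        best = int(np.argmax(specs))
    thr = float(thresholds[best])

    pred = scores >= thr
    tp = int(np.sum(pred & (y_true == 1)))
    fp = int(np.sum(pred & (y_true == 0)))
    fn = int(np.sum(~pred & (y_true == 1)))
    tn = int(np.sum(~pred & (y_true == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv_val = tp / (tp + fp) if (tp + fp) > 0 else float("nan")

    return ClassifierReport(
        sensitivity=sens,
        specificity=spec,
        auc_roc=auc_roc,
        auc_pr=auc_pr,
        ppv=ppv_val,
        threshold=thr,
        confusion=np.array([[tn, fp], [fn, tp]]),
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([recall[::-1], precision[::-1]]),
    )


def ppv(sensitivity: float, specificity: float, n_pos: int, n_neg: int) -> float:
    """Positive predictive value implied by rates on a finite sample.

    TP = round(sens * n_pos), FP = n_neg - round(spec * n_neg); raises when
    no positive calls are made (PPV undefined).
    """
    for r in (sensitivity, specificity):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be nonnegative")
    tp = round(sensitivity * n_pos)
    fp = n_neg - round(specificity * n_neg)
    if tp + fp == 0:
        raise ValueError("PPV undefined: no predicted positives (TP + FP = 0)")
    return tp / (tp + fp)
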