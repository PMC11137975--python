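"""Evaluation: confusion-matrix metrics, ROC/AUC, and the paired z-test.

The positive class throughout is ncRNA.  Seven scalar metrics are reported —
ACC, MCC, SE (sensitivity/recall), SPC (specificity), PPV (precision), NPV
and F1 — alongside AUC from the empirical ROC.  Any metric whose denominator
is zero is reported as ``None`` (undefined) rather than silently zero.

Two classifiers are compared with a paired z-test over their discordant
predictions on the positive-class instances: with f12 the ncRNA instances the
first method got right and the second wrong, and f21 the converse,
``z = (f12 - f21) / sqrt(f12 + f21)`` and the one-tailed p-value is
``1 - Phi(z)``.  A z above 1.64 (the one-tailed 5% critical value of the
standard normal, to two decimals) indicates a significant accuracy advantage
of the first method.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve

from .data_io import POSITIVE_CLASS


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class EvaluationReport:
    acc: float | None
    mcc: float | None
    se: float | None
    spc: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    cm: ConfusionMatrix
    auc: float | None = None

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("acc", "mcc", "se", "spc", "ppv", "npv", "f1", "auc")}
        d["confusion"] = {"TP": self.cm.TP, "TN": self.cm.TN,
                          "FP": self.cm.FP, "FN": self.cm.FN}
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def __str__(self) -> str:
        def fmt(v):
            return "undefined" if v is None else f"{v:.4f}"
        lines = [f"{name.upper():>4}  {fmt(getattr(self, name))}"
                 for name in ("acc", "mcc", "se", "spc", "ppv", "npv", "f1", "auc")]
        lines.append(f"  CM  TP={self.cm.TP} TN={self.cm.TN} FP={self.cm.FP} FN={self.cm.FN}")
        return "\n".join(lines)


@dataclass(frozen=True)
class PairedComparison:
    f12: int
    f21: int
    z: float
    p: float


def confusion(labels, predictions, positive: str = POSITIVE_CLASS) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with ncRNA as the positive class."""
    y = np.asarray(labels)
    yhat = np.asarray(predictions)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError(f"label/prediction shape mismatch or empty: {y.shape} vs {yhat.shape}")
    pos, ppos = y == positive, yhat == positive
    return ConfusionMatrix(
        TP=int(np.sum(pos & ppos)),
        TN=int(np.sum(~pos & ~ppos)),
        FP=int(np.sum(~pos & ppos)),
        FN=int(np.sum(pos & ~ppos)),
    )


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(cm: ConfusionMatrix) -> EvaluationReport:
    """The seven scalar metrics from a confusion matrix (AUC left unset)."""
    if cm.total == 0:
        raise ValueError("all-zero confusion matrix")
    tp, tn, fp, fn = cm.TP, cm.TN, cm.FP, cm.FN
    mcc_den = math.sqrt(float(tp + fn) * (tp + fp) * (tn + fp) * (tn + fn))
    return EvaluationReport(
        acc=(tp + tn) / cm.total,
        mcc=None if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den,
        se=_ratio(tp, tp + fn),
        spc=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
        cm=cm,
    )


def roc_auc(labels, scores, positive: str = POSITIVE_CLASS):
    """AUC (rank/Mann-Whitney tie handling) and the empirical ROC points.

    Returns ``(auc, points)`` where points is a list of (fpr, tpr, threshold).
    """
    y = (np.asarray(labels) == positive).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    return auc, list(zip(fpr.tolist(), tpr.tolist(), thr.tolist()))


def evaluate_predictions(labels, predictions, scores=None) -> EvaluationReport:
    """Full report: confusion metrics plus AUC when scores are given."""
    report = compute_metrics(confusion(labels, predictions))
    if scores is not None:
        report.auc = roc_auc(labels, scores)[0]
    return report


def paired_z_test(truth, pred_a, pred_b, positive: str = POSITIVE_CLASS) -> PairedComparison:
    """Paired z-test on discordant positive-class predictions.

    Only instances whose true class is ncRNA enter the counts.  With no
    discordant instances the statistic is reported as z = 0, p = 0.5.
    """
    y = np.asarray(truth)
    a = np.asarray(pred_a)
    b = np.asarray(pred_b)
    if not (y.shape == a.shape == b.shape):
        raise ValueError("truth and both prediction vectors must share a length")
    pos = y == positive
    a_right = (a == positive) & pos
    b_right = (b == positive) & pos
    f12 = int(np.sum(a_right & ~b_right & pos))
    f21 = int(np.sum(~a_right & b_right & pos))
    if f12 + f21 == 0:
        return PairedComparison(0, 0, 0.0, 0.5)
    z = (f12 - f21) / math.sqrt(f12 + f21)
    return PairedComparison(f12, f21, z, float(norm.sf(z)))


def write_roc_tsv(points, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\tthreshold\n")
        for fpr, tpr, thr in points:
            fh.write(f"{fpr:.6g}\t{tpr:.6g}\t{thr:.6g}\n")
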