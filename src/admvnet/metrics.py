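"""Classification metrics and fold-paired significance testing.

ACC, SEN, SPEC and BAC are computed from confusion counts at the argmax
operating point; AUC uses the rank-sum (Mann-Whitney) estimator with
midranks for tied scores, equivalent to trapezoidal integration of the ROC
curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class MetricsReport:
    acc: float
    sen: float
    spec: float
    bac: float
    auc: float | None
    confusion: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {"acc": self.acc, "sen": self.sen, "spec": self.spec,
             "bac": self.bac, "auc": self.auc}
        d.update({k.lower(): v for k, v in self.confusion.items()})
        return d


def auc_midrank(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC with midrank tie handling."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(labels, predictions, scores=None) -> MetricsReport:
    """labels/predictions: binary vectors; scores: positive-class
    probabilities (optional; without them AUC is reported as None)."""
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n if n else float("nan")
    sen = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    bac = (sen + spec) / 2
    auc = None
    if scores is not None:
        try:
            auc = auc_midrank(labels, scores)
        except ValueError:
            warnings.warn("single-class label vector: AUC undefined, reported as None")
    return MetricsReport(acc=acc, sen=sen, spec=spec, bac=bac, auc=auc,
                         confusion={"TP": tp, "FP": fp, "FN": fn, "TN": tn})


@dataclass
class PairedTestResult:
    t: float
    p: float
    degenerate: bool = False


def paired_ttest(metric_a, metric_b) -> PairedTestResult:
    """Two-sided paired t-test on per-fold metric values."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return PairedTestResult(t=0.0 if np.allclose(d.mean(), 0.0) else float("inf"),
                                p=float("nan"), degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(t=float(t), p=float(p))
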