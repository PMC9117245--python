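"""Evaluation protocol: ROC/PR, threshold sweeps and misprediction detection.

Two questions are answered about an uncertainty-aware classifier:

1. *Predictive boosting* — does folding uncertainty into the score improve
   ranking (ROC/PR AUC) or, more importantly, flatten the accuracy-versus-
   threshold curve so that the operating point matters less?
2. *Misprediction detection* — how well does an uncertainty score rank the
   classifier's errors above its correct predictions, summarised by ROC-AUC
   with mispredictions as the positive class, at fixed classification
   thresholds (0.1, 0.5 and 0.9 by convention)?

Positivity is strict (``score > threshold``) throughout, consistent with the
combiner.  Undefined quantities (precision with no positive predictions,
AUC with a single class present) raise :class:`UndefinedMetricError` rather
than silently returning 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import sklearn.metrics as skm

from .metrics import (METRICS, MeanScoreVector, UncertaintyVector,
                      baseline_uncertainty)
from .samplers import SampleMatrix

__all__ = [
    "UndefinedMetricError",
    "ConfusionCounts",
    "RocCurve",
    "PrCurve",
    "AccuracySweep",
    "MispredictionReport",
    "confusion_counts",
    "accuracy",
    "recall",
    "precision",
    "fpr",
    "roc_auc",
    "pr_auc",
    "accuracy_sweep",
    "default_grid",
    "misprediction_labels",
    "misprediction_auc",
    "build_report",
]


class UndefinedMetricError(ValueError):
    """A requested quantity is mathematically undefined on this input."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(scores: np.ndarray, labels: np.ndarray,
                     threshold: float) -> ConfusionCounts:
    """Partition N inputs by (prediction = score > threshold) × label."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    pred = s > threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def accuracy(counts: ConfusionCounts) -> float:
    if counts.total == 0:
        raise UndefinedMetricError("accuracy undefined on zero inputs")
    return (counts.tp + counts.tn) / counts.total


def recall(counts: ConfusionCounts) -> float:
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("recall undefined: no positive inputs")
    return counts.tp / (counts.tp + counts.fn)


def precision(counts: ConfusionCounts) -> float:
    if counts.tp + counts.fp == 0:
        raise UndefinedMetricError("precision undefined: no positive predictions")
    return counts.tp / (counts.tp + counts.fp)


def fpr(counts: ConfusionCounts) -> float:
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("FPR undefined: no negative inputs")
    return counts.fp / (counts.tn + counts.fp)


@dataclass(frozen=True)
class RocCurve:
    """(FPR, TPR) points from (0,0) to (1,1), their thresholds, and the
    trapezoidal AUC (equal to the Mann–Whitney statistic with midrank tie
    handling)."""

    points: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass(frozen=True)
class PrCurve:
    """(recall, precision) points with recall non-decreasing, and the
    step-wise average-precision AUC."""

    points: np.ndarray
    auc: float


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    return y


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve over all distinct score thresholds.

    Requires both classes to be present; with one class the curve (and the
    ranking it summarises) is undefined.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = _check_binary(labels)
    if y.min() == y.max():
        raise UndefinedMetricError("ROC undefined: only one class present")
    f, t, thr = skm.roc_curve(y, s, drop_intermediate=False)
    return RocCurve(points=np.column_stack([f, t]), thresholds=thr,
                    auc=float(skm.auc(f, t)))


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> PrCurve:
    """Precision–recall curve with the average-precision summary."""
    s = np.asarray(scores, dtype=np.float64)
    y = _check_binary(labels)
    if np.sum(y == 1) == 0:
        raise UndefinedMetricError("PR curve undefined: no positive inputs")
    prec, rec, _ = skm.precision_recall_curve(y, s)
    # sklearn emits recall decreasing; store with recall non-decreasing
    pts = np.column_stack([rec[::-1], prec[::-1]])
    return PrCurve(points=pts, auc=float(skm.average_precision_score(y, s)))


def default_grid(lo: float = 0.0, hi: float = 1.0,
                 n: int = 201) -> np.ndarray:
    """Evenly spaced threshold grid; 201 points in [0, 1] by default."""
    return np.linspace(lo, hi, n)


@dataclass(frozen=True)
class AccuracySweep:
    """Accuracy at each grid threshold, its peak, and the width of the
    contiguous threshold region within one percentage point of the peak
    (the operational measure of how forgiving the operating-point choice is).
    """

    thresholds: np.ndarray
    accuracies: np.ndarray
    peak_threshold: float
    peak_accuracy: float
    plateau_width: float


def accuracy_sweep(scores: np.ndarray, labels: np.ndarray,
                   grid: np.ndarray | None = None) -> AccuracySweep:
    """Sweep classification accuracy over a strictly increasing threshold
    grid.

    The plateau is the contiguous run of grid points containing the peak
    whose accuracy stays within 0.01 of the peak; its width is the threshold
    span of that run plus one grid spacing (so a single-point plateau has
    width equal to the spacing).
    """
    s = np.asarray(scores, dtype=np.float64)
    y = _check_binary(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    g = default_grid() if grid is None else np.asarray(grid, dtype=np.float64)
    if g.size == 0:
        raise ValueError("threshold grid is empty")
    if g.size > 1 and not (np.diff(g) > 0).all():
        raise ValueError("threshold grid must be strictly increasing")
    preds = s[None, :] > g[:, None]
    acc = (preds == (y == 1)[None, :]).mean(axis=1)
    i_peak = int(np.argmax(acc))
    ok = acc >= acc[i_peak] - 0.01
    lo = i_peak
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = i_peak
    while hi < g.size - 1 and ok[hi + 1]:
        hi += 1
    spacing = float(g[1] - g[0]) if g.size > 1 else 0.0
    return AccuracySweep(
        thresholds=g, accuracies=acc,
        peak_threshold=float(g[i_peak]), peak_accuracy=float(acc[i_peak]),
        plateau_width=float(g[hi] - g[lo]) + spacing,
    )


def misprediction_labels(single_scores: MeanScoreVector, labels: np.ndarray,
                         classification_threshold: float) -> np.ndarray:
    """1 where the thresholded single-model prediction disagrees with ground
    truth (mispredictions become the positive class), else 0."""
    if not 0.0 <= classification_threshold <= 1.0:
        raise ValueError("classification threshold must lie in [0, 1]")
    y = _check_binary(labels)
    pred = (single_scores.values > classification_threshold).astype(np.int64)
    return (pred != y).astype(np.int64)


def misprediction_auc(uncertainty: UncertaintyVector,
                      mispredictions: np.ndarray) -> float:
    """ROC-AUC of the uncertainty score for ranking mispredictions above
    correct predictions.

    Raises when the classifier made no mispredictions (nothing to detect) or
    no correct predictions at the chosen threshold.
    """
    mis = _check_binary(mispredictions)
    if mis.sum() == 0:
        raise UndefinedMetricError(
            "misprediction AUC undefined: the classifier made no "
            "mispredictions at this threshold")
    return roc_auc(uncertainty.values, mis).auc


@dataclass(frozen=True)
class MispredictionReport:
    """Misprediction-detection AUCs at one classification threshold, for
    every (method, metric) pair plus the single-softmax baseline."""

    classification_threshold: float
    accuracy: float
    baseline_auc: float
    rows: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        recs = [{"method": m, "metric": k, "misprediction_auc": v}
                for (m, k), v in sorted(self.rows.items())]
        recs.append({"method": "single", "metric": "baseline",
                     "misprediction_auc": self.baseline_auc})
        df = pd.DataFrame.from_records(recs)
        df.insert(0, "classification_threshold", self.classification_threshold)
        df.insert(1, "accuracy", self.accuracy)
        return df


def build_report(samples_by_method: Mapping[str, SampleMatrix],
                 single_scores: MeanScoreVector,
                 labels: np.ndarray,
                 thresholds: Sequence[float] = (0.1, 0.5, 0.9),
                 metrics: Sequence[str] | None = None,
                 ) -> list[MispredictionReport]:
    """Misprediction-detection table across classification thresholds.

    For each threshold: the classifier accuracy at that threshold, the
    baseline AUC from ``u_base`` on the single-model score, and the AUC of
    every uncertainty metric computed from every provided sample matrix.
    """
    y = _check_binary(labels)
    metric_names = list(metrics) if metrics is not None else list(METRICS)
    uncert: dict[tuple[str, str], UncertaintyVector] = {}
    for method, sm in samples_by_method.items():
        for name in metric_names:
            uncert[(method, name)] = METRICS[name](sm)
    base = baseline_uncertainty(single_scores)

    reports = []
    for t in thresholds:
        mis = misprediction_labels(single_scores, y, t)
        acc = 1.0 - mis.mean()
        rows = {key: misprediction_auc(u, mis) for key, u in uncert.items()}
        reports.append(MispredictionReport(
            classification_threshold=float(t), accuracy=float(acc),
            baseline_auc=misprediction_auc(base, mis), rows=rows))
    return reports
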