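"""Evaluation metrics for thermostability prediction.

Classification: accuracy, per-class precision, ROC curves and AUC, plus
macro-averaged one-vs-rest ROC/AUC for the multiclass case (macro rather
than micro, so every thermostability class counts equally under imbalance).
The positive class of the binary task is "hot".

Regression: Pearson and Spearman correlation, R-squared and RMSE.

AUC uses the rank (Mann-Whitney) statistic with half credit for ties, so an
uninformative constant scorer yields exactly 0.5; it coincides with the
trapezoidal area under the ROC curve.  R-squared may be negative for fits
worse than the mean predictor.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "MetricReport",
    "confusion_counts",
    "accuracy",
    "precision",
    "roc_curve",
    "auc",
    "macro_roc_auc",
    "pearson",
    "spearman",
    "r_squared",
    "rmse",
]


@dataclasses.dataclass
class ConfusionCounts:
    """Binary confusion counts; positive class is "hot"."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclasses.dataclass
class RocCurve:
    """ROC points anchored at (0,0) and (1,1); fpr nondecreasing."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclasses.dataclass
class MetricReport:
    """A serialisable bundle of evaluation results."""

    task: str
    metrics: dict
    roc: dict | None = None  # per-class {fpr, tpr} lists, when applicable

    def to_json(self, **kwargs) -> str:
        payload = {"task": self.task, "metrics": self.metrics}
        if self.roc is not None:
            payload["roc"] = self.roc
        return json.dumps(payload, sort_keys=True, **kwargs)


def _binary(arr, name):
    a = np.asarray(arr)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1 labels")
    return a.astype(int)


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Count TP/TN/FP/FN with 1 = hot (positive), 0 = cold."""
    pred = _binary(pred, "pred")
    truth = _binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: pred {pred.shape} vs truth {truth.shape}")
    return ConfusionCounts(
        TP=int(np.sum((pred == 1) & (truth == 1))),
        TN=int(np.sum((pred == 0) & (truth == 0))),
        FP=int(np.sum((pred == 1) & (truth == 0))),
        FN=int(np.sum((pred == 0) & (truth == 1))),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / n."""
    if c.n == 0:
        raise ValueError("accuracy undefined on an empty evaluation")
    return (c.TP + c.TN) / c.n


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); NaN with a warning when nothing was predicted positive."""
    if c.TP + c.FP == 0:
        warnings.warn("precision undefined: no positive predictions", stacklevel=2)
        return float("nan")
    return c.TP / (c.TP + c.FP)


def roc_curve(scores, truth) -> RocCurve:
    """ROC curve from continuous scores; thresholds descend from +inf."""
    scores = np.asarray(scores, dtype=np.float64)
    truth = _binary(truth, "truth")
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_truth = truth[order]
    # one curve point per distinct score (all tied samples cross together)
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), len(scores) - 1]
    tps = np.cumsum(sorted_truth)[distinct]
    fps = distinct + 1 - tps
    fpr = np.r_[0.0, fps / n_neg]
    tpr = np.r_[0.0, tps / n_pos]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)


def auc(scores, truth) -> float:
    """Rank-based AUC (ties get half credit); equals the trapezoidal ROC area."""
    scores = np.asarray(scores, dtype=np.float64)
    truth = _binary(truth, "truth")
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores, method="average")
    u = ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def macro_roc_auc(scores, truth, n_classes: int | None = None):
    """One-vs-rest ROC/AUC per class with unweighted macro averaging.

    ``scores`` is (n, C); ``truth`` holds class indices.  Returns
    (per_class_aucs, macro_auc, macro_curve) where the macro curve averages
    the per-class TPR on the union grid of FPR values.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.int64)
    if scores.ndim != 2 or scores.shape[0] != truth.shape[0]:
        raise ValueError("scores must be (n, C) aligned with truth")
    C = scores.shape[1] if n_classes is None else n_classes
    missing = sorted(set(range(C)) - set(truth.tolist()))
    if missing:
        raise ValueError(f"classes absent from truth: {missing}")
    per_class = []
    curves = []
    for c in range(C):
        y = (truth == c).astype(int)
        per_class.append(auc(scores[:, c], y))
        curves.append(roc_curve(scores[:, c], y))
    grid = np.unique(np.concatenate([cv.fpr for cv in curves]))
    mean_tpr = np.mean([np.interp(grid, cv.fpr, cv.tpr) for cv in curves], axis=0)
    macro_curve = RocCurve(fpr=grid, tpr=mean_tpr, thresholds=np.full_like(grid, np.nan))
    return np.array(per_class), float(np.mean(per_class)), macro_curve


def pearson(x, y) -> float:
    """cov(x, y) / (sigma_x sigma_y), population convention."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("pearson requires two equal-length arrays with n >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).mean())
    sy = np.sqrt((yc * yc).mean())
    if sx == 0.0 or sy == 0.0:
        raise ValueError("pearson undefined: zero variance")
    return float((xc * yc).mean() / (sx * sy))


def spearman(x, y) -> float:
    """Pearson correlation of tie-averaged ranks."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("spearman requires two equal-length arrays with n >= 2")
    return pearson(rankdata(x, method="average"), rankdata(y, method="average"))


def r_squared(y, y_hat) -> float:
    """1 - SS_res / SS_tot; negative for fits worse than the mean predictor."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("r_squared requires two equal-length arrays with n >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r_squared undefined: constant ground truth")
    return float(1.0 - np.sum((y - y_hat) ** 2) / ss_tot)


def rmse(y, y_hat) -> float:
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))
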