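"""Segment-based evaluation: confusion matrices, the five headline metrics,
fold-averaged ROC/AUC, per-participant accuracy and cohort statistics."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with the EP class as positive."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        # rows = true (healthy, EP), columns = predicted (healthy, EP)
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionMatrix:
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary (0/1)")
    return ConfusionMatrix(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {name}; defining it as 0", stacklevel=3)
        return 0.0
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> Dict[str, float]:
    """accuracy, sensitivity, specificity, precision and F1 as fractions."""
    sens = _safe_div(cm.tp, cm.tp + cm.fn, "sensitivity")
    spec = _safe_div(cm.tn, cm.tn + cm.fp, "specificity")
    prec = _safe_div(cm.tp, cm.tp + cm.fp, "precision")
    acc = _safe_div(cm.tp + cm.tn, cm.n, "accuracy")
    f1 = _safe_div(2.0 * prec * sens, prec + sens, "f1")
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
    }


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> Tuple[np.ndarray, float]:
    """ROC points from a threshold sweep and the trapezoidal AUC.

    Returns an (n, 2) array of (fpr, tpr) points.  The AUC equals the
    probability that a random positive outscores a random negative (ties
    counted one half).
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class AveragedROC:
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    std_tpr: np.ndarray
    auc_mean: float
    auc_std: float


def average_roc(
    fold_results: Sequence[Tuple[np.ndarray, float]], n_grid: int = 101
) -> AveragedROC:
    """Vertical averaging of per-fold ROC curves over a fixed FPR grid.

    The band is +/- one sample standard deviation of the interpolated TPR;
    the AUC is summarised as mean and sample standard deviation across folds.
    """
    if len(fold_results) < 2:
        raise ValueError("need at least 2 folds to average")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = []
    for roc_points, _ in fold_results:
        pts = np.asarray(roc_points)
        tprs.append(np.interp(grid, pts[:, 0], pts[:, 1]))
    tprs = np.stack(tprs)
    aucs = np.array([a for _, a in fold_results], dtype=np.float64)
    return AveragedROC(
        fpr_grid=grid,
        mean_tpr=tprs.mean(axis=0),
        std_tpr=tprs.std(axis=0, ddof=1),
        auc_mean=float(aucs.mean()),
        auc_std=float(aucs.std(ddof=1)),
    )


def per_participant_accuracy(
    subject_ids: Sequence[str],
    labels: Sequence[int],
    predictions: Sequence[int],
) -> Tuple[Dict[str, float], Dict[str, int]]:
    """Per-subject fraction of correctly classified segments.

    Also counts subjects clearing the 0.8 and 0.9 accuracy thresholds
    (segment-error thresholds of 0.2 and 0.1).
    """
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if not (len(subject_ids) == len(y) == len(p)):
        raise ValueError("subject_ids, labels and predictions must align")
    per_subject: Dict[str, List[int]] = {}
    for sid, correct in zip(subject_ids, (y == p).astype(int)):
        per_subject.setdefault(sid, []).append(int(correct))
    acc = {sid: float(np.mean(v)) for sid, v in per_subject.items()}
    counts = {
        "above_0.8": sum(a >= 0.8 for a in acc.values()),
        "above_0.9": sum(a >= 0.9 for a in acc.values()),
    }
    return acc, counts


def chi_square_2x2(table: Sequence[Sequence[float]]) -> float:
    """Pearson chi-square without continuity correction: N(ad-bc)^2/(r1 r2 c1 c2)."""
    t = np.asarray(table, dtype=np.float64)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    r1, r2 = t.sum(axis=1)
    c1, c2 = t.sum(axis=0)
    if min(r1, r2, c1, c2) <= 0:
        raise ValueError("all marginals must be positive")
    return float(n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sample Mann-Whitney U = min(U_x, U_y) with midrank tie handling."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    u_x = float(stats.mannwhitneyu(x, y, alternative="two-sided").statistic)
    return min(u_x, len(x) * len(y) - u_x)


@dataclass
class MetricsReport:
    """Per-fold and aggregate segment-level evaluation results."""

    model_kind: str
    per_fold: List[Dict[str, float]] = field(default_factory=list)
    confusions: List[ConfusionMatrix] = field(default_factory=list)
    fold_rocs: List[Tuple[np.ndarray, float]] = field(default_factory=list)
    averaged_roc: AveragedROC | None = None
    per_participant: Dict[str, float] = field(default_factory=dict)
    threshold_counts: Dict[str, int] = field(default_factory=dict)

    @property
    def mean(self) -> Dict[str, float]:
        return {
            m: float(np.mean([f[m] for f in self.per_fold])) for m in METRIC_NAMES
        }

    @property
    def std(self) -> Dict[str, float]:
        # sample standard deviation across folds
        return {
            m: float(np.std([f[m] for f in self.per_fold], ddof=1))
            if len(self.per_fold) > 1 else 0.0
            for m in METRIC_NAMES
        }
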