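"""Cross-validated OSA classification from detected marker intensities.

Subjects are classified (positive = untreated OSA) from the intensities
of all detected panel markers using a linear maximum-margin classifier
(SVM, unit cost) in stratified 10-fold cross-validation. The AUC is
averaged over folds; the confusion matrix is pooled over folds at the
classifier's default decision threshold (margin sign — the study reports
a single operating point, so no threshold tuning).

Auto-scaling moments are cohort statistics, so by default they are
recomputed inside each training fold and applied to the held-out fold
(leakage-free). ``paper_mode=True`` instead scales once globally before
the folds — the simpler historical protocol — and is exposed to make the
difference measurable.

``balanced_subsample`` down-samples the majority class uniformly at
random to the minority size before model building, which trades a little
sensitivity for materially better specificity on imbalanced cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ClassificationError


@dataclass
class CVConfig:
    """Cross-validation setup."""

    k: int = 10
    seed: int = 0
    stratified: bool = True
    classifier: str = "linear_svm"
    svm_c: float = 1.0
    paper_mode: bool = False  # global (pre-CV) auto-scaling instead of fold-internal

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class ConfusionMatrix:
    """Counts at the default operating point; positive = untreated OSA."""

    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity (recall on positives) and specificity."""
    if cm.total == 0:
        raise ClassificationError("empty confusion matrix")
    return {
        "accuracy": (cm.tp + cm.tn) / cm.total,
        "sensitivity": cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else 0.0,
        "specificity": cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else 0.0,
    }


@dataclass
class PerformanceReport:
    """Fold-averaged AUC, pooled confusion matrix and headline metrics."""

    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    fold_auc: list[float]
    confusion: ConfusionMatrix
    seed: int
    config: Optional[CVConfig] = None

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "fold_auc": self.fold_auc,
            "confusion": {
                "tp": self.confusion.tp,
                "fn": self.confusion.fn,
                "fp": self.confusion.fp,
                "tn": self.confusion.tn,
            },
            "seed": self.seed,
        }


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank statistic; ties count 1/2.

    Equals U1/(n1*n2) with U1 the Mann-Whitney statistic of the positive
    scores against the negatives.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ClassificationError("both classes required for AUC")
    ranks = rankdata(scores)
    u1 = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n1 * n0))


def balanced_subsample(
    labels: Sequence[int], seed: int = 0
) -> np.ndarray:
    """Indices of a class-balanced subset (majority down-sampled, no
    replacement); deterministic given seed."""
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ClassificationError("balanced subsampling needs two classes")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if idx.size > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(np.sort(idx))
    return np.sort(np.concatenate(keep))


def _autoscale_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mean, sd


def crossvalidate(
    X: np.ndarray,
    labels: Sequence[int],
    config: Optional[CVConfig] = None,
) -> PerformanceReport:
    """Stratified k-fold cross-validated classification.

    ``X`` is subjects x detected-marker intensities on the
    median-TIC-scaled scale (pre auto-scaling); scaling moments are
    fitted fold-internally unless ``config.paper_mode``.
    """
    config = config or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ClassificationError("exactly two classes required")
    if counts.min() < config.k:
        raise ClassificationError(
            f"need >= k={config.k} subjects per class for stratified folds, "
            f"got {counts.min()}"
        )
    if config.paper_mode:
        mean, sd = _autoscale_fit(X)
        X = (X - mean) / sd
    splitter = StratifiedKFold(
        n_splits=config.k, shuffle=True, random_state=config.seed
    )
    cm = ConfusionMatrix()
    fold_auc: list[float] = []
    for train, test in splitter.split(X, y):
        Xtr, Xte = X[train], X[test]
        if not config.paper_mode:
            mean, sd = _autoscale_fit(Xtr)
            Xtr = (Xtr - mean) / sd
            Xte = (Xte - mean) / sd
        clf = SVC(kernel="linear", C=config.svm_c)
        clf.fit(Xtr, y[train])
        score = clf.decision_function(Xte)
        pred = (score > 0).astype(int)
        yt = y[test]
        cm.tp += int(((pred == 1) & (yt == 1)).sum())
        cm.fn += int(((pred == 0) & (yt == 1)).sum())
        cm.fp += int(((pred == 1) & (yt == 0)).sum())
        cm.tn += int(((pred == 0) & (yt == 0)).sum())
        if np.unique(yt).size == 2:
            fold_auc.append(roc_auc(score, yt))
    metrics = confusion_metrics(cm)
    return PerformanceReport(
        auc=float(np.mean(fold_auc)),
        accuracy=metrics["accuracy"],
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        fold_auc=fold_auc,
        confusion=cm,
        seed=config.seed,
        config=config,
    )
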