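"""Leave-one-out classification harness and group comparison.

Evaluates feature tables (graph-theoretic or graph-signal features, one
row per network) with four standard classifiers under leave-one-out
cross-validation, reporting accuracy, sensitivity, specificity, a
threshold-averaged ROC curve with its AUC, and a Wilcoxon rank-sum
comparison of per-group feature values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "FeatureTable",
    "EvalReport",
    "CLASSIFIERS",
    "loo_evaluate",
    "confusion_rates",
    "roc_threshold_averaged",
    "ranksum_compare",
]

CLASSIFIERS = ("linear-svm", "lda", "logistic", "knn")


@dataclass(frozen=True)
class FeatureTable:
    """Per-network feature rows with binary class labels."""

    features: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        x = self.features
        y = np.asarray(self.labels)
        if x.isna().any().any():
            raise ValueError("feature table contains missing values")
        if len(x) != y.size:
            raise ValueError("labels must match feature rows")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ValueError(f"need exactly 2 classes, got {classes.size}")
        if counts.min() < 2:
            raise ValueError("need at least 2 rows per class")
        object.__setattr__(self, "labels", y)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def select(self, columns: list[str]) -> "FeatureTable":
        return FeatureTable(self.features[columns], self.labels)


@dataclass
class EvalReport:
    """Pooled leave-one-out performance of one classifier."""

    classifier: str
    accuracy: float  # percent
    sensitivity: float  # percent
    specificity: float  # percent
    auc: float
    roc: np.ndarray  # (n_points, 2) of (FPR, TPR)
    positive_label: object
    predictions: np.ndarray = field(repr=False, default=None)
    scores: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "roc": self.roc.tolist(),
            "positive_label": str(self.positive_label),
        }


def _make_model(name: str, n_train: int):
    if name == "linear-svm":
        return SVC(kernel="linear", C=1.0)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "logistic":
        return LogisticRegression(max_iter=5000)
    if name == "knn":
        k = 20
        if k >= n_train:
            k = max(1, n_train - 1)
            warnings.warn(f"kNN neighbourhood reduced to k={k} for n_train={n_train}")
        return KNeighborsClassifier(n_neighbors=k, weights="uniform")
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def _decision_scores(model, x: np.ndarray, positive_idx: int) -> np.ndarray:
    """Continuous score increasing with confidence in the positive class."""
    if hasattr(model, "decision_function"):
        s = np.atleast_1d(model.decision_function(x))
        # sklearn orients decision_function toward classes_[1]
        return s if positive_idx == 1 else -s
    return model.predict_proba(x)[:, positive_idx]


def loo_evaluate(
    table: FeatureTable,
    classifier: str = "linear-svm",
    positive_label=None,
    n_thresholds: int | None = 101,
) -> EvalReport:
    """Leave-one-out evaluation of one classifier on one feature table.

    Each row is predicted by a model trained on the remaining rows;
    features are standardized with training-fold mean/SD only (no
    leakage).  Accuracy, sensitivity and specificity are computed from
    the pooled predictions; the ROC is built from the pooled continuous
    decision scores by threshold averaging.
    """
    x = table.features.to_numpy(dtype=float)
    y = table.labels
    classes = table.classes
    if positive_label is None:
        positive_label = classes[1]
    pos_idx = int(np.nonzero(classes == positive_label)[0][0])

    n = len(y)
    preds = np.empty(n, dtype=object)
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        mu = x[mask].mean(axis=0)
        sd = x[mask].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        model = _make_model(classifier, n_train=n - 1)
        model.fit((x[mask] - mu) / sd, y[mask])
        xi = (x[i : i + 1] - mu) / sd
        preds[i] = model.predict(xi)[0]
        local_pos = int(np.nonzero(model.classes_ == positive_label)[0][0])
        scores[i] = _decision_scores(model, xi, local_pos)[0]

    se, sp, acc = confusion_rates(preds, y, positive_label)
    roc, auc = roc_threshold_averaged(
        scores, y == positive_label, n_thresholds=n_thresholds
    )
    return EvalReport(
        classifier=classifier,
        accuracy=acc,
        sensitivity=se,
        specificity=sp,
        auc=auc,
        roc=roc,
        positive_label=positive_label,
        predictions=preds,
        scores=scores,
    )


def confusion_rates(predictions, labels, positive_label) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) in percent from pooled predictions."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    pos = labels == positive_label
    if not pos.any() or pos.all():
        raise ValueError("both classes must appear in the labels")
    tp = np.sum((predictions == positive_label) & pos)
    fn = np.sum((predictions != positive_label) & pos)
    tn = np.sum((predictions != positive_label) & ~pos)
    fp = np.sum((predictions == positive_label) & ~pos)
    se = 100.0 * tp / (tp + fn)
    sp = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / labels.size
    return float(se), float(sp), float(acc)


def roc_threshold_averaged(
    scores: np.ndarray,
    positive: np.ndarray,
    n_thresholds: int | None = 101,
) -> tuple[np.ndarray, float]:
    """Threshold-averaged ROC curve and trapezoidal AUC.

    Thresholds are ``n_thresholds`` evenly spaced quantiles of the score
    distribution (plus ±∞ endpoints); ``None`` uses every distinct score
    (the exact empirical ROC, whose AUC equals the Mann-Whitney U
    statistic divided by n₁n₂).  A sample is called positive when its
    score is ≥ the threshold.  Degenerate (constant) scores yield the
    chance diagonal and AUC 0.5 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    if scores.shape != positive.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = positive.sum()
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if np.ptp(scores) == 0:
        warnings.warn("constant decision scores; ROC is the chance diagonal")
        roc = np.array([[0.0, 0.0], [1.0, 1.0]])
        return roc, 0.5
    if n_thresholds is None:
        thr = np.unique(scores)
    else:
        if n_thresholds < 2:
            raise ValueError("need at least 2 thresholds")
        thr = np.quantile(scores, np.linspace(0.0, 1.0, n_thresholds))
        thr = np.unique(thr)
    thr = np.concatenate(([-np.inf], thr, [np.inf]))
    called = scores[None, :] >= thr[:, None]
    tpr = (called & positive[None, :]).sum(axis=1) / n_pos
    fpr = (called & ~positive[None, :]).sum(axis=1) / n_neg
    order = np.lexsort((tpr, fpr))
    roc = np.column_stack([fpr[order], tpr[order]])
    auc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    return roc, auc


def ranksum_compare(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for small tie-free samples (both n ≤ 25), normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if max(a.size, b.size) <= 25 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        mannwhitneyu(
            a, b, alternative="two-sided", method=method, use_continuity=False
        ).pvalue
    )
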