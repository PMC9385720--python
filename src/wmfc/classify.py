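"""Leave-one-out cross-validated discrimination on bundle mCC features.

Each subject is scored by a linear support-vector machine trained on the
remaining n-1 subjects, with feature standardization fit on the training
fold only.  Hard predictions at the classifier's native decision threshold
give sensitivity and specificity (patients as positive class); the pooled
held-out decision scores give the ROC curve and its area, computed by the
rank (Mann-Whitney) formulation so score ties are handled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC


@dataclass
class FeatureMatrix:
    """Subjects x features with binary class labels (1 = positive/patient)."""

    X: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if not self.feature_names:
            self.feature_names = [f"f{j + 1}" for j in range(self.X.shape[1])]
        if self.X.shape[0] != self.labels.size:
            raise ValueError("one label per subject required")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("one name per feature required")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix must be finite (no missing entries)")
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        counts = np.bincount(self.labels, minlength=2)
        if (counts < 2).any():
            raise ValueError("each class needs >= 2 subjects")


@dataclass
class ClassifierConfig:
    kernel: str = "linear"
    C: float = 1.0


@dataclass
class ClassificationResult:
    scores: np.ndarray        # held-out decision values, one per subject
    predicted: np.ndarray     # held-out hard predictions
    labels: np.ndarray
    sensitivity: float
    specificity: float
    auc: float
    roc_points: np.ndarray    # (n_points, 2) of (FPR, TPR)

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "auc"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} {val} outside [0, 1]")
        pts = np.asarray(self.roc_points, dtype=float)
        if (np.diff(pts, axis=0) < 0).any():
            raise ValueError("ROC points must be monotone non-decreasing")
        if not (np.allclose(pts[0], (0, 0)) and np.allclose(pts[-1], (1, 1))):
            raise ValueError("ROC must start at (0,0) and end at (1,1)")


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formulation.

    Equals the probability that a random positive outscores a random
    negative, with ties counted one-half; identical to trapezoidal
    integration of the empirical ROC over all thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)  # midranks for ties
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Empirical ROC curve: (FPR, TPR) at every distinct score threshold.

    Thresholds sweep from above the maximum score (0, 0) down to below the
    minimum (1, 1); tied scores move together.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels == 1)
    fp = np.cumsum(sorted_labels == 0)
    # keep only the last index of each tied-score run
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    pts = np.column_stack([fp[distinct] / n_neg, tp[distinct] / n_pos])
    return np.vstack([[0.0, 0.0], pts])


def confusion_metrics(
    predicted: np.ndarray, labels: np.ndarray, positive_class: int = 1
) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP)."""
    predicted = np.asarray(predicted)
    labels = np.asarray(labels)
    if predicted.shape != labels.shape:
        raise ValueError("predicted and labels must align")
    pos = labels == positive_class
    neg = ~pos
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present; metrics undefined")
    tp = int(np.sum(pos & (predicted == positive_class)))
    tn = int(np.sum(neg & (predicted != positive_class)))
    return tp / int(pos.sum()), tn / int(neg.sum())


def loocv_classify(
    features: FeatureMatrix,
    classifier_config: ClassifierConfig | None = None,
) -> ClassificationResult:
    """Leave-one-out cross-validated SVM classification.

    For each subject i the classifier is trained on the other n-1 subjects
    (z-scoring fit on that training fold only) and subject i receives a
    held-out decision score and hard prediction.  Feature selection is
    assumed fixed upstream (e.g. by the group comparison); it is not
    re-selected inside folds.
    """
    cfg = classifier_config or ClassifierConfig()
    X, y = features.X, features.labels
    n = X.shape[0]
    if n < 4:
        raise ValueError("LOOCV requires n >= 4")
    scores = np.empty(n)
    predicted = np.empty(n, dtype=int)
    for i in range(n):
        train = np.arange(n) != i
        y_train = y[train]
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"training fold {i} is missing a class")
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel=cfg.kernel, C=cfg.C)
        clf.fit((X[train] - mu) / sd, y_train)
        z = (X[i:i + 1] - mu) / sd
        scores[i] = clf.decision_function(z)[0]
        predicted[i] = clf.predict(z)[0]
    sens, spec = confusion_metrics(predicted, y, positive_class=1)
    return ClassificationResult(
        scores=scores,
        predicted=predicted,
        labels=y.copy(),
        sensitivity=sens,
        specificity=spec,
        auc=roc_auc(scores, y),
        roc_points=roc_points(scores, y),
    )
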