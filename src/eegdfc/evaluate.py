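"""Cross-validated classification and evaluation metrics.

Classifiers follow the GUI nicknames used in the source method: "cubic"
SVM is a degree-3 polynomial kernel (one-vs-one), "fine" k-NN is 1-NN
Euclidean, and the random forest uses 100 trees.  Evaluation metrics:
binary cross-entropy cost, macro precision/sensitivity/F1, plug-in mutual
information, paired t-test, and intra/inter-class distance summaries.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dfc import HistogramFeatures
from .exceptions import DataError
from .features import FeatureTable
from .selection import CombinedFeatureVector

logger = logging.getLogger(__name__)

CLASSIFIERS = ("svm_cubic", "knn_fine", "rf")
_CLIP = 1e-12


@dataclass
class EvaluationReport:
    classifier: str
    accuracy: float
    per_class_tp: np.ndarray
    per_class_fp: np.ndarray
    per_class_fn: np.ndarray
    precision: float
    sensitivity: float
    f1: float
    cost: float
    fold_accuracies: list[float]
    t_test_p: float | None = None
    mi: float | None = None

    def __post_init__(self) -> None:
        for name in ("accuracy", "precision", "sensitivity", "f1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "accuracy": self.accuracy,
            "per_class_tp": [int(v) for v in self.per_class_tp],
            "per_class_fp": [int(v) for v in self.per_class_fp],
            "per_class_fn": [int(v) for v in self.per_class_fn],
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "f1": self.f1,
            "cost": self.cost,
            "fold_accuracies": self.fold_accuracies,
            "t_test_p": self.t_test_p,
            "mi": self.mi,
        }


def _make_classifier(name: str, seed: int):
    if name == "svm_cubic":
        # "cubic" preset: degree-3 polynomial kernel, one-vs-one, with
        # feature standardization as the GUI preset applies
        return make_pipeline(
            StandardScaler(),
            SVC(
                kernel="poly",
                degree=3,
                gamma="scale",
                decision_function_shape="ovo",
                probability=True,
                random_state=seed,
            ),
        )
    if name == "knn_fine":
        return KNeighborsClassifier(n_neighbors=1)
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise DataError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")


def _as_xy(features) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(features, HistogramFeatures):
        return features.counts.astype(float), np.asarray(features.class_labels)
    if isinstance(features, (CombinedFeatureVector, FeatureTable)):
        return features.rows, features.labels()
    X, y = features  # (X, y) tuple fallback
    return np.asarray(X, dtype=float), np.asarray(y)


def crossval_classify(
    features, classifier: str = "svm_cubic", n_folds: int = 10, seed: int = 0
) -> EvaluationReport:
    """Stratified non-overlapping k-fold CV with pooled confusion counts."""
    X, y = _as_xy(features)
    classes = np.unique(y)
    if classes.size < 2:
        raise DataError("cross-validation needs >= 2 classes")
    if X.shape[0] < n_folds:
        raise DataError(f"need >= n_folds={n_folds} observations, got {X.shape[0]}")
    if n_folds == X.shape[0]:  # leave-one-out: stratification is moot
        skf = KFold(n_splits=n_folds)
    else:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    proba = np.zeros((y.size, classes.size))
    fold_accs = []
    for train, test in skf.split(X, y):
        clf = _make_classifier(classifier, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X[train], y[train])
            pred = clf.predict(X[test])
            p = clf.predict_proba(X[test])
        y_pred[test] = pred
        # align predict_proba columns with the global class list
        for j, c in enumerate(clf.classes_):
            proba[test, np.flatnonzero(classes == c)[0]] = p[:, j]
        fold_accs.append(float(np.mean(pred == y[test])))
    tp = np.array([np.sum((y_pred == c) & (y == c)) for c in classes])
    fp = np.array([np.sum((y_pred == c) & (y != c)) for c in classes])
    fn = np.array([np.sum((y_pred != c) & (y == c)) for c in classes])
    precision, sensitivity, f1 = precision_sensitivity_f1(tp, fp, fn)
    onehot = (y[:, None] == classes[None, :]).astype(float)
    return EvaluationReport(
        classifier=classifier,
        accuracy=float(np.mean(y_pred == y)),
        per_class_tp=tp,
        per_class_fp=fp,
        per_class_fn=fn,
        precision=precision,
        sensitivity=sensitivity,
        f1=f1,
        cost=cost_entropy(onehot, proba),
        fold_accuracies=fold_accs,
    )


def cost_entropy(targets: np.ndarray, actual: np.ndarray) -> float:
    """Mean (per sample) binary cross-entropy between one-hot targets and
    predicted probabilities, probabilities clipped to [1e-12, 1 - 1e-12]."""
    t = np.asarray(targets, dtype=float)
    a = np.asarray(actual, dtype=float)
    if t.shape != a.shape:
        raise DataError(f"targets shape {t.shape} != actual shape {a.shape}")
    t = np.atleast_2d(t)
    a = np.clip(np.atleast_2d(a), _CLIP, 1.0 - _CLIP)
    per_sample = -(t * np.log(a) + (1.0 - t) * np.log(1.0 - a)).sum(axis=1)
    return float(per_sample.mean())


def precision_sensitivity_f1(tp, fp, fn) -> tuple[float, float, float]:
    """Macro-averaged precision P, sensitivity S and F1 = 2PS/(P+S).

    Per-class 0/0 ratios count as 0 (logged); F1 is 0 when P + S = 0.
    """
    tp = np.asarray(tp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    fn = np.asarray(fn, dtype=float)
    if np.any(tp < 0) or np.any(fp < 0) or np.any(fn < 0):
        raise DataError("confusion counts must be >= 0")

    def _macro(num, denom, label):
        out = np.zeros_like(num)
        ok = denom > 0
        out[ok] = num[ok] / denom[ok]
        if not np.all(ok):
            logger.warning("%s: %d class(es) with empty denominator -> 0", label, (~ok).sum())
        return float(out.mean())

    precision = _macro(tp, tp + fp, "precision")
    sensitivity = _macro(tp, tp + fn, "sensitivity")
    f1 = 0.0 if precision + sensitivity == 0 else 2.0 * precision * sensitivity / (
        precision + sensitivity
    )
    return precision, sensitivity, f1


def mutual_information(X, Y, n_bins: int = 8) -> float:
    """Plug-in MI (nats) from the joint equal-width histogram; >= 0, symmetric."""
    x = np.asarray(X, dtype=float).ravel()
    y = np.asarray(Y, dtype=float).ravel()
    if x.size != y.size:
        raise DataError("X and Y must have equal length")
    if x.size < n_bins * n_bins:
        raise DataError(f"need >= n_bins^2 = {n_bins * n_bins} samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("degenerate (constant) input to mutual_information -> 0")
        return 0.0
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    total = joint.sum()
    pxy = joint / total
    # marginals from integer counts: exact sums, so symmetry is bitwise
    px = joint.sum(axis=1, keepdims=True) / total
    py = joint.sum(axis=0, keepdims=True) / total
    nz = pxy > 0
    # math.fsum is exactly associative, so MI(X,Y) == MI(Y,X) bit-for-bit
    mi = math.fsum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz]))
    return max(mi, 0.0)


def binned_entropy(X, n_bins: int = 8) -> float:
    """Shannon entropy (nats) of the equal-width binned distribution of X."""
    x = np.asarray(X, dtype=float).ravel()
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def paired_ttest(scores_a, scores_b) -> float:
    """Two-sided paired t-test p-value; NaN when differences have zero variance."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise DataError("paired_ttest needs equal lengths >= 2")
    d = a - b
    if np.allclose(d, d[0]):
        logger.warning("zero-variance differences: paired t-test undefined")
        return float("nan")
    return float(stats.ttest_rel(a, b).pvalue)


@dataclass
class ClassDistanceReport:
    intra_distance: float
    inter_distance: float
    intra_pearson: float
    inter_pearson: float


def class_distance_report(features, labels) -> ClassDistanceReport:
    """Mean pairwise Euclidean distance and Pearson r, within vs between classes."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise DataError("need >= 2 classes")
    n = X.shape[0]
    d = np.sqrt(
        np.maximum(
            np.sum(X * X, axis=1)[:, None]
            - 2.0 * X @ X.T
            + np.sum(X * X, axis=1)[None, :],
            0.0,
        )
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X) if X.shape[1] > 1 else np.full((n, n), np.nan)
    same = y[:, None] == y[None, :]
    iu = np.triu_indices(n, k=1)
    intra_mask = same[iu]
    intra_d = d[iu][intra_mask]
    inter_d = d[iu][~intra_mask]
    intra_r = r[iu][intra_mask]
    inter_r = r[iu][~intra_mask]

    def _mean(v):
        v = v[np.isfinite(v)]
        return float(v.mean()) if v.size else float("nan")

    return ClassDistanceReport(
        intra_distance=_mean(intra_d),
        inter_distance=_mean(inter_d),
        intra_pearson=_mean(intra_r),
        inter_pearson=_mean(inter_r),
    )
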