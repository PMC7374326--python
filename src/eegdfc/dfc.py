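"""Deep Feature Clustering: per-class k-means vocabulary + histogram features.

The vocabulary is built by running k-means separately on each class's
feature rows and stacking the centers class-by-class, giving exactly
k_per_class x n_classes centers.  Observations are then summarized per
(subject, trial) unit as a histogram of nearest-center assignments — the
final, heavily reduced feature vector used for classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .exceptions import DataError
from .features import FeatureTable
from .selection import CombinedFeatureVector

DEFAULT_K = 10


@dataclass
class Vocabulary:
    k_per_class: int
    n_classes: int
    centers: np.ndarray  # (k_per_class * n_classes, n_features)
    center_class: np.ndarray  # class label per center
    sse: float
    seed: int

    def __post_init__(self) -> None:
        if self.centers.shape[0] != self.k_per_class * self.n_classes:
            raise DataError("number of centers must be k_per_class * n_classes")
        if len(self.center_class) != self.centers.shape[0]:
            raise DataError("center_class must parallel centers")
        if self.sse < 0:
            raise DataError("sse must be >= 0")

    @property
    def size(self) -> int:
        return self.centers.shape[0]


@dataclass
class HistogramFeatures:
    counts: np.ndarray  # (n_units, vocabulary_size), non-negative ints
    unit_keys: list[tuple]  # (subject, trial)
    class_labels: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if np.any(c < 0):
            raise DataError("counts must be non-negative")
        if len(self.unit_keys) != c.shape[0] or len(self.class_labels) != c.shape[0]:
            raise DataError("unit_keys and class_labels must parallel counts rows")
        self.counts = c.astype(int)

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    def normalized(self) -> np.ndarray:
        """L1-normalized counts (rows with zero mass stay zero)."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        sums[sums == 0] = 1.0
        return self.counts / sums


def _rows_and_labels(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, (CombinedFeatureVector, FeatureTable)):
        return data.rows, data.labels()
    raise DataError("expected a CombinedFeatureVector or FeatureTable")


def build_vocabulary(
    cfv, k_per_class: int = DEFAULT_K, seed: int = 0, n_init: int = 10
) -> Vocabulary:
    """Per-class k-means; centers stacked class-by-class; SSE totalled.

    Raises if any class has fewer rows than ``k_per_class``.
    """
    rows, labels = _rows_and_labels(cfv)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise DataError("vocabulary needs >= 2 classes")
    if k_per_class < 1:
        raise DataError("k_per_class must be >= 1")
    centers, center_class = [], []
    sse = 0.0
    for ci, c in enumerate(classes):
        class_rows = rows[labels == c]
        if class_rows.shape[0] < k_per_class:
            raise DataError(
                f"class {c!r} has {class_rows.shape[0]} rows < k_per_class={k_per_class}"
            )
        km = KMeans(
            n_clusters=k_per_class,
            n_init=n_init,
            max_iter=300,
            random_state=seed + ci,
        ).fit(class_rows)
        centers.append(km.cluster_centers_)
        center_class.extend([c] * k_per_class)
        sse += float(km.inertia_)
    return Vocabulary(
        k_per_class=k_per_class,
        n_classes=len(classes),
        centers=np.vstack(centers),
        center_class=np.asarray(center_class),
        sse=sse,
        seed=seed,
    )


def sweep_k(cfv, k_values, seed: int = 0, n_init: int = 10) -> dict[int, float]:
    """Total within-cluster SSE per candidate k (elbow report)."""
    return {
        int(k): build_vocabulary(cfv, k_per_class=int(k), seed=seed, n_init=n_init).sse
        for k in k_values
    }


def assign_to_centers(rows: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest center per row (Euclidean; ties break to the lowest index)."""
    if rows.shape[1] != centers.shape[1]:
        raise DataError(
            f"feature dimension {rows.shape[1]} != vocabulary dimension {centers.shape[1]}"
        )
    # ||r - c||^2 = ||r||^2 - 2 r.c + ||c||^2; argmin over exact distances to
    # keep tie-breaking faithful on small inputs
    d2 = (
        np.sum(rows * rows, axis=1)[:, None]
        - 2.0 * rows @ centers.T
        + np.sum(centers * centers, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def histogram_features(
    vocab: Vocabulary, features, unit: str = "subject_trial"
) -> HistogramFeatures:
    """Counts of vocabulary usage per (subject, trial) unit.

    Row sums equal the number of feature rows contributed by each unit.
    """
    if unit != "subject_trial":
        raise DataError(f"unsupported histogram unit {unit!r}")
    if isinstance(features, (CombinedFeatureVector, FeatureTable)):
        rows, keys = features.rows, features.keys
    else:
        raise DataError("expected a CombinedFeatureVector or FeatureTable")
    assignment = assign_to_centers(rows, vocab.centers)
    unit_keys = sorted({(k[0], k[1]) for k in keys})
    unit_index = {u: i for i, u in enumerate(unit_keys)}
    counts = np.zeros((len(unit_keys), vocab.size), dtype=int)
    unit_label: dict = {}
    for row_i, key in enumerate(keys):
        u = (key[0], key[1])
        counts[unit_index[u], assignment[row_i]] += 1
        if u in unit_label and unit_label[u] != key[4]:
            raise DataError(f"unit {u} carries conflicting class labels")
        unit_label[u] = key[4]
    return HistogramFeatures(
        counts=counts,
        unit_keys=unit_keys,
        class_labels=np.asarray([unit_label[u] for u in unit_keys]),
    )
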