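"""Chi-square nearest-neighbour classification and cross-validation.

Texture histograms are compared with the chi-square distance

    D(X, Y) = sum_i (X_i - Y_i)^2 / (X_i + Y_i)

(terms with a zero denominator contribute zero, the usual convention
for sparse histograms).  A query is assigned the label of the training
exemplar at minimum distance; ties go to the lowest training index.
Accuracy is the plain percentage of correct detections, and k-fold
evaluation uses a seeded stratified random partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .core import FeatureVector

__all__ = [
    "LabeledDataset",
    "chi_square_distance",
    "chi_square_matrix",
    "nearest_neighbor",
    "classify_all",
    "accuracy",
    "cross_validate",
]


def _as_matrix(vectors) -> np.ndarray:
    rows = [
        v.values if isinstance(v, FeatureVector) else np.asarray(v, dtype=float)
        for v in vectors
    ]
    lengths = {r.size for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent feature lengths {sorted(lengths)}")
    return np.vstack(rows)


@dataclass
class LabeledDataset:
    """Feature matrix plus class labels, the classifier's input unit."""

    features: np.ndarray
    labels: np.ndarray

    def __init__(self, features, labels):
        self.features = _as_matrix(features)
        self.labels = np.asarray(labels)
        if self.features.shape[0] != self.labels.size:
            raise ValueError("feature/label count mismatch")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def n_classes(self) -> int:
        return np.unique(self.labels).size


def chi_square_distance(x, y) -> float:
    """Chi-square distance between two non-negative histograms."""
    x = x.values if isinstance(x, FeatureVector) else np.asarray(x, dtype=float)
    y = y.values if isinstance(y, FeatureVector) else np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("histogram entries must be non-negative")
    denom = x + y
    num = (x - y) ** 2
    return float(np.divide(num, denom, out=np.zeros_like(num), where=denom > 0).sum())


def chi_square_matrix(queries: np.ndarray, train: np.ndarray) -> np.ndarray:
    """Pairwise chi-square distances, queries along rows."""
    q = queries[:, None, :]
    t = train[None, :, :]
    denom = q + t
    num = (q - t) ** 2
    return np.divide(num, denom, out=np.zeros_like(num), where=denom > 0).sum(axis=2)


def nearest_neighbor(train: LabeledDataset, query) -> object:
    """Label of the chi-square-nearest training exemplar (first index on ties)."""
    if len(train) == 0:
        raise ValueError("empty training set")
    q = query.values if isinstance(query, FeatureVector) else np.asarray(query, dtype=float)
    d = chi_square_matrix(q[None, :], train.features)[0]
    return train.labels[int(np.argmin(d))]


def classify_all(train: LabeledDataset, queries) -> np.ndarray:
    """Vectorised nearest-neighbour labels for a batch of queries."""
    if len(train) == 0:
        raise ValueError("empty training set")
    q = _as_matrix(queries)
    d = chi_square_matrix(q, train.features)
    return train.labels[np.argmin(d, axis=1)]


def accuracy(predicted: Sequence, actual: Sequence) -> float:
    """Percentage of correct detections in [0, 100]."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    return float(100.0 * (predicted == actual).mean())


def cross_validate(data: LabeledDataset, k: int = 10, seed: int = 0) -> np.ndarray:
    """Seeded stratified k-fold nearest-neighbour accuracies (percent).

    Each class must contribute at least k items so every fold holds a
    stratified sample; per-class fold sizes then differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels, counts = np.unique(data.labels, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least two classes")
    small = labels[counts < k]
    if small.size:
        raise ValueError(f"classes {small.tolist()} have fewer than {k} items")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(data.features, data.labels):
        train = LabeledDataset(data.features[train_idx], data.labels[train_idx])
        pred = classify_all(train, data.features[test_idx])
        accs.append(accuracy(pred, data.labels[test_idx]))
    return np.asarray(accs)
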