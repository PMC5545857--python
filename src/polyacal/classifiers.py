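"""Built-in k-means discriminant scorer.

Deliberately marginal classifier: cluster the training set into two groups,
label each cluster by majority vote, and score a new point by the ratio of
its distances to the two class centroids.  The resulting score
distributions are highly non-Gaussian and strongly overlapping, which is
exactly the regime where calibration granularity matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

__all__ = ["KMeansDiscriminant", "train_kmeans_discriminant", "score_kmeans",
           "KMeansDiscriminantScorer"]

_ZERO_DISTANCE_CAP = 1e6


@dataclass(frozen=True)
class KMeansDiscriminant:
    """Two class-labelled centroids; lower scores favour class 1."""

    centroid_class1: np.ndarray
    centroid_class2: np.ndarray


def train_kmeans_discriminant(
    features: np.ndarray, labels: np.ndarray, seed: int = 0
) -> KMeansDiscriminant:
    """Cluster with k=2 and assign class labels to centroids by majority.

    The cluster with the higher fraction of class-1 members becomes the
    class-1 centroid; an exact tie breaks toward the lower cluster index.
    Labels may be coded {0, 1} or {1, 2}; the smaller-coded positive class
    is class 1 (label 1).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be 2-D with one row per labelled subject")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if np.all(X == X[0]):
        raise ValueError("degenerate clustering")
    pos = _positive_mask(y)

    km = KMeans(n_clusters=2, n_init=4, random_state=seed).fit(X)
    frac1 = np.array([
        pos[km.labels_ == c].mean() if np.any(km.labels_ == c) else 0.0
        for c in (0, 1)
    ])
    c1 = 0 if frac1[0] >= frac1[1] else 1
    return KMeansDiscriminant(
        centroid_class1=km.cluster_centers_[c1].copy(),
        centroid_class2=km.cluster_centers_[1 - c1].copy(),
    )


def _positive_mask(y: np.ndarray) -> np.ndarray:
    vals = set(np.unique(y).tolist())
    if vals <= {0, 1}:
        return y == 1
    if vals <= {1, 2}:
        return y == 1
    raise ValueError(f"labels must be binary ({{0,1}} or {{1,2}}), got {sorted(vals)}")


def score_kmeans(model: KMeansDiscriminant, x: np.ndarray) -> float:
    """Distance-ratio score d(x, centroid_1) / d(x, centroid_2).

    Euclidean distances; a zero denominator returns the cap 1e6.  Scores
    below 1 favour class 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != model.centroid_class1.size:
        raise ValueError("feature dimension mismatch")
    d1 = float(np.linalg.norm(x - model.centroid_class1))
    d2 = float(np.linalg.norm(x - model.centroid_class2))
    if d2 == 0.0:
        return _ZERO_DISTANCE_CAP
    return d1 / d2


class KMeansDiscriminantScorer:
    """Trainable-scorer adaptor for the cross-validation driver.

    Note the sign convention: the raw distance ratio is small for
    class-1-like points, so the positive class sits at the low end of the
    score axis.
    """

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._model: KMeansDiscriminant | None = None

    def train(self, features: np.ndarray, labels: np.ndarray) -> "KMeansDiscriminantScorer":
        self._model = train_kmeans_discriminant(features, labels, seed=self.seed)
        return self

    def score(self, x: np.ndarray) -> float:
        if self._model is None:
            raise RuntimeError("scorer not trained")
        return score_kmeans(self._model, x)
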