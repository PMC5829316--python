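"""From-scratch K-Means on the squared-Euclidean clustering objective.

The objective is the total within-cluster sum of squared distances

    D(C) = sum_i  min_j || x_i - C_j ||^2 ,

minimised by alternating nearest-center assignment with centroid updates
(center = mean of its assigned points) until the assignment reaches a fixed
point. This is the comparison baseline for the genetic-algorithm clusterer,
which minimises the same D by evolutionary search.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin

from .features import FeatureMatrix
from .model import ClusterModel

__all__ = [
    "euclidean_distance",
    "assign",
    "total_within_cluster_distance",
    "KMeansClusterer",
    "kmeans_fit",
]


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance between two p-vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.sum((x - y) ** 2)))


def _check_dims(X: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if X.shape[1] != centers.shape[1]:
        raise ValueError(
            f"data has {X.shape[1]} features but centers have {centers.shape[1]}"
        )
    return X, centers


def assign(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Label each point with its nearest center (0-based).

    Ties go to the lowest center index.
    """
    X, centers = _check_dims(X, centers)
    return np.argmin(cdist(X, centers, metric="sqeuclidean"), axis=1)


def total_within_cluster_distance(X: np.ndarray, centers: np.ndarray) -> float:
    """Total squared distance of each point to its nearest center."""
    X, centers = _check_dims(X, centers)
    return float(np.min(cdist(X, centers, metric="sqeuclidean"), axis=1).sum())


class KMeansClusterer(ClusterMixin, BaseEstimator):
    """Lloyd-style K-Means estimator.

    Parameters
    ----------
    n_clusters : int, default=3
        Number of clusters K.
    n_init : int, default=10
        Independent restarts; the run with the lowest final objective wins.
        Lloyd's iteration only finds a local optimum, so restarting from
        different initial centers is the standard guard.
    max_iter : int, default=300
        Iteration cap per restart.
    tol : float, default=0.0
        Minimum objective improvement to keep iterating; 0 demands an exact
        assignment fixed point.
    random_state : int or None
        Seed for the single random stream driving every restart's
        initialisation draw (K distinct data points, uniform without
        replacement).

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters, p)
    labels_ : ndarray of shape (N,), 0-based
    inertia_ : float
        Final objective D.
    n_iter_ : int
    converged_ : bool
    objective_trace_ : list of float
        Objective after each assignment step; non-increasing.
    """

    def __init__(self, n_clusters=3, n_init=10, max_iter=300, tol=0.0, random_state=None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty 2-D array")
        n, _ = X.shape
        k = self.n_clusters
        if k < 1 or k > n:
            raise ValueError(f"n_clusters must be in [1, {n}], got {k}")
        if self.n_init < 1:
            raise ValueError("n_init must be at least 1")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init):
            run = self._single_run(X, k, rng)
            if best is None or run[2] < best[2]:
                best = run
        centers, labels, inertia, n_iter, converged, trace = best
        self.cluster_centers_ = centers
        self.labels_ = labels
        self.inertia_ = inertia
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.objective_trace_ = trace
        return self

    def _single_run(self, X, k, rng):
        n = X.shape[0]
        centers = X[rng.choice(n, size=k, replace=False)].copy()
        labels = assign(X, centers)
        trace = [total_within_cluster_distance(X, centers)]
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            for j in range(k):
                members = X[labels == j]
                if len(members):
                    centers[j] = members.mean(axis=0)
                else:
                    centers[j] = self._farthest_point(X, centers)
            new_labels = assign(X, centers)
            trace.append(total_within_cluster_distance(X, centers))
            if np.array_equal(new_labels, labels):
                converged = True
                labels = new_labels
                break
            if self.tol > 0 and trace[-2] - trace[-1] <= self.tol:
                labels = new_labels
                converged = True
                break
            labels = new_labels
        return centers, labels, trace[-1], n_iter, converged, trace

    @staticmethod
    def _farthest_point(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
        # empty-cluster repair: re-seed at the worst-covered point
        d = np.min(cdist(X, centers, metric="sqeuclidean"), axis=1)
        return X[int(np.argmax(d))].copy()

    def predict(self, X):
        return assign(X, self.cluster_centers_)

    def score(self, X, y=None):
        return -total_within_cluster_distance(X, self.cluster_centers_)


def kmeans_fit(
    data: FeatureMatrix | np.ndarray,
    k: int,
    seed: int | None = None,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 0.0,
) -> ClusterModel:
    """Fit K-Means and package the result as a :class:`ClusterModel`."""
    fm = data if isinstance(data, FeatureMatrix) else None
    X = data.values if fm is not None else np.asarray(data, dtype=float)
    est = KMeansClusterer(
        n_clusters=k, n_init=n_init, max_iter=max_iter, tol=tol, random_state=seed
    ).fit(X)
    return ClusterModel(
        centers=est.cluster_centers_,
        k=k,
        objective=est.inertia_,
        n_iterations=est.n_iter_,
        converged=est.converged_,
        method="km",
        seed=seed,
        labels=est.labels_ + 1,
        centers_original=(
            fm.to_original_units(est.cluster_centers_) if fm is not None else None
        ),
        feature_names=fm.feature_names if fm is not None else None,
    )
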