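"""K-means discretization of tICA space into microstates.

A thin, deterministic wrapper around scikit-learn's Lloyd K-means with
k-means++ initialization from a fixed seed (single init). Assignment ties are
broken by the lowest center index, and per-trajectory label sequences retain
trajectory boundaries, as required by MSM counting and adaptive sampling.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .containers import FeatureMatrix

__all__ = ["MicrostateKMeans", "fit_kmeans", "assign"]


def _pool(X):
    """Return (pooled array, per-trajectory lengths or None)."""
    if isinstance(X, FeatureMatrix):
        return X.values, None
    if isinstance(X, np.ndarray):
        return np.asarray(X, dtype=float), None
    arrays = [
        item.values if isinstance(item, FeatureMatrix) else np.asarray(item, float)
        for item in X
    ]
    return np.vstack(arrays), [a.shape[0] for a in arrays]


class MicrostateKMeans(BaseEstimator, ClusterMixin):
    """Seeded K-means microstate model.

    Parameters
    ----------
    n_clusters : int
        Number of microstates (k). The adaptive-sampling controller ships
        with 100.
    random_state : int
        Seed of the single k-means++ initialization; identical inputs and
        seed yield identical centers.
    """

    def __init__(self, n_clusters: int = 100, random_state: int = 0,
                 max_iter: int = 300, tol: float = 1e-6):
        self.n_clusters = n_clusters
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        data, lengths = _pool(X)
        if not np.isfinite(data).all():
            raise ValueError("non-finite data")
        if data.shape[0] < self.n_clusters:
            raise ValueError(
                f"{data.shape[0]} frames < n_clusters={self.n_clusters}"
            )
        km = KMeans(
            n_clusters=self.n_clusters,
            init="k-means++",
            n_init=1,
            algorithm="lloyd",
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
        ).fit(data)
        self.cluster_centers_ = km.cluster_centers_
        self.inertia_ = km.inertia_
        # recompute labels through our own tie rule (lowest index wins)
        self.labels_ = self.predict(data)
        self._lengths = lengths
        return self

    def predict(self, X):
        """Nearest-center labels (0-based); ties go to the lowest index.

        List input returns one label array per trajectory.
        """
        data, lengths = _pool(X)
        if data.shape[0] == 0:
            labels = np.empty(0, dtype=int)
        else:
            if data.shape[1] != self.cluster_centers_.shape[1]:
                raise ValueError(
                    f"data dimension {data.shape[1]} != centers dimension "
                    f"{self.cluster_centers_.shape[1]}"
                )
            d2 = (
                (data ** 2).sum(1)[:, None]
                - 2 * data @ self.cluster_centers_.T
                + (self.cluster_centers_ ** 2).sum(1)[None, :]
            )
            # exact distances for tie stability
            d = np.sqrt(np.maximum(
                ((data[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(-1),
                0,
            )) if data.shape[0] * self.cluster_centers_.shape[0] <= 2_000_000 else None
            labels = (np.argmin(d, axis=1) if d is not None
                      else np.argmin(d2, axis=1))
        if lengths is None:
            return labels
        out, start = [], 0
        for ln in lengths:
            out.append(labels[start:start + ln])
            start += ln
        return out

    def fit_predict(self, X, y=None):
        self.fit(X)
        return self.predict(X)


def fit_kmeans(data, k: int, seed: int = 0, max_iter: int = 300,
               tol: float = 1e-6) -> MicrostateKMeans:
    return MicrostateKMeans(n_clusters=k, random_state=seed,
                            max_iter=max_iter, tol=tol).fit(data)


def assign(model: MicrostateKMeans, data):
    return model.predict(data)
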