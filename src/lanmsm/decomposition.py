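"""Time-lagged independent component analysis (tICA).

tICA finds linear combinations of input features that are maximally
autocorrelated at a chosen lag: it solves the generalized symmetric
eigenproblem

    C_tau v = lambda C_0 v,

where C_0 is the instantaneous covariance (regularized on the diagonal) and
C_tau the symmetrized time-lagged covariance, with lagged pairs pooled within
(never across) trajectories after mean removal. Eigenvalues approximate the
lag-tau autocorrelation of the projected coordinates, so the leading
components (tICs) are the slowest linear collective coordinates of the data —
the standard dimensionality reduction preceding microstate clustering in
Markov-state-model building.

Components are scaled so that projected coordinates have unit instantaneous
variance (no kinetic-map scaling).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import FeatureMatrix

__all__ = ["TICA", "fit_tica", "feature_tic_correlation"]

DEFAULT_TICA_LAG = 10


def _as_arrays(X):
    """Normalize input to (list of 2-D arrays, feature names or None)."""
    if isinstance(X, FeatureMatrix):
        X = [X]
    elif isinstance(X, np.ndarray) and X.ndim == 2:
        X = [X]
    arrays, names = [], None
    for item in X:
        if isinstance(item, FeatureMatrix):
            if names is None:
                names = item.feature_names
            elif item.feature_names != names:
                diff = sorted(
                    set(item.feature_names).symmetric_difference(names)
                )
                raise ValueError(f"feature names differ across inputs: {diff}")
            arrays.append(item.values)
        else:
            arrays.append(np.asarray(item, dtype=float))
    return arrays, names


class TICA(BaseEstimator, TransformerMixin):
    """Time-lagged independent component analysis.

    Parameters
    ----------
    lag : int
        Lag time in frames for the time-lagged covariance.
    n_components : int
        Number of components (tICs) to keep.
    regularization : float or None
        Scalar added to the diagonal of the instantaneous covariance;
        ``None`` uses ``1e-6 * trace(C0)/dim``.

    Attributes
    ----------
    mean_ : per-feature mean over all frames.
    eigenvalues_ : descending autocorrelations, in (-1, 1] up to noise.
    components_ : (n_components, n_features) projection vectors, orthonormal
        in the metric of the instantaneous covariance.
    """

    def __init__(self, lag: int = DEFAULT_TICA_LAG, n_components: int = 2,
                 regularization: float | None = None):
        self.lag = lag
        self.n_components = n_components
        self.regularization = regularization

    def fit(self, X, y=None):
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        arrays, names = _as_arrays(X)
        shortest = min(a.shape[0] for a in arrays)
        if self.lag >= shortest:
            raise ValueError(
                f"lag {self.lag} must be shorter than the shortest trajectory "
                f"({shortest} frames)"
            )
        dim = arrays[0].shape[1]
        if self.n_components > dim:
            raise ValueError("n_components exceeds feature count")

        n_frames = sum(a.shape[0] for a in arrays)
        mean = sum(a.sum(axis=0) for a in arrays) / n_frames
        c0 = np.zeros((dim, dim))
        ct = np.zeros((dim, dim))
        n_pairs = 0
        for a in arrays:
            b = a - mean
            c0 += b.T @ b
            x, y_ = b[:-self.lag], b[self.lag:]
            ct += x.T @ y_
            n_pairs += x.shape[0]
        c0 /= n_frames
        ct /= n_pairs
        ct = 0.5 * (ct + ct.T)  # symmetrize: reversible-dynamics assumption

        reg = self.regularization
        if reg is None:
            reg = 1e-6 * np.trace(c0) / dim
        if reg < 0:
            raise ValueError("regularization must be non-negative")
        if reg == 0 and np.linalg.matrix_rank(c0) < dim:
            raise ValueError(
                "instantaneous covariance is rank-deficient; "
                "use a positive regularization"
            )
        c0r = c0 + reg * np.eye(dim)

        evals, evecs = scipy.linalg.eigh(ct, c0r)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        # eigh returns b-orthonormal vectors: v.T @ C0r @ v = I, which is the
        # unit-instantaneous-variance normalization of the projections.
        self.mean_ = mean
        self.eigenvalues_ = evals[: self.n_components]
        self.components_ = evecs[:, : self.n_components].T
        self.n_features_in_ = dim
        self.feature_names_in_ = names
        self.regularization_ = reg
        self.n_pairs_ = n_pairs
        return self

    def transform(self, X) -> np.ndarray | FeatureMatrix:
        """Project features onto the tICs (mean-removed).

        A FeatureMatrix input returns a FeatureMatrix with columns named
        tIC1, tIC2, ...; arrays return arrays.
        """
        if isinstance(X, FeatureMatrix):
            if (
                self.feature_names_in_ is not None
                and X.feature_names != self.feature_names_in_
            ):
                diff = [
                    f"{a!r} != {b!r}"
                    for a, b in zip(X.feature_names, self.feature_names_in_)
                    if a != b
                ]
                raise ValueError(f"feature mismatch: {diff}")
            y = (X.values - self.mean_) @ self.components_.T
            return FeatureMatrix(
                y, [f"tIC{i + 1}" for i in range(y.shape[1])], X.source_id
            )
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"input has {X.shape[1]} features, model expects "
                f"{self.n_features_in_}"
            )
        return (X - self.mean_) @ self.components_.T


def fit_tica(features, lag: int = DEFAULT_TICA_LAG, n_components: int = 2,
             regularization: float | None = None) -> TICA:
    """Functional wrapper over :class:`TICA`."""
    return TICA(lag=lag, n_components=n_components,
                regularization=regularization).fit(features)


def feature_tic_correlation(model: TICA, features) -> pd.DataFrame:
    """Pearson correlation between each input feature and each tIC.

    Pools frames across the given trajectories. Zero-variance features get
    correlation 0 with a warning.
    """
    arrays, names = _as_arrays(features)
    X = np.vstack(arrays)
    Y = model.transform(X)
    if names is None:
        names = [f"f{i}" for i in range(X.shape[1])]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = Xc.std(axis=0)
    sy = Yc.std(axis=0)
    zero = sx == 0
    if zero.any():
        warnings.warn(
            f"zero-variance features reported with correlation 0: "
            f"{[names[i] for i in np.flatnonzero(zero)]}"
        )
    sx = np.where(zero, 1.0, sx)
    corr = (Xc.T @ Yc) / X.shape[0] / np.outer(sx, sy)
    corr[zero, :] = 0.0
    return pd.DataFrame(
        corr, index=names,
        columns=[f"tIC{i + 1}" for i in range(Y.shape[1])],
    )
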