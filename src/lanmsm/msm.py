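"""Markov state model estimation, implied timescales, and VAMP-2 scoring.

A Markov state model (MSM) approximates the conformational dynamics by a
row-stochastic transition matrix T between discrete microstates at a lag time
tau; T_ij is the probability of transitioning from state i to state j within
one lag. Estimation here:

1. Transition counting (sliding or strided) within each trajectory, never
   across trajectory boundaries.
2. Ergodic trimming to the largest strongly connected component of the
   directed count graph; frames in trimmed states receive zero weight
   downstream.
3. Either a non-reversible estimate (row-normalized counts, stationary
   distribution = leading left eigenvector) or — the default — the maximum
   likelihood reversible estimate under detailed balance
   (pi_i T_ij = pi_j T_ji), obtained by the standard self-consistent
   fixed-point iteration on the unnormalized symmetric flux matrix.

The stationary distribution pi of the MSM reweights adaptively sampled frames
back to equilibrium. Relaxation is summarized by implied timescales
t_k(tau) = -tau / ln lambda_k(tau); Markovianity of the discretization is
judged by their convergence in tau. Model quality across hyperparameters
(number of tICs, number of clusters) is compared with the VAMP-2 score, the
sum of squared leading transition-matrix eigenvalues, cross-validated at
trajectory granularity.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

from .cluster import MicrostateKMeans
from .containers import FeatureMatrix
from .decomposition import TICA

__all__ = [
    "MarkovStateModel",
    "count_matrix",
    "estimate_msm",
    "implied_timescales",
    "ImpliedTimescaleTable",
    "select_lag",
    "vamp2_score",
    "cross_validated_vamp2",
]

DEFAULT_VAMP2_K = 6  # number of eigenvalues in the score, unit eigenvalue included
DEFAULT_CV_FOLDS = 10

_token_counter = itertools.count()


def count_matrix(dtrajs, lag: int, n_states: int | None = None,
                 mode: str = "sliding") -> np.ndarray:
    """Transition count matrix at the given lag.

    ``sliding`` counts every pair (s_t, s_{t+lag}); ``strided`` only
    t = 0, lag, 2 lag, ... No pairs cross trajectory boundaries.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if mode not in ("sliding", "strided"):
        raise ValueError(f"unknown counting mode {mode!r}")
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    if n_states is None:
        n_states = max((int(d.max()) + 1 for d in dtrajs if d.size), default=0)
    C = np.zeros((n_states, n_states))
    any_pair = False
    for d in dtrajs:
        if d.size <= lag:
            continue
        a, b = d[:-lag], d[lag:]
        if mode == "strided":
            a, b = a[::lag], b[::lag]
        np.add.at(C, (a, b), 1)
        any_pair = True
    if not any_pair:
        raise ValueError(f"lag {lag} is >= the length of every trajectory")
    return C


def _largest_scc(C: np.ndarray) -> np.ndarray:
    """States of the largest strongly connected component of the count graph
    (ties broken by total counts, then lowest state index)."""
    n = C.shape[0]
    n_comp, labels = connected_components(
        csr_matrix(C > 0), directed=True, connection="strong"
    )
    best = None
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        if not C[np.ix_(members, members)].sum() and members.size == 1:
            # isolated state without a self-transition carries no dynamics
            if C[members[0], members[0]] == 0:
                continue
        key = (members.size, C[np.ix_(members, members)].sum(), -members[0])
        if best is None or key > best[0]:
            best = (key, members)
    if best is None:
        raise ValueError("count matrix has no connected set with transitions")
    return best[1]


def _reversible_mle(C: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000):
    """Maximum-likelihood reversible transition matrix.

    Self-consistent fixed-point iteration on the symmetric flux x_ij:
        x_ij <- (C_ij + C_ji) / (c_i / x_i + c_j / x_j),
    converged when the stationary distribution changes by < tol in max-norm.
    """
    c_row = C.sum(axis=1)
    if (c_row == 0).any():
        raise ValueError("reversible MLE requires every state to have counts")
    X = C + C.T
    x_row = X.sum(axis=1)
    pi = x_row / x_row.sum()
    sym = C + C.T
    for iteration in range(1, max_iter + 1):
        denom = (c_row / x_row)[:, None] + (c_row / x_row)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            X = np.where(sym > 0, sym / denom, 0.0)
        x_row = X.sum(axis=1)
        pi_new = x_row / x_row.sum()
        delta = np.abs(pi_new - pi).max()
        pi = pi_new
        if delta < tol:
            T = X / x_row[:, None]
            return T, pi
    raise RuntimeError(
        f"reversible MLE did not converge within {max_iter} iterations "
        f"(last max-norm change {delta:.3e})"
    )


class MarkovStateModel(BaseEstimator):
    """Maximum-likelihood Markov state model estimator.

    Parameters
    ----------
    lag : int
        Lag time in frames.
    reversible : bool
        Estimate under detailed balance (default) or by plain row
        normalization.
    count_mode : {"sliding", "strided"}

    Attributes (after fit)
    ----------------------
    count_matrix_ : full k x k transition counts.
    active_set_ : state indices retained after ergodic trimming.
    transition_matrix_ : row-stochastic T over the active set.
    stationary_distribution_ : pi with pi T = pi.
    eigenvalues_ : spectrum of T, lambda_1 = 1 first, then by |lambda| desc.
    """

    def __init__(self, lag: int = 1, reversible: bool = True,
                 count_mode: str = "sliding"):
        self.lag = lag
        self.reversible = reversible
        self.count_mode = count_mode

    # -- construction -----------------------------------------------------
    def fit(self, dtrajs, y=None, n_states: int | None = None):
        C = count_matrix(dtrajs, self.lag, n_states=n_states,
                         mode=self.count_mode)
        return self._fit_from_counts(C)

    @classmethod
    def from_count_matrix(cls, C, lag: int = 1, reversible: bool = True):
        model = cls(lag=lag, reversible=reversible)
        return model._fit_from_counts(np.asarray(C, dtype=float))

    def _fit_from_counts(self, C: np.ndarray):
        if (C < 0).any() or C.sum() == 0:
            raise ValueError("count matrix must be nonnegative with counts")
        active = _largest_scc(C)
        Ca = C[np.ix_(active, active)]
        if self.reversible:
            T, pi = _reversible_mle(Ca)
        else:
            T = Ca / Ca.sum(axis=1, keepdims=True)
            evals, evecs = scipy.linalg.eig(T, left=True, right=False)
            i = int(np.argmax(evals.real))
            pi = np.abs(evecs[:, i].real)
            pi /= pi.sum()
        self.count_matrix_ = C
        self.active_set_ = active
        self.transition_matrix_ = T
        self.stationary_distribution_ = pi
        self.eigenvalues_ = self._spectrum(T, pi)
        self.n_states_ = C.shape[0]
        self._token = next(_token_counter)
        return self

    def _spectrum(self, T, pi):
        if self.reversible:
            # similarity transform to a symmetric matrix: real spectrum
            s = np.sqrt(pi)
            M = (s[:, None] * T) / s[None, :]
            evals = scipy.linalg.eigh(0.5 * (M + M.T), eigvals_only=True)
        else:
            evals = scipy.linalg.eigvals(T)
            if np.abs(evals.imag).max() > 1e-12:
                warnings.warn(
                    "complex eigenvalues in non-reversible MSM; "
                    "reporting moduli"
                )
                evals = np.abs(evals)
            else:
                evals = evals.real
        order = np.argsort(-np.abs(evals))
        evals = evals[order]
        # numerical guarantee lambda_1 == 1 exactly
        evals[0] = 1.0
        return evals

    # -- derived quantities ------------------------------------------------
    def timescales(self, m: int | None = None) -> np.ndarray:
        """Implied timescales -tau / ln lambda_k for k = 2..m+1 (frames).

        Entries whose eigenvalue is outside (0, 1) are NaN (flagged, never
        silently dropped).
        """
        ev = self.eigenvalues_[1:None if m is None else m + 1]
        out = np.full(ev.shape, np.nan)
        ok = (ev > 0) & (ev < 1)
        out[ok] = -self.lag / np.log(ev[ok])
        return out

    def eigenvectors_right(self, k: int) -> np.ndarray:
        """First k right eigenvectors of T (columns), pi-weighted-orthonormal
        for reversible models; psi_1 is the constant vector."""
        pi = self.stationary_distribution_
        s = np.sqrt(pi)
        T = self.transition_matrix_
        if self.reversible:
            M = (s[:, None] * T) / s[None, :]
            evals, evecs = scipy.linalg.eigh(0.5 * (M + M.T))
            order = np.argsort(-np.abs(evals))
            psi = evecs[:, order[:k]] / s[:, None]
        else:
            evals, evecs = scipy.linalg.eig(T)
            order = np.argsort(-np.abs(evals))
            psi = evecs[:, order[:k]].real
        # sign/scale convention: psi_1 = 1
        psi[:, 0] = psi[:, 0] / psi[0, 0]
        return psi

    def score_vamp2(self, k: int = DEFAULT_VAMP2_K,
                    include_stationary: bool = True) -> float:
        return vamp2_score(self, k=k, include_stationary=include_stationary)

    def check_valid(self, tol: float = 1e-8) -> None:
        """Assert the structural MSM invariants; raises on violation."""
        T = self.transition_matrix_
        pi = self.stationary_distribution_
        if np.abs(T.sum(axis=1) - 1).max() > 1e-10:
            raise AssertionError("rows of T do not sum to 1")
        if (pi < -tol).any() or abs(pi.sum() - 1) > tol:
            raise AssertionError("pi is not a probability vector")
        if np.abs(pi @ T - pi).max() > tol:
            raise AssertionError("pi T != pi")
        if self.reversible:
            flux = pi[:, None] * T
            if np.abs(flux - flux.T).max() > tol:
                raise AssertionError("detailed balance violated")


def estimate_msm(C, lag: int = 1, reversible: bool = True) -> MarkovStateModel:
    """Estimate an MSM from a count matrix (functional wrapper)."""
    return MarkovStateModel.from_count_matrix(C, lag=lag, reversible=reversible)


@dataclass
class ImpliedTimescaleTable:
    lags: list
    timescales: np.ndarray  # (n_lags, m); NaN where undefined
    m: int
    errors: dict = field(default_factory=dict)  # lag -> message

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.timescales, index=self.lags,
            columns=[f"t{k + 2}" for k in range(self.m)],
        )


def implied_timescales(dtrajs, lags, m: int = 3, reversible: bool = True,
                       count_mode: str = "sliding") -> ImpliedTimescaleTable:
    """Top-m implied timescales per lag; per-lag failures are recorded in
    ``errors`` without aborting the other lags."""
    lags = list(lags)
    table = np.full((len(lags), m), np.nan)
    errors = {}
    for i, lag in enumerate(lags):
        try:
            model = MarkovStateModel(
                lag=lag, reversible=reversible, count_mode=count_mode
            ).fit(dtrajs)
            ts = model.timescales(m)
            table[i, : ts.size] = ts
        except (ValueError, RuntimeError) as exc:
            errors[lag] = str(exc)
    return ImpliedTimescaleTable(lags, table, m, errors)


def select_lag(table: ImpliedTimescaleTable, rtol: float = 0.1) -> int:
    """Smallest lag whose timescales have converged.

    Convergence at lag tau_i: every timescale differs from the next larger
    lag's by less than ``rtol`` relative to the latter.
    """
    if len(table.lags) < 2:
        raise ValueError("need at least two lags")
    for i in range(len(table.lags) - 1):
        a, b = table.timescales[i], table.timescales[i + 1]
        if np.isnan(a).any() or np.isnan(b).any():
            continue
        if (np.abs(a - b) / np.abs(b) < rtol).all():
            return table.lags[i]
    raise ValueError(
        f"implied timescales not converged within rtol={rtol} over lags "
        f"{table.lags}; try longer lags"
    )


def vamp2_score(msm: MarkovStateModel, k: int = DEFAULT_VAMP2_K,
                include_stationary: bool = True) -> float:
    """VAMP-2 score: sum of the squared first k eigenvalues of T.

    With ``include_stationary`` (default) the unit eigenvalue counts among
    the k, so the score lies in [1, k]; otherwise the sum starts at
    lambda_2 over k non-unit eigenvalues.
    """
    ev = msm.eigenvalues_ if include_stationary else msm.eigenvalues_[1:]
    if k > ev.size:
        raise ValueError(f"k={k} exceeds available spectrum ({ev.size})")
    head = ev[:k]
    score = float(np.sum(head ** 2))
    if not include_stationary:
        score += 1.0
    return score


def _lagged_autocorr(series_pairs):
    """Pearson correlation over pooled (y_t, y_{t+lag}) pairs."""
    a = np.concatenate([p[0] for p in series_pairs])
    b = np.concatenate([p[1] for p in series_pairs])
    if a.size < 2:
        return np.nan
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def cross_validated_vamp2(
    features,
    grid,
    lag: int,
    tica_lag: int = 10,
    k: int = DEFAULT_VAMP2_K,
    folds: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
    tica_regularization: float | None = None,
) -> pd.DataFrame:
    """Cross-validated VAMP-2 score over a (n_tics, n_clusters) grid.

    Trajectories are partitioned into ``folds`` folds by a seeded stream.
    Per fold, tICA + K-means + MSM are fit on the training trajectories only
    (cluster centers refit per fold to avoid leakage); the test score is
    1 + sum_{i=2..k} rho_i^2 where rho_i is the empirical lag-tau
    autocorrelation of the i-th training eigenfunction evaluated on the
    held-out trajectories. Folds whose held-out frames land only in trimmed
    states are flagged and excluded from the mean with a warning.

    Returns a DataFrame with columns n_tics, n_clusters, mean_score,
    sd_score, n_folds_used.
    """
    features = list(features)
    M = len(features)
    if M < folds:
        raise ValueError(f"{M} trajectories < folds={folds}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(M)
    fold_of = np.empty(M, dtype=int)
    for pos, t in enumerate(perm):
        fold_of[t] = pos % folds

    rows = []
    for n_tics, n_clusters in grid:
        scores = []
        excluded = 0
        for f in range(folds):
            train = [features[i] for i in range(M) if fold_of[i] != f]
            test = [features[i] for i in range(M) if fold_of[i] == f]
            try:
                score = _cv_fold_score(
                    train, test, n_tics, n_clusters, lag, tica_lag, k,
                    seed + 1000 * f, tica_regularization,
                )
            except (ValueError, RuntimeError) as exc:
                warnings.warn(f"fold {f} failed for ({n_tics}, {n_clusters}): {exc}")
                excluded += 1
                continue
            if score is None:
                warnings.warn(
                    f"fold {f} excluded for ({n_tics}, {n_clusters}): held-out "
                    "frames only in trimmed states"
                )
                excluded += 1
                continue
            scores.append(score)
        scores = np.array(scores)
        rows.append(
            {
                "n_tics": n_tics,
                "n_clusters": n_clusters,
                "mean_score": scores.mean() if scores.size else np.nan,
                "sd_score": scores.std(ddof=1) if scores.size > 1 else 0.0,
                "n_folds_used": scores.size,
            }
        )
    return pd.DataFrame(rows)


def _cv_fold_score(train, test, n_tics, n_clusters, lag, tica_lag, k, seed,
                   reg):
    tica = TICA(lag=tica_lag, n_components=n_tics, regularization=reg).fit(train)
    train_y = [tica.transform(t) for t in train]
    km = MicrostateKMeans(n_clusters=n_clusters, random_state=seed).fit(train_y)
    dtrajs = km.predict(train_y)
    msm = MarkovStateModel(lag=lag).fit(dtrajs, n_states=n_clusters)
    n_active = msm.active_set_.size
    k_eff = min(k, n_active)
    psi = msm.eigenvectors_right(k_eff)
    state_to_active = np.full(msm.n_states_, -1, dtype=int)
    state_to_active[msm.active_set_] = np.arange(n_active)

    test_y = [tica.transform(t) for t in test]
    test_d = km.predict(test_y)
    rho = []
    for i in range(1, k_eff):
        pairs = []
        for d in test_d:
            act = state_to_active[np.asarray(d)]
            y = np.where(act >= 0, psi[np.clip(act, 0, None), i], np.nan)
            a, b = y[:-lag], y[lag:]
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.any():
                pairs.append((a[ok], b[ok]))
        if not pairs:
            return None
        rho.append(_lagged_autocorr(pairs))
    return 1.0 + float(np.nansum(np.square(rho)))
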