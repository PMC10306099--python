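import numpy as np
import pytest
from scipy.optimize import minimize

from lanmsm.msm import (
    ImpliedTimescaleTable,
    MarkovStateModel,
    count_matrix,
    cross_validated_vamp2,
    estimate_msm,
    implied_timescales,
    select_lag,
    vamp2_score,
)
from tests.conftest import chain_eigs, sample_chain


class TestCountMatrix:
    def test_sliding_lag1_enumeration(self):
        C = count_matrix([[0, 0, 1, 1]], lag=1)
        np.testing.assert_array_equal(C, [[1, 1], [0, 1]])

    def test_sliding_lag2_enumeration(self):
        C = count_matrix([[0, 0, 1, 1]], lag=2)
        np.testing.assert_array_equal(C, [[0, 2], [0, 0]])

    def test_no_pairs_across_trajectory_boundary(self):
        C = count_matrix([[0, 1], [1, 0]], lag=1)
        np.testing.assert_array_equal(C, [[0, 1], [1, 0]])

    def test_sliding_equals_strided_at_lag1(self):
        rng = np.random.default_rng(0)
        d = [rng.integers(0, 4, size=200) for _ in range(3)]
        np.testing.assert_array_equal(
            count_matrix(d, 1, mode="sliding"),
            count_matrix(d, 1, mode="strided"),
        )

    def test_lag_longer_than_all_trajectories_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            count_matrix([[0, 1, 0]], lag=5)


class TestEstimation:
    def test_symmetric_two_state(self):
        msm = estimate_msm([[9, 1], [1, 9]], lag=1)
        np.testing.assert_allclose(
            msm.transition_matrix_, [[0.9, 0.1], [0.1, 0.9]], atol=1e-10
        )
        np.testing.assert_allclose(
            msm.stationary_distribution_, [0.5, 0.5], atol=1e-10
        )
        assert msm.eigenvalues_[1] == pytest.approx(0.8, abs=1e-10)
        msm.check_valid()

    def test_two_state_reversible_equals_nonreversible(self):
        # every 2-state chain satisfies detailed balance
        C = [[37, 5], [9, 121]]
        rev = estimate_msm(C, reversible=True)
        nonrev = estimate_msm(C, reversible=False)
        np.testing.assert_allclose(
            rev.transition_matrix_, nonrev.transition_matrix_, atol=1e-10
        )
        np.testing.assert_allclose(
            rev.stationary_distribution_, nonrev.stationary_distribution_,
            atol=1e-10,
        )

    def test_reversible_mle_matches_brute_force_oracle(self):
        """Oracle: direct numerical maximization of prod T_ij^C_ij under
        detailed balance, parametrized by the symmetric flux matrix."""
        C = np.array([[10, 2, 0], [3, 8, 1], [0, 2, 6]], dtype=float)
        msm = estimate_msm(C, reversible=True)

        iu = np.triu_indices(3)

        def neg_log_likelihood(u):
            X = np.zeros((3, 3))
            X[iu] = np.exp(u)
            X = X + X.T - np.diag(np.diag(X))
            T = X / X.sum(axis=1, keepdims=True)
            with np.errstate(divide="ignore"):
                ll = np.where(C > 0, C * np.log(np.where(T > 0, T, 1)), 0.0)
            return -ll.sum()

        best = None
        for s in range(3):
            x0 = np.log((C + C.T + 0.1 * (s + 1))[iu])
            r = minimize(neg_log_likelihood, x0, method="Nelder-Mead",
                         options={"maxiter": 40_000, "xatol": 1e-12,
                                  "fatol": 1e-14})
            if best is None or r.fun < best.fun:
                best = r
        X = np.zeros((3, 3))
        X[iu] = np.exp(best.x)
        X = X + X.T - np.diag(np.diag(X))
        T_oracle = X / X.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(
            msm.transition_matrix_, T_oracle, atol=1e-6
        )
        pi_oracle = X.sum(axis=1) / X.sum()
        np.testing.assert_allclose(
            msm.stationary_distribution_, pi_oracle, atol=1e-6
        )

    def test_detailed_balance_and_spectrum_invariants(self):
        rng = np.random.default_rng(8)
        C = rng.integers(1, 50, size=(5, 5)).astype(float)
        msm = estimate_msm(C, reversible=True)
        msm.check_valid()
        assert msm.eigenvalues_[0] == 1.0
        assert (np.abs(msm.eigenvalues_[1:]) <= 1 + 1e-10).all()

    def test_ergodic_trimming_keeps_largest_component(self):
        # states 0-1 communicate; state 2 is only reachable, never left
        C = np.array([[5, 3, 1], [4, 6, 0], [0, 0, 0]], dtype=float)
        msm = estimate_msm(C)
        np.testing.assert_array_equal(msm.active_set_, [0, 1])

    def test_empty_count_matrix_rejected(self):
        with pytest.raises(ValueError):
            estimate_msm(np.zeros((3, 3)))


class TestImpliedTimescales:
    def test_closed_form_from_eigenvalue(self):
        msm = estimate_msm([[9, 1], [1, 9]], lag=1)  # lambda_2 = 0.8
        assert msm.timescales(1)[0] == pytest.approx(-1 / np.log(0.8))

    def test_lag_two_with_e_inverse_eigenvalue(self):
        # T with lambda_2 = exp(-1) at lag 2 -> t2 = 2.0
        p = (1 - np.exp(-1)) / 2
        C = 1e6 * np.array([[1 - p, p], [p, 1 - p]])
        msm = MarkovStateModel.from_count_matrix(C, lag=2)
        assert msm.timescales(1)[0] == pytest.approx(2.0, rel=1e-9)

    def test_recovery_from_simulated_three_state_chain(self):
        # reversible 3-state chain built from a symmetric flux matrix
        K = np.array([[80.0, 6, 2], [6, 70, 5], [2, 5, 60]])
        T_true = K / K.sum(axis=1, keepdims=True)
        lam2 = chain_eigs(T_true)[1]
        rng = np.random.default_rng(123)
        dtrajs = [sample_chain(T_true, 20_000, rng) for _ in range(10)]
        table = implied_timescales(dtrajs, lags=[1, 2, 5], m=1)
        t_true = -1 / np.log(lam2)
        for i in range(3):
            assert table.timescales[i, 0] == pytest.approx(t_true, rel=0.10)

    def test_select_lag_constant_table_returns_smallest(self):
        table = ImpliedTimescaleTable(
            [1, 2, 5], np.full((3, 2), 7.0), m=2
        )
        assert select_lag(table, rtol=0.1) == 1

    def test_select_lag_divergent_table_errors(self):
        ts = np.array([[10.0], [15.0], [22.5]])
        table = ImpliedTimescaleTable([1, 2, 5], ts, m=1)
        with pytest.raises(ValueError, match="longer lags"):
            select_lag(table, rtol=0.1)

    def test_select_lag_worked_example(self):
        ts = np.array([[5.0], [9.0], [9.5], [9.6]])
        table = ImpliedTimescaleTable([1, 2, 5, 10], ts, m=1)
        assert select_lag(table, rtol=0.1) == 2

    def test_per_lag_errors_do_not_abort(self):
        table = implied_timescales([[0, 0, 0, 1, 1, 1, 0, 0, 0]],
                                   lags=[1, 10], m=1)
        assert 10 in table.errors
        assert np.isfinite(table.timescales[0, 0])


class TestVAMP2:
    def test_closed_form_three_eigenvalues(self):
        msm = MarkovStateModel()
        msm.eigenvalues_ = np.array([1.0, 0.8, 0.5])
        assert vamp2_score(msm, k=3) == pytest.approx(1.89)

    def test_identity_spectrum_scores_k(self):
        msm = MarkovStateModel()
        msm.eigenvalues_ = np.ones(6)
        assert vamp2_score(msm, k=6) == 6.0

    def test_k1_is_always_one(self):
        msm = estimate_msm([[9, 1], [1, 9]])
        assert vamp2_score(msm, k=1) == 1.0

    def test_k_beyond_spectrum_rejected(self):
        msm = estimate_msm([[9, 1], [1, 9]])
        with pytest.raises(ValueError, match="exceeds"):
            vamp2_score(msm, k=6)

    def test_exclude_stationary_convention(self):
        msm = MarkovStateModel()
        msm.eigenvalues_ = np.array([1.0, 0.8, 0.5])
        assert vamp2_score(msm, k=2, include_stationary=False) == (
            pytest.approx(1 + 0.64 + 0.25)
        )


@pytest.fixture(scope="module")
def four_state_features():
    """Trajectories from a 4-state metastable chain with distinct 1-D
    Gaussian emissions; the true VAMP-2 score is known from the chain."""
    K = np.array(
        [[200.0, 10, 1, 1], [10, 180, 8, 1], [1, 8, 160, 9], [1, 1, 9, 150]]
    )
    T = K / K.sum(axis=1, keepdims=True)
    rng = np.random.default_rng(77)
    centers = np.array([0.0, 3.0, 6.0, 9.0])
    feats, true_score = [], 1 + (chain_eigs(T)[1:4] ** 2).sum()
    for _ in range(12):
        h = sample_chain(T, 1500, rng)
        feats.append((centers[h] + rng.normal(0, 0.4, h.size))[:, None])
    return feats, float(true_score)


class TestCrossValidatedVAMP2:
    def test_score_grows_then_plateaus_with_cluster_count(
        self, four_state_features
    ):
        feats, true_score = four_state_features
        table = cross_validated_vamp2(
            feats, grid=[(1, 2), (1, 4), (1, 8)], lag=1, tica_lag=5,
            k=4, folds=4, seed=3,
        )
        scores = table["mean_score"].to_numpy()
        assert scores[1] > scores[0]  # 4 clusters resolve more than 2
        # plateau: 8 clusters within 1 sd of 4 clusters
        assert abs(scores[2] - scores[1]) <= (
            table["sd_score"].iloc[1] + table["sd_score"].iloc[2]
        )
        # no discretization beats the true chain score (within 2 sd)
        assert scores.max() <= true_score + 2 * table["sd_score"].max()

    def test_leave_one_out_runs_per_trajectory(self, four_state_features):
        feats, _ = four_state_features
        table = cross_validated_vamp2(
            feats[:6], grid=[(1, 4)], lag=1, tica_lag=5, k=4,
            folds=6, seed=0,
        )
        assert table["n_folds_used"].iloc[0] == 6

    def test_fewer_trajectories_than_folds_rejected(self, four_state_features):
        feats, _ = four_state_features
        with pytest.raises(ValueError, match="folds"):
            cross_validated_vamp2(feats[:3], [(1, 2)], lag=1, folds=10)


def test_stationary_recovery_improves_with_data():
    """Total-variation error of the estimated pi decreases with more data."""
    K = np.array([[80.0, 6, 2], [6, 70, 5], [2, 5, 60]])
    T_true = K / K.sum(axis=1, keepdims=True)
    pi_true = K.sum(axis=1) / K.sum()
    rng = np.random.default_rng(5)

    def tv_error(n_frames):
        dtrajs = [sample_chain(T_true, n_frames, rng) for _ in range(5)]
        msm = MarkovStateModel(lag=1).fit(dtrajs)
        return 0.5 * np.abs(msm.stationary_distribution_ - pi_true).sum()

    small, large = tv_error(400), tv_error(8000)
    assert large < 0.02
    assert large < small + 0.01
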