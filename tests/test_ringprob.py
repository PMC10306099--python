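import numpy as np
import pytest

from lanmsm.msm import MarkovStateModel, estimate_msm
from lanmsm.ringprob import (
    DEFAULT_BOOT_FRAC,
    DEFAULT_N_BOOT,
    KB_KCAL_PER_MOL_K,
    bootstrap_ring_probability,
    compare_rings,
    equilibrium_ring_probability,
    frame_weights,
    free_energy_landscape,
    weighted_helicity_distribution,
)
from tests.conftest import sample_chain


def _msm_with_pi(pi, lag=1):
    """Construct a 2-state MSM whose stationary distribution is pi."""
    pi = np.asarray(pi, dtype=float)
    # detailed-balance chain: flux x_01 = x_10
    scale = 1e7
    x = 0.05 * min(pi)
    C = scale * np.array(
        [[pi[0] - x, x], [x, pi[1] - x]]
    )
    msm = estimate_msm(C, lag=lag)
    np.testing.assert_allclose(msm.stationary_distribution_, pi, atol=1e-9)
    return msm


class TestFrameWeights:
    def test_worked_arithmetic_example(self):
        msm = _msm_with_pi([0.6, 0.4])
        dtrajs = [[0, 0, 0, 1, 1]]
        w = frame_weights(msm, dtrajs)[0]
        np.testing.assert_allclose(w, 0.2)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_pi_equal_population_gives_uniform_weights(self):
        msm = _msm_with_pi([0.5, 0.5])
        w = np.concatenate(frame_weights(msm, [[0, 1], [1, 0]]))
        np.testing.assert_allclose(w, 0.25)

    def test_trimmed_state_gets_zero_weight(self):
        # state 2 has one frame but is disconnected (no transitions)
        dtrajs = [[0, 0, 1, 1, 0], [2]]
        msm = MarkovStateModel(lag=1).fit(dtrajs, n_states=3)
        assert 2 not in msm.active_set_
        w = frame_weights(msm, dtrajs)
        assert w[1][0] == 0.0
        assert np.concatenate(w).sum() == pytest.approx(1.0, abs=1e-12)


class TestEquilibriumRingProbability:
    def test_boundary_frames_at_cutoff(self):
        msm = estimate_msm([[10.0]])
        res = equilibrium_ring_probability(
            [[7.49, 7.51]], [[0, 0]], msm, cutoff=7.5
        )
        assert res.equilibrium_probability == 0.5  # <= cutoff is closed

    def test_linearity_in_state_probabilities(self):
        msm = _msm_with_pi([0.5, 0.5])
        # state 0: 1 of 5 closed; state 1: 2 of 5 closed
        d = [[1.0, 9, 9, 9, 9], [1.0, 1.0, 9, 9, 9]]
        res = equilibrium_ring_probability(
            d, [[0] * 5, [1] * 5], msm, cutoff=7.5
        )
        assert res.equilibrium_probability == pytest.approx(0.3, abs=1e-12)

    def test_state_independent_probability_for_any_pi(self):
        msm = _msm_with_pi([0.73, 0.27])
        d = [[1.0, 9.0] * 10, [1.0, 9.0] * 10]
        res = equilibrium_ring_probability(
            d, [[0] * 20, [1] * 20], msm, cutoff=7.5
        )
        assert res.equilibrium_probability == pytest.approx(0.5, abs=1e-12)

    def test_double_computation_identity(self):
        rng = np.random.default_rng(0)
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        dtrajs = [sample_chain(T, 500, rng) for _ in range(4)]
        dists = [rng.uniform(3, 12, 500) for _ in range(4)]
        msm = MarkovStateModel(lag=1).fit(dtrajs)
        res = equilibrium_ring_probability(dists, dtrajs, msm, cutoff=7.5)
        assert abs(
            res.equilibrium_probability - res.frame_weight_probability
        ) <= 1e-12

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(1)
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        dtrajs = [sample_chain(T, 400, rng) for _ in range(3)]
        dists = [rng.uniform(3, 12, 400) for _ in range(3)]
        msm = MarkovStateModel(lag=1).fit(dtrajs)
        probs = [
            equilibrium_ring_probability(
                dists, dtrajs, msm, cutoff=c
            ).equilibrium_probability
            for c in (4.5, 7.0, 7.5, 8.0, 11.0)
        ]
        assert all(a <= b for a, b in zip(probs, probs[1:]))

    def test_misaligned_lengths_rejected(self):
        msm = estimate_msm([[10.0]])
        with pytest.raises(ValueError, match="misaligned"):
            equilibrium_ring_probability([[1.0, 2.0]], [[0]], msm, 7.5)


@pytest.fixture(scope="module")
def chain_data():
    rng = np.random.default_rng(42)
    T = np.array([[0.95, 0.05], [0.1, 0.9]])
    dtrajs = [sample_chain(T, 300, rng) for _ in range(12)]
    dists = [
        np.where(np.asarray(d) == 0, rng.uniform(4, 7, len(d)),
                 rng.uniform(9, 14, len(d)))
        for d in dtrajs
    ]
    return dists, dtrajs


class TestBootstrap:
    def test_shipped_defaults(self):
        assert DEFAULT_N_BOOT == 200
        assert DEFAULT_BOOT_FRAC == 0.8

    def test_full_fraction_gives_exactly_zero_sd(self, chain_data):
        dists, dtrajs = chain_data
        res = bootstrap_ring_probability(
            dists, dtrajs, lag=1, cutoff=7.5, n_boot=20, frac=1.0, seed=0
        )
        assert res.bootstrap_sd == 0.0
        assert res.bootstrap_mean == pytest.approx(
            res.equilibrium_probability, abs=1e-12
        )

    def test_full_estimate_within_three_sd_of_bootstrap(self, chain_data):
        dists, dtrajs = chain_data
        res = bootstrap_ring_probability(
            dists, dtrajs, lag=1, cutoff=7.5, n_boot=100, frac=0.8, seed=1
        )
        assert res.n_failed == 0
        assert abs(res.equilibrium_probability - res.bootstrap_mean) <= (
            3 * res.bootstrap_sd
        )

    def test_sd_shrinks_with_more_trajectories(self):
        T = np.array([[0.95, 0.05], [0.1, 0.9]])

        def sd_at(n_traj, seed):
            rng = np.random.default_rng(seed)
            dtrajs = [sample_chain(T, 200, rng) for _ in range(n_traj)]
            dists = [
                np.where(np.asarray(d) == 0, 5.0, 12.0) for d in dtrajs
            ]
            return bootstrap_ring_probability(
                dists, dtrajs, lag=1, cutoff=7.5, n_boot=60, frac=0.8,
                seed=seed,
            ).bootstrap_sd

        small = np.median([sd_at(8, s) for s in range(5)])
        large = np.median([sd_at(64, s + 100) for s in range(5)])
        assert large < small


class TestFreeEnergyLandscape:
    def test_closed_form_two_bin_difference(self):
        # weight ratio 10:1 at 300 K -> dF = kT ln 10 = 1.373 kcal/mol
        c1 = np.array([0.25] * 10 + [0.75])
        c2 = np.full(11, 0.25)
        w = np.full(11, 1 / 11)
        fel = free_energy_landscape(c1, c2, w, bins=2, range=[[0, 1], [0, 1]],
                                    temperature=300.0)
        dF = fel.free_energy[1, 0] - fel.free_energy[0, 0]
        assert dF == pytest.approx(KB_KCAL_PER_MOL_K * 300 * np.log(10),
                                   rel=1e-9)
        assert fel.free_energy.min() == 0.0
        assert fel.probability.sum() == pytest.approx(1.0)

    def test_uniform_weights_flat_landscape(self):
        rng = np.random.default_rng(0)
        grid = np.linspace(0.05, 0.95, 10)
        c1, c2 = np.meshgrid(grid, grid)
        n = c1.size
        fel = free_energy_landscape(
            c1.ravel(), c2.ravel(), np.full(n, 1 / n), bins=10,
            range=[[0, 1], [0, 1]],
        )
        np.testing.assert_allclose(fel.free_energy.compressed(), 0.0,
                                   atol=1e-12)

    def test_empty_bins_masked_not_infinite(self):
        fel = free_energy_landscape(
            [0.1, 0.1], [0.1, 0.1], [0.5, 0.5], bins=2,
            range=[[0, 1], [0, 1]],
        )
        assert fel.free_energy.mask.sum() == 3
        assert np.isfinite(fel.free_energy.compressed()).all()

    def test_zero_weight_in_range_rejected(self):
        with pytest.raises(ValueError, match="zero total weight"):
            free_energy_landscape([5.0], [5.0], [1.0], bins=2,
                                  range=[[0, 1], [0, 1]])


class TestHelicityDistribution:
    def test_all_mass_in_top_bin(self):
        hist, edges = weighted_helicity_distribution(
            np.ones(5), np.full(5, 0.2), bins=10
        )
        assert hist[-1] == pytest.approx(1.0)

    def test_end_bins_split_evenly(self):
        hist, _ = weighted_helicity_distribution(
            [0.0, 1.0], [0.5, 0.5], bins=10
        )
        assert hist[0] == pytest.approx(0.5)
        assert hist[-1] == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            weighted_helicity_distribution([1.2], [1.0])


class TestCompareRings:
    def _result(self, p, sd, label, token=1):
        from lanmsm.ringprob import RingProbabilityResult

        return RingProbabilityResult(
            ring=None, cutoff=7.5, per_state_probability=np.array([p]),
            equilibrium_probability=p, frame_weight_probability=p,
            n_frames_used=100, bootstrap_sd=sd, msm_token=token, label=label,
        )

    def test_ordering_and_prediction(self):
        cmp = compare_rings(
            [self._result(0.1, 0.01, "A"), self._result(0.3, 0.02, "B")]
        )
        assert cmp.order == ["B", "A"]
        assert cmp.predicted_first == "B"
        assert not cmp.tie

    def test_tie_flagged_no_prediction(self):
        cmp = compare_rings(
            [self._result(0.30, 0.02, "A"), self._result(0.31, 0.02, "B")]
        )
        assert cmp.tie
        assert cmp.predicted_first is None

    def test_results_from_different_msms_rejected(self):
        with pytest.raises(ValueError, match="different MSMs"):
            compare_rings(
                [self._result(0.1, 0.01, "A", token=1),
                 self._result(0.2, 0.01, "B", token=2)]
            )
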