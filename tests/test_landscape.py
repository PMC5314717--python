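"""Stochastic layer: SIN noise, transition chain, MFPT, global ordering."""

import numpy as np
import pytest

from epiland import (
    BooleanNetwork,
    NoiseModel,
    TransitionMatrix,
    TruthTable,
    aggregate_by_basins,
    basin_partition,
    estimate_transition_matrix,
    exact_one_step_operator,
    find_attractors,
    iterate_distribution,
    mfpt_analytic,
    mfpt_simulated,
    net_rates_and_ordering,
    stochastic_step,
    synchronous_step,
    temporal_attainment,
)
from epiland.fixtures import random_chain


@pytest.fixture
def identity_net():
    return BooleanNetwork(
        nodes=("x",), rules={"x": TruthTable(("x",), (0, 1))}
    )


class TestStochasticStep:
    def test_zero_noise_is_deterministic(self, toggle, rng):
        for code in range(4):
            s = toggle.decode(code)
            assert stochastic_step(toggle, s, NoiseModel(0.0), rng) == \
                synchronous_step(toggle, s)

    def test_full_noise_forces_disobedience(self, identity_net, rng):
        assert stochastic_step(identity_net, (1,), NoiseModel(1.0), rng) == (0,)

    def test_invalid_xi_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(1.5)

    def test_clamped_node_never_flips(self, toggle, rng):
        clamped = toggle.clamp("a", 1)
        for _ in range(50):
            nxt = stochastic_step(clamped, (1, 0), NoiseModel(0.9), rng)
            assert nxt[0] == 1

    def test_empirical_flip_rate_matches_xi(self, identity_net, rng):
        xi, n = 0.05, 20_000
        flips = sum(
            stochastic_step(identity_net, (1,), NoiseModel(xi), rng) == (0,)
            for _ in range(n)
        )
        se = np.sqrt(xi * (1 - xi) / n)
        assert abs(flips / n - xi) < 3 * se


class TestExactOperator:
    def test_zero_noise_gives_permutation(self, toggle):
        P = exact_one_step_operator(toggle, NoiseModel(0.0))
        succ = toggle.successor_table()
        for s in range(4):
            assert P[s, succ[s]] == 1.0

    def test_identity_net_closed_form(self, identity_net):
        P = exact_one_step_operator(identity_net, NoiseModel(0.05))
        np.testing.assert_allclose(P, [[0.95, 0.05], [0.05, 0.95]])

    def test_rows_sum_to_one(self, toggle):
        P = exact_one_step_operator(toggle, NoiseModel(0.2))
        np.testing.assert_allclose(P.sum(axis=1), 1.0)


class TestEstimateTransitionMatrix:
    def test_zero_noise_identity(self, toggle, rng):
        basins = basin_partition(toggle)
        tm = estimate_transition_matrix(
            toggle, NoiseModel(0.0), basins, reps=50, rng=rng
        )
        np.testing.assert_allclose(tm.pi, np.eye(len(basins.attractors)))

    def test_rows_stochastic(self, toggle, rng):
        basins = basin_partition(toggle)
        tm = estimate_transition_matrix(
            toggle, NoiseModel(0.1), basins, reps=500, rng=rng
        )
        np.testing.assert_allclose(tm.pi.sum(axis=1), 1.0, atol=1e-9)

    def test_monte_carlo_matches_exact_aggregation(self, self_activator, rng):
        """MC estimate within 3 binomial SE of the basin-pooled operator."""
        xi, reps = 0.1, 10_000
        basins = basin_partition(self_activator)
        P = exact_one_step_operator(self_activator, NoiseModel(xi))
        exact = aggregate_by_basins(P, basins)
        est = estimate_transition_matrix(
            self_activator, NoiseModel(xi), basins, reps=reps, rng=rng
        )
        n_states = 1  # one state per basin here
        se = np.sqrt(exact.pi * (1 - exact.pi) / (reps * n_states))
        assert (np.abs(est.pi - exact.pi) <= 3 * se + 1e-12).all()


class TestIterateDistribution:
    def test_identity_matrix_constant(self):
        tm = TransitionMatrix(pi=np.eye(2), labels=("a", "b"))
        out = iterate_distribution(tm, [0.3, 0.7], 5)
        np.testing.assert_allclose(out, np.tile([0.3, 0.7], (6, 1)))

    def test_swap_matrix_alternates(self):
        tm = TransitionMatrix(pi=np.array([[0.0, 1.0], [1.0, 0.0]]), labels=("a", "b"))
        out = iterate_distribution(tm, [1.0, 0.0], 3)
        np.testing.assert_allclose(out[:, 0], [1, 0, 1, 0])

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError):
            TransitionMatrix(pi=np.array([[0.5, 0.2], [0.1, 0.9]]), labels=("a", "b"))


class TestTemporalAttainment:
    def test_identity_sequence_is_start(self):
        tm = TransitionMatrix(pi=np.eye(3), labels=("a", "b", "c"))
        seq, _, _ = temporal_attainment(tm, [0, 1, 0], 10)
        assert seq == (1,)

    def test_planted_chain_recovers_order(self):
        pi, path = random_chain(3, flow_strength=0.9, seed=5)
        tm = TransitionMatrix(pi=pi, labels=("0", "1", "2"))
        p0 = np.zeros(3)
        p0[0] = 1.0
        seq, _, _ = temporal_attainment(tm, p0, 400)
        assert seq == path


class TestMFPT:
    def test_two_state_geometric(self, rng):
        p = 0.2
        pi = np.array([[1 - p, p], [0.0, 1.0]])
        tm = TransitionMatrix(pi=pi, labels=("i", "j"))
        analytic = mfpt_analytic(tm)
        assert analytic[0, 1] == pytest.approx(1 / p)
        sim, censored = mfpt_simulated(tm, n_paths=4000, max_steps=2000, rng=rng)
        se = np.sqrt((1 - p) / p**2 / 4000)
        assert abs(sim[0, 1] - 1 / p) < 3 * se
        assert censored[0, 1] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_simulated_agrees_with_fundamental_matrix(self, seed):
        pi, _ = random_chain(3, flow_strength=0.6, seed=seed)
        tm = TransitionMatrix(pi=pi, labels=("a", "b", "c"))
        analytic = mfpt_analytic(tm)
        rng = np.random.default_rng(seed + 100)
        sim, _ = mfpt_simulated(tm, n_paths=3000, max_steps=50_000, rng=rng)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                # conservative bound: 3 SE with SD <= mean for near-geometric laws
                se = analytic[i, j] / np.sqrt(3000)
                assert abs(sim[i, j] - analytic[i, j]) < 4 * se + 0.5

    def test_unreachable_pair_censored(self, rng):
        pi = np.array([[1.0, 0.0], [0.0, 1.0]])
        tm = TransitionMatrix(pi=pi, labels=("a", "b"))
        sim, censored = mfpt_simulated(tm, n_paths=50, max_steps=100, rng=rng)
        assert np.isinf(sim[0, 1]) and censored[0, 1] == 50


class TestNetRatesAndOrdering:
    def test_antisymmetry(self):
        pi, _ = random_chain(4, flow_strength=0.7, seed=2)
        tm = TransitionMatrix(pi=pi, labels=tuple("abcd"))
        m = mfpt_analytic(tm)
        summary = net_rates_and_ordering(m, tm.labels)
        np.testing.assert_allclose(summary.net_rates, -summary.net_rates.T, atol=1e-12)

    def test_symmetric_chain_has_no_ordering(self):
        pi = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
        tm = TransitionMatrix(pi=pi, labels=("a", "b", "c"))
        summary = net_rates_and_ordering(mfpt_analytic(tm), tm.labels)
        assert summary.ordering is None

    def test_planted_flow_recovered(self):
        pi, path = random_chain(3, flow_strength=0.9, seed=11)
        tm = TransitionMatrix(pi=pi, labels=("a", "b", "c"))
        summary = net_rates_and_ordering(mfpt_analytic(tm), tm.labels)
        assert summary.ordering == path
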