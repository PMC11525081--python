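"""Batch-constrained Q-learning: supervisor, masking, TD training."""

import numpy as np
import pytest

from ventrl import BCQAgent, BCQHyperparams, train_bcq
from ventrl.mdp import N_ACTIONS, TransitionDataset


def make_dataset(states, actions, rewards=None, terminal=True):
    """All-terminal single-step dataset from (state, action) pairs."""
    n = len(actions)
    states = np.asarray(states, dtype=float)
    rewards = np.zeros(n) if rewards is None else np.asarray(rewards, dtype=float)
    return TransitionDataset(
        states=states,
        actions=np.asarray(actions, dtype=int),
        rewards=rewards,
        next_states=np.full_like(states, np.nan),
        done=np.ones(n, dtype=bool),
        patient_ids=np.array([f"p{i}" for i in range(n)]),
        step_index=np.zeros(n, dtype=int),
    )


@pytest.fixture
def toy_hp():
    return BCQHyperparams(hidden_widths=(32, 32), supervisor_pretrain_iterations=1500,
                          training_iterations=100, seed=0)


class TestSupervisor:
    def test_learns_deterministic_action(self, toy_hp):
        """A single action taken everywhere gets probability near 1."""
        rng = np.random.default_rng(0)
        states = rng.uniform(size=(1000, 2))
        ds = make_dataset(states, np.full(1000, 7))
        agent = BCQAgent(2, toy_hp)
        agent.train_supervisor(ds, iterations=5000)
        probs = agent.supervisor_probs(states[:50])
        assert probs[:, 7].min() > 0.99

    def test_recovers_state_dependent_mapping(self, toy_hp):
        states = np.tile(np.array([[0.0, 1.0], [1.0, 0.0]]), (300, 1))
        actions = np.tile(np.array([3, 11]), 300)
        agent = BCQAgent(2, toy_hp)
        agent.train_supervisor(make_dataset(states, actions), iterations=1500)
        probs = agent.supervisor_probs(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert probs[0].argmax() == 3 and probs[1].argmax() == 11

    def test_uniform_behavior_gives_uniform_probs(self):
        """Maximum-likelihood limit: uniform actions on one repeated state."""
        rng = np.random.default_rng(1)
        states = np.full((3600, 2), 0.5)
        actions = rng.integers(N_ACTIONS, size=3600)
        hp = BCQHyperparams(hidden_widths=(32, 32), seed=0)
        agent = BCQAgent(2, hp)
        agent.train_supervisor(make_dataset(states, actions), iterations=4000)
        probs = agent.supervisor_probs(states[:1])
        np.testing.assert_allclose(probs[0], 1.0 / N_ACTIONS, atol=0.02)

    def test_rejects_states_outside_unit_cube(self, toy_hp):
        agent = BCQAgent(2, toy_hp)
        ds = make_dataset(np.array([[1.5, 0.0]]), [0])
        with pytest.raises(ValueError):
            agent.train_supervisor(ds, iterations=1)


class TestConstrainedActions:
    def _agent_with_probs(self, probs, tau):
        hp = BCQHyperparams(hidden_widths=(8, 8), extrapolation_threshold=tau, seed=0)
        agent = BCQAgent(3, hp)
        probs = np.asarray(probs)
        agent.supervisor_probs = lambda s: np.tile(probs, (np.atleast_2d(s).shape[0], 1))
        return agent

    def test_tau_zero_admits_everything(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(N_ACTIONS))
        agent = self._agent_with_probs(p, 0.0)
        assert len(agent.constrained_action_set(np.zeros(3))) == N_ACTIONS

    def test_tau_one_admits_only_argmax(self):
        p = np.full(N_ACTIONS, 0.01)
        p[5] = 1.0 - 0.01 * (N_ACTIONS - 1)
        agent = self._agent_with_probs(p, 1.0)
        assert list(agent.constrained_action_set(np.zeros(3))) == [5]

    def test_documented_ratio_example(self):
        p = np.zeros(N_ACTIONS)
        p[0], p[1], p[2] = 0.90, 0.08, 0.02
        agent = self._agent_with_probs(p, 0.05)
        assert list(agent.constrained_action_set(np.zeros(3))) == [0, 1]

    def test_mask_shrinks_as_tau_grows(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(N_ACTIONS) * 0.5)
        sizes = []
        for tau in (0.0, 0.02, 0.1, 0.5, 1.0):
            agent = self._agent_with_probs(p, tau)
            sizes.append(len(agent.constrained_action_set(np.zeros(3))))
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[0] == N_ACTIONS and sizes[-1] == 1

    def test_masking_overrides_higher_q(self):
        p = np.zeros(N_ACTIONS)
        p[0] = 1.0
        agent = self._agent_with_probs(p, 1.0)
        q = np.zeros((1, N_ACTIONS))
        q[0, 1] = 5.0
        agent.q_values = lambda s: q
        assert agent.select_action(np.zeros(3)) == 0

    def test_tie_broken_by_lowest_index(self):
        p = np.full(N_ACTIONS, 1.0 / N_ACTIONS)
        agent = self._agent_with_probs(p, 0.0)
        q = np.zeros((1, N_ACTIONS))
        q[0, 3] = q[0, 7] = 2.0
        agent.q_values = lambda s: q
        assert agent.select_action(np.zeros(3)) == 3

    def test_simplex_conservation(self, toy_hp):
        rng = np.random.default_rng(5)
        agent = BCQAgent(4, toy_hp)
        probs = agent.supervisor_probs(rng.uniform(size=(2000, 4)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.min() >= 0


class TestTraining:
    def test_terminal_targets_are_rewards(self):
        """All-terminal batch: squared TD loss equals mean (Q(s,a) - r)^2 / 2."""
        hp = BCQHyperparams(hidden_widths=(16, 16), seed=0)
        agent = BCQAgent(2, hp)
        ds = make_dataset(np.random.default_rng(0).uniform(size=(32, 2)),
                          np.zeros(32, dtype=int), rewards=np.full(32, 3.0))
        q_before = agent.q_values(ds.states)[np.arange(32), ds.actions]
        l_q, _ = agent.bcq_training_step(ds)
        assert l_q == pytest.approx(0.5 * np.mean((q_before - 3.0) ** 2), rel=1e-9)

    def test_two_action_terminal_gap(self):
        """Terminal rewards 0 vs 1 on one state: Q gap converges to 1."""
        rng = np.random.default_rng(2)
        states = np.full((2000, 2), 0.5)
        actions = rng.integers(2, size=2000)
        ds = make_dataset(states, actions, rewards=actions.astype(float))
        hp = BCQHyperparams(hidden_widths=(32, 32), training_iterations=4000,
                            supervisor_pretrain_iterations=500, seed=0)
        agent = train_bcq(ds, hp)
        q = agent.q_values(states[:1])[0]
        assert q[1] - q[0] == pytest.approx(1.0, abs=0.05)

    def test_two_state_chain_fixed_point(self):
        """Deterministic chain s0 -> s1 -> end with rewards (1, 2):
        Q(s0) = 1 + gamma * 2, Q(s1) = 2, within 5%."""
        gamma = 0.9
        s0, s1 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        n = 500
        states = np.tile(np.vstack([s0, s1]), (n, 1))
        next_states = np.tile(np.vstack([s1, np.full(2, np.nan)]), (n, 1))
        ds = TransitionDataset(
            states=states,
            actions=np.zeros(2 * n, dtype=int),
            rewards=np.tile([1.0, 2.0], n),
            next_states=next_states,
            done=np.tile([False, True], n),
            patient_ids=np.repeat([f"p{i}" for i in range(n)], 2),
            step_index=np.tile([0, 1], n),
        )
        hp = BCQHyperparams(hidden_widths=(32, 32), discount=gamma,
                            training_iterations=6000,
                            supervisor_pretrain_iterations=500, seed=1)
        agent = train_bcq(ds, hp)
        q = agent.q_values(np.vstack([s0, s1]))[:, 0]
        assert q[0] == pytest.approx(1.0 + gamma * 2.0, rel=0.05)
        assert q[1] == pytest.approx(2.0, rel=0.05)

    def test_gamma_zero_targets_ignore_next_state(self):
        hp = BCQHyperparams(hidden_widths=(16, 16), discount=0.0, seed=0)
        agent = BCQAgent(2, hp)
        states = np.random.default_rng(1).uniform(size=(32, 2))
        ds = TransitionDataset(
            states=states, actions=np.zeros(32, dtype=int), rewards=np.full(32, 2.0),
            next_states=states.copy(), done=np.zeros(32, dtype=bool),
            patient_ids=np.array([f"p{i}" for i in range(32)]),
            step_index=np.zeros(32, dtype=int),
        )
        q_before = agent.q_values(states)[np.arange(32), 0]
        l_q, _ = agent.bcq_training_step(ds)
        assert l_q == pytest.approx(0.5 * np.mean((q_before - 2.0) ** 2), rel=1e-9)

    def test_training_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        ds = make_dataset(rng.uniform(size=(200, 3)), rng.integers(4, size=200),
                          rewards=rng.normal(size=200))
        hp = BCQHyperparams(hidden_widths=(16, 16), training_iterations=300,
                            supervisor_pretrain_iterations=100, seed=9)
        a = train_bcq(ds, hp)
        b = train_bcq(ds, hp)
        assert a.training_log == b.training_log
        probe = rng.uniform(size=(10, 3))
        np.testing.assert_array_equal(a.q_values(probe), b.q_values(probe))

    def test_empty_dataset_rejected(self):
        ds = make_dataset(np.zeros((0, 2)), np.zeros(0, dtype=int))
        with pytest.raises(ValueError):
            train_bcq(ds, BCQHyperparams())

    def test_save_load_round_trip(self, tmp_path, toy_hp):
        rng = np.random.default_rng(6)
        ds = make_dataset(rng.uniform(size=(100, 3)), rng.integers(3, size=100))
        hp = BCQHyperparams(hidden_widths=(16, 16), training_iterations=100,
                            supervisor_pretrain_iterations=100, seed=2)
        agent = train_bcq(ds, hp)
        path = tmp_path / "agent.npz"
        agent.save(path)
        back = BCQAgent.load(path)
        probe = rng.uniform(size=(5, 3))
        np.testing.assert_array_equal(back.q_values(probe), agent.q_values(probe))
        np.testing.assert_array_equal(back.supervisor_probs(probe),
                                      agent.supervisor_probs(probe))


class TestExpectedReturn:
    def test_function_of_initial_state_only(self, toy_hp):
        agent = BCQAgent(2, toy_hp)
        t1 = {"states": np.array([[0.2, 0.8], [0.5, 0.5]])}
        t2 = {"states": np.array([[0.2, 0.8], [0.9, 0.1]])}
        assert agent.expected_return(t1) == agent.expected_return(t2)

    def test_empty_trajectory_rejected(self, toy_hp):
        agent = BCQAgent(2, toy_hp)
        with pytest.raises(ValueError):
            agent.expected_return({"states": np.zeros((0, 2))})

    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            BCQHyperparams(extrapolation_threshold=1.5)
        with pytest.raises(ValueError):
            BCQHyperparams(discount=1.0)
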