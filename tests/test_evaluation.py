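"""Benchmark policies, CWPDIS, return-to-outcome mapping, V-curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ventrl import (
    ConstantActionPolicy,
    Policy,
    RewardParams,
    SimulatorConfig,
    UniformRandomPolicy,
    cwpdis,
    make_benchmark,
    map_return_to_outcome,
    proportion_in_range,
    v_curve,
)
from ventrl.mdp import N_ACTIONS, VentilatorActionSpace
from ventrl.simulator import sample_tabular_transitions


class FixedProbPolicy(Policy):
    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def action_probabilities(self, state):
        return self.probs


@pytest.fixture(scope="module")
def tabular_batch(reward_params):
    cfg = SimulatorConfig(mode="tabular", seed=2)
    ds, trajs, env = sample_tabular_transitions(cfg, reward_params, 500, seed=4)
    return ds, trajs, env


class TestBenchmarks:
    def test_random_is_uniform(self):
        pol = make_benchmark("random")
        np.testing.assert_allclose(
            pol.action_probabilities(np.zeros(40)), 1.0 / N_ACTIONS
        )

    def test_one_size_fits_all_is_modal_action(self, tabular_batch):
        ds, _, _ = tabular_batch
        pol = make_benchmark("one_size_fits_all", ds)
        modal = np.bincount(ds.actions, minlength=N_ACTIONS).argmax()
        assert isinstance(pol, ConstantActionPolicy)
        for s in ds.states[:20]:
            assert pol.select(s) == modal

    def test_physician_estimate_on_simplex(self, tabular_batch):
        ds, _, _ = tabular_batch
        pol = make_benchmark("physician", ds, n_clusters=10)
        rng = np.random.default_rng(0)
        for s in ds.states[rng.integers(len(ds), size=50)]:
            p = pol.action_probabilities(s)
            assert p.min() > 0
            assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_benchmark("oracle")


class TestCWPDIS:
    def test_self_evaluation_identity(self, tabular_batch):
        """Evaluating the behavior policy on its own batch returns the batch
        mean discounted return exactly."""
        _, trajs, env = tabular_batch
        behavior = env.behavior_policy()
        res = cwpdis(trajs, behavior, behavior, 0.99)
        returns = [
            float((0.99 ** np.arange(len(t["rewards"])) * t["rewards"]).sum())
            for t in trajs
        ]
        assert res.value_estimate == pytest.approx(np.mean(returns), rel=1e-12)
        assert res.effective_sample_size == pytest.approx(len(trajs))

    def test_single_trajectory_weights_cancel(self, tabular_batch):
        _, trajs, env = tabular_batch
        tr = trajs[0]
        eval_pol = UniformRandomPolicy()
        res = cwpdis([tr], eval_pol, env.behavior_policy(), 0.95)
        expected = float((0.95 ** np.arange(len(tr["rewards"])) * tr["rewards"]).sum())
        assert res.value_estimate == pytest.approx(expected, rel=1e-12)

    def test_zero_behavior_probability_rejected(self):
        traj = {
            "patient_id": "a",
            "states": np.zeros((1, 4)),
            "actions": np.array([2]),
            "rewards": np.array([1.0]),
        }
        zero_two = np.full(N_ACTIONS, 1.0 / (N_ACTIONS - 1))
        zero_two[2] = 0.0
        with pytest.raises(ValueError, match="a"):
            cwpdis([traj], UniformRandomPolicy(), FixedProbPolicy(zero_two), 1.0)

    def test_exhaustive_two_step_mdp_closed_form(self):
        """On a fully enumerated 2-step, 2-state, 2-action decision process,
        CWPDIS with exact trajectory probabilities as weights reproduces the
        closed-form policy value to 1e-10."""
        # deterministic transitions: state s, action a -> next state a
        # reward r(s, a) = s + 2a at each of the two steps
        def reward(s, a):
            return float(s + 2 * a)

        pi_b = {0: np.array([0.6, 0.4]), 1: np.array([0.3, 0.7])}
        pi_e = {0: np.array([0.2, 0.8]), 1: np.array([0.9, 0.1])}
        gamma = 0.9

        def enc(s):
            v = np.zeros(2)
            v[s] = 1.0
            return v

        class DictPolicy(Policy):
            def __init__(self, table):
                self.table = table

            def action_probabilities(self, state):
                p = np.zeros(N_ACTIONS)
                p[:2] = self.table[int(np.argmax(state))]
                return p

        trajs, weights = [], []
        value = 0.0
        for a0 in (0, 1):
            for a1 in (0, 1):
                s0, s1 = 0, a0
                prob_b = pi_b[s0][a0] * pi_b[s1][a1]
                prob_e = pi_e[s0][a0] * pi_e[s1][a1]
                ret = reward(s0, a0) + gamma * reward(s1, a1)
                value += prob_e * ret
                trajs.append({
                    "states": np.vstack([enc(s0), enc(s1)]),
                    "actions": np.array([a0, a1]),
                    "rewards": np.array([reward(s0, a0), reward(s1, a1)]),
                })
                weights.append(prob_b)
        res = cwpdis(trajs, DictPolicy(pi_e), DictPolicy(pi_b), gamma,
                     weights=np.array(weights))
        assert res.value_estimate == pytest.approx(value, abs=1e-10)

    def test_weight_diagnostics_contracts(self, tabular_batch):
        _, trajs, env = tabular_batch
        res = cwpdis(trajs, UniformRandomPolicy(), env.behavior_policy(), 0.99)
        assert np.all(res.per_horizon_weight_sums >= 0)
        assert 0 < res.effective_sample_size <= len(trajs)


class TestReturnToOutcome:
    def test_degenerate_identical_returns(self):
        outcomes = np.array([0, 1, 0, 1, 1])
        est, curve = map_return_to_outcome(
            np.zeros(5), outcomes, 3, np.array([5.0, -2.0])
        )
        assert est == pytest.approx(outcomes.mean())

    def test_threshold_fixture(self):
        """Deaths exactly below return 0; non-negative evaluated returns map
        to the mortality of the non-negative bins only."""
        phys = np.array([-4.0, -3.0, -2.0, -1.0, 1.0, 2.0, 3.0, 4.0])
        outcomes = (phys < 0).astype(float)
        est, curve = map_return_to_outcome(phys, outcomes, 4, np.array([1.5, 3.5]))
        assert est == pytest.approx(0.0)

    def test_monotone_relation_gives_monotone_curve(self):
        rng = np.random.default_rng(0)
        returns = rng.normal(size=4000)
        ranks = returns.argsort().argsort() / (len(returns) - 1)
        outcomes = rng.random(4000) < (1.0 - ranks)
        _, curve = map_return_to_outcome(returns, outcomes, 10, returns)
        rates = curve["outcome_rate"].to_numpy()
        assert np.all(np.diff(rates) <= 0.05)  # non-increasing up to noise

    @given(shift=st.floats(-5, 5), scale=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_monotone_transform(self, shift, scale):
        rng = np.random.default_rng(11)
        phys = rng.normal(size=300)
        outcomes = (rng.random(300) < 0.3).astype(float)
        ai = rng.normal(size=100)
        base, _ = map_return_to_outcome(phys, outcomes, 8, ai)
        mapped, _ = map_return_to_outcome(scale * phys + shift, outcomes, 8,
                                          scale * ai + shift)
        assert mapped == pytest.approx(base, abs=1e-12)


class TestVCurve:
    def _outcomes(self, pids, morts):
        return pd.DataFrame({"patient_id": pids, "hospital_mortality": morts,
                             "wean_time_h": np.nan})

    def test_perfect_agreement_single_zero_bin(self, action_space):
        comp = pd.DataFrame({
            "patient_id": ["a"] * 3 + ["b"] * 3,
            "administered": [4, 7, 12, 1, 4, 15],
            "recommended": [4, 7, 12, 1, 4, 15],
        })
        curves = v_curve(comp, self._outcomes(["a", "b"], [0, 1]), action_space)
        for dim, df in curves.items():
            assert df["level_difference"].tolist() == [0]
            assert df["n_patients"].sum() == 2

    def test_difference_bins_within_level_range(self, action_space):
        rng = np.random.default_rng(0)
        comp = pd.DataFrame({
            "patient_id": np.repeat([f"p{i}" for i in range(30)], 4),
            "administered": rng.integers(N_ACTIONS, size=120),
            "recommended": rng.integers(N_ACTIONS, size=120),
        })
        outcomes = self._outcomes([f"p{i}" for i in range(30)],
                                  rng.integers(2, size=30))
        curves = v_curve(comp, outcomes, action_space)
        assert set(curves) == {"peep", "fio2", "tidal_volume"}
        assert curves["peep"]["level_difference"].between(-1, 1).all()
        for dim in ("fio2", "tidal_volume"):
            assert curves[dim]["level_difference"].between(-2, 2).all()
            assert curves[dim]["n_patients"].sum() == 30

    def test_mortality_minimum_at_zero_when_constructed(self, action_space):
        """Mortality rising with |difference| puts the V-curve minimum at 0."""
        rng = np.random.default_rng(1)
        pids = [f"p{i}" for i in range(600)]
        adm = rng.integers(N_ACTIONS, size=600)
        rec = rng.integers(N_ACTIONS, size=600)
        lv_a = np.column_stack(action_space.levels_of_index(adm))
        lv_r = np.column_stack(action_space.levels_of_index(rec))
        dist = np.abs(lv_a - lv_r).sum(axis=1)
        mort = rng.random(600) < (0.05 + 0.18 * dist)
        comp = pd.DataFrame({"patient_id": pids, "administered": adm,
                             "recommended": rec})
        curves = v_curve(comp, self._outcomes(pids, mort.astype(int)), action_space)
        for dim, df in curves.items():
            zero_row = df.loc[df["level_difference"] == 0, "mortality"]
            assert zero_row.iloc[0] == df["mortality"].min()


class TestProportionInRange:
    def _steps(self, spo2, durations=None):
        n = len(spo2)
        durations = np.ones(n) if durations is None else np.asarray(durations)
        starts = np.r_[0.0, np.cumsum(durations)[:-1]]
        return pd.DataFrame({
            "patient_id": ["a"] * n, "start_h": starts,
            "end_h": starts + durations, "spo2": spo2,
        })

    def test_all_in_range(self):
        assert proportion_in_range(self._steps([96.0] * 4), "spo2", (94, 98),
                                   inclusive="neither") == 1.0

    def test_open_interval_boundary_excluded(self):
        assert proportion_in_range(self._steps([94.0] * 4), "spo2", (94, 98),
                                   inclusive="neither") == 0.0

    def test_time_weighted_vs_per_step(self):
        steps = self._steps([96.0, 90.0], durations=[3.0, 1.0])
        assert proportion_in_range(steps, "spo2", (94, 98), "per-step",
                                   "neither") == 0.5
        assert proportion_in_range(steps, "spo2", (94, 98), "time-weighted",
                                   "neither") == 0.75

    def test_unknown_variable_rejected(self):
        with pytest.raises(KeyError):
            proportion_in_range(self._steps([96.0]), "unknown", (0, 1))
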