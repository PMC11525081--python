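"""Synthetic ICU ventilation cohorts with known ground-truth dynamics.

A latent severity process drives everything: vital signs and labs are
severity-conditional draws, ventilator settings chosen close to a
severity-dependent ideal pull severity down, poorly matched settings push
it up, and hospital mortality is a logistic function of terminal severity.
"Better ventilation leads to better outcomes" therefore holds by
construction, which makes policy improvement detectable and lets exact
oracles (value iteration in the tabular mode, Monte-Carlo rollouts in the
continuous mode) validate every downstream stage.

Two modes share one configuration:

* ``tabular`` — severity is one of ``severity_levels`` integer states and
  the dynamics form a small stationary Markov decision process with an
  absorbing end state (episodes end by a weaning/discharge hazard, not a
  fixed horizon), so policy values are exactly computable.
* ``continuous`` — severity is a bounded random walk updated hourly, with
  irregular observation times, per-variable missingness and a 48-hour
  horizon; this is the cohort the preprocessing pipeline consumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .mdp import (
    N_ACTIONS,
    RewardParams,
    TransitionDataset,
    VentilatorActionSpace,
    compute_reward,
)
from .policies import (
    EpsilonIdealTabularPolicy,
    Policy,
    TabularPolicy,
)
from .schema import (
    DYNAMIC_VARIABLES,
    SETTING_VARIABLES,
    STATIC_VARIABLES,
    FeatureSchema,
    default_schema,
)

_ACTION_SPACE = VentilatorActionSpace()

#: relative observation frequency per dynamic variable (events per hour at rate 1)
_OBS_RATE = {
    "spo2": 1.0,
    "heart_rate": 1.0,
    "resp_rate": 1.0,
    "mbp": 0.8,
    "temperature": 0.3,
    "pao2": 0.15,
    "ph": 0.15,
    "lactate": 0.10,
    "creatinine": 0.08,
    "wbc": 0.08,
    "glucose": 0.2,
    "vasopressor_dose": 0.5,
}


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def ideal_levels_for_severity(s: int, fio2_offset: int = 0) -> tuple[int, int, int]:
    """Severity-dependent ideal setting levels (peep, fio2, tidal volume).

    Sicker patients need more PEEP and FiO2 and a lower (lung-protective)
    tidal volume; ``fio2_offset`` shifts the oxygen requirement for
    patients with a heavier comorbidity burden.
    """
    s = int(np.clip(s, 0, 4))
    peep = 1 if s >= 3 else 0
    fio2 = {0: 0, 1: 0, 2: 1, 3: 1, 4: 2}[s]
    tv = 1 if s <= 2 else 0
    return peep, min(2, fio2 + fio2_offset), tv


@dataclass
class SimulatorConfig:
    """Generative-model configuration; identical config + seed gives identical output."""

    n_patients: int = 1000
    seed: int = 0
    mode: str = "continuous"  # "continuous" | "tabular"
    severity_levels: int = 5
    ideal_action_map: Callable[[int, int], tuple[int, int, int]] | None = None
    transition_noise: float = 0.15  # hourly severity noise sd (continuous); base worsening prob (tabular)
    behavior_epsilon: float = 0.3  # prob physician picks a uniform-random action
    behavior_bias_prob: float = 0.35  # continuous mode: prob a patient's physician
    # holds a persistent one-level practice bias in one setting dimension
    perception_noise: float = 0.3  # sd of the physician's severity estimate
    # (clinicians read the same noisy charts the agent reads, not the latent state)
    missingness_rate: float = 0.2
    observation_rate_per_hour: float = 1.0
    mortality_logit_coefficients: tuple[float, float] = (-3.0, 0.9)
    max_hours: int = 48
    wean_threshold: float = 2.0
    drift_penalty: float = 0.08  # severity increase per level-distance from ideal, per hour
    recovery_rate: float = 0.12  # spontaneous severity decrease per hour

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.mode not in ("continuous", "tabular"):
            raise ValueError(f"mode must be 'continuous' or 'tabular', got {self.mode!r}")
        if self.severity_levels < 2:
            raise ValueError("severity_levels must be >= 2")
        for name in ("missingness_rate", "behavior_epsilon", "behavior_bias_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.transition_noise < 0:
            raise ValueError("transition_noise must be non-negative")
        if self.perception_noise < 0:
            raise ValueError("perception_noise must be non-negative")
        if self.observation_rate_per_hour <= 0:
            raise ValueError("observation_rate_per_hour must be positive")
        if self.max_hours < 24:
            raise ValueError("max_hours must be >= 24 (cohort requires 24 h of ventilation)")
        if not 0 <= self.wean_threshold <= self.severity_levels:
            raise ValueError("wean_threshold must lie within the severity range")
        if len(self.mortality_logit_coefficients) != 2:
            raise ValueError("mortality_logit_coefficients must be (intercept, slope)")

    def ideal_levels(self, severity: int, fio2_offset: int = 0) -> tuple[int, int, int]:
        fn = self.ideal_action_map or ideal_levels_for_severity
        return fn(severity, fio2_offset)

    def ideal_action(self, severity: int, fio2_offset: int = 0) -> int:
        return int(_ACTION_SPACE.index_of(*self.ideal_levels(severity, fio2_offset)))

    def mortality_prob(self, severity: float) -> float:
        c0, c1 = self.mortality_logit_coefficients
        return _sigmoid(c0 + c1 * float(severity))


@dataclass
class RawEventTable:
    """Long-format irregular observations plus per-patient outcomes.

    ``events`` columns: patient_id, time_h, variable, value.
    ``outcomes`` columns: patient_id, hospital_mortality, wean_time_h (NaN
    if the patient was never weaned before the horizon).
    """

    events: pd.DataFrame
    outcomes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.events["patient_id"]) - set(self.outcomes["patient_id"])
        if missing:
            raise ValueError(f"patients without outcome record: {sorted(missing)[:5]}")
        if len(self.events) and (self.events["time_h"] < 0).any():
            raise ValueError("negative time_h in events")

    def to_csv(self, events_path, outcomes_path) -> None:
        self.events.to_csv(events_path, index=False)
        self.outcomes.to_csv(outcomes_path, index=False)

    @classmethod
    def from_csv(cls, events_path, outcomes_path) -> "RawEventTable":
        return cls(pd.read_csv(events_path), pd.read_csv(outcomes_path))


class TabularEnv:
    """The stationary tabular MDP implied by a tabular-mode configuration.

    States 0..L-1 are alive severity levels; state L is absorbing. Taking
    action ``a`` in state ``s``: with probability ``term(s)`` the episode
    ends (death with the severity-dependent logistic probability, terminal
    reward +a_param or -a_param/2); otherwise the intermittent vital-sign
    reward for ``s`` accrues and severity drifts up or down with
    probabilities that worsen with the level distance to the ideal action.
    """

    # Exit hazards per 4-h step. Below the wean threshold patients leave
    # quickly (weaning). Above it, a discharge/censoring hazard of 1/6
    # stands in for the deterministic 48-h analysis cutoff: it keeps the
    # process stationary (so value iteration is exact) while ending ~90%
    # of episodes within the 12-step window, as the cohort design does.
    WEAN_TERM_PROB = 0.30
    BASE_TERM_PROB = 1.0 / 6.0
    MAX_STEPS = 300

    def __init__(self, config: SimulatorConfig):
        config.validate()
        if config.mode != "tabular":
            raise ValueError("TabularEnv requires mode='tabular'")
        self.config = config
        L = config.severity_levels
        self.n_states = L
        self.ideal_actions = np.array(
            [config.ideal_action(s) for s in range(L)], dtype=int
        )

        # level distance to ideal, per (state, action)
        p_lv, f_lv, t_lv = _ACTION_SPACE.levels_of_index(np.arange(N_ACTIONS))
        self.distance = np.zeros((L, N_ACTIONS))
        for s in range(L):
            ip, if_, it = config.ideal_levels(s)
            self.distance[s] = (
                np.abs(p_lv - ip) + np.abs(f_lv - if_) + np.abs(t_lv - it)
            )

        self.term_prob = np.where(
            np.arange(L) < config.wean_threshold, self.WEAN_TERM_PROB, self.BASE_TERM_PROB
        )
        self.death_prob = np.array([config.mortality_prob(s) for s in range(L)])
        # vital-sign range membership as a function of severity
        self.spo2_in = np.arange(L) <= 1
        self.mbp_in = np.arange(L) <= 2

        p_up = np.clip(config.transition_noise + 0.08 * self.distance, 0.0, 0.9)
        p_down = np.clip(0.30 - 0.05 * self.distance, 0.02, 1.0)
        drift = np.zeros((N_ACTIONS, L, L))
        for a in range(N_ACTIONS):
            for s in range(L):
                up, down = p_up[s, a], p_down[s, a]
                stay = 1.0 - up - down
                drift[a, s, min(s + 1, L - 1)] += up
                drift[a, s, max(s - 1, 0)] += down
                drift[a, s, s] += stay
        self.drift = drift

        # full matrices over L+1 states (last absorbing)
        P = np.zeros((N_ACTIONS, L + 1, L + 1))
        P[:, :L, :L] = drift * (1.0 - self.term_prob)[None, :, None]
        P[:, :L, L] = self.term_prob[None, :]
        P[:, L, L] = 1.0
        self.transition_matrices = P

    def intermittent_rewards(self, params: RewardParams) -> np.ndarray:
        return np.where(self.mbp_in, params.b, -params.b / 2.0) + np.where(
            self.spo2_in, params.c, -params.c / 2.0
        )

    def expected_rewards(self, params: RewardParams) -> np.ndarray:
        """Expected one-step reward R(s, a) including the termination branch."""
        r_int = self.intermittent_rewards(params)
        r_term = params.a * (1.0 - self.death_prob) - (params.a / 2.0) * self.death_prob
        r = self.term_prob * r_term + (1.0 - self.term_prob) * r_int
        return np.tile(r, (N_ACTIONS, 1)).T  # reward independent of action

    def encode_state(self, s: int, n_features: int = 40) -> np.ndarray:
        x = np.zeros(n_features)
        x[int(s)] = 1.0
        return x

    def encode_states(self, states: np.ndarray, n_features: int = 40) -> np.ndarray:
        out = np.zeros((len(states), n_features))
        out[np.arange(len(states)), np.asarray(states, dtype=int)] = 1.0
        return out

    def behavior_policy(self, epsilon: float | None = None) -> EpsilonIdealTabularPolicy:
        eps = self.config.behavior_epsilon if epsilon is None else epsilon
        return EpsilonIdealTabularPolicy(self.ideal_actions, eps)

    def policy_matrix(self, policy: Policy) -> np.ndarray:
        """Per-severity action probabilities (L, 18) for vectorized rollouts."""
        probs = np.stack(
            [policy.action_probabilities(self.encode_state(s)) for s in range(self.n_states)]
        )
        if probs.shape != (self.n_states, N_ACTIONS) or np.any(probs < -1e-12):
            raise ValueError("policy must emit probability vectors over the 18 actions")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("policy probabilities must sum to 1 per state")
        return np.clip(probs, 0.0, None)

    def sample_trajectories(
        self,
        policy: Policy,
        n_trajectories: int,
        params: RewardParams,
        rng: np.random.Generator,
    ) -> list[dict]:
        """Sample full episodes; each dict has states, actions, rewards, mortality.

        Start severity is uniform over alive states. Episodes end by the
        termination hazard (a safety cap at 300 steps forces termination
        with negligible probability mass).
        """
        pmat = self.policy_matrix(policy)
        pcum = np.cumsum(pmat, axis=1)
        r_int = self.intermittent_rewards(params)
        L = self.n_states
        drift_cum = np.cumsum(self.drift, axis=2)  # (A, L, L)

        out = []
        for _ in range(n_trajectories):
            s = int(rng.integers(L))
            states, actions, rewards = [], [], []
            mortality = False
            for t in range(self.MAX_STEPS):
                a = int(np.searchsorted(pcum[s], rng.random(), side="right"))
                a = min(a, N_ACTIONS - 1)
                states.append(s)
                actions.append(a)
                if rng.random() < self.term_prob[s] or t == self.MAX_STEPS - 1:
                    mortality = rng.random() < self.death_prob[s]
                    rewards.append(-params.a / 2.0 if mortality else params.a)
                    break
                rewards.append(float(r_int[s]))
                s = int(np.searchsorted(drift_cum[a, s], rng.random(), side="right"))
                s = min(s, L - 1)
            out.append(
                {
                    "severities": np.array(states, dtype=int),
                    "states": self.encode_states(np.array(states, dtype=int)),
                    "actions": np.array(actions, dtype=int),
                    "rewards": np.array(rewards, dtype=float),
                    "mortality": bool(mortality),
                }
            )
        return out

    def rollout_value(
        self,
        policy: Policy,
        n_rollouts: int,
        gamma: float,
        params: RewardParams,
        rng: np.random.Generator,
    ) -> "PolicyValue":
        """Vectorized Monte-Carlo estimate of the policy's discounted value."""
        pmat = self.policy_matrix(policy)
        pcum = np.cumsum(pmat, axis=1)
        drift_cum = np.cumsum(self.drift, axis=2)
        r_int = self.intermittent_rewards(params)
        L = self.n_states

        s = rng.integers(L, size=n_rollouts)
        alive = np.ones(n_rollouts, dtype=bool)
        returns = np.zeros(n_rollouts)
        disc = 1.0
        for t in range(self.MAX_STEPS):
            if not alive.any():
                break
            u = rng.random(n_rollouts)
            a = np.minimum(
                (u[:, None] >= pcum[s]).sum(axis=1), N_ACTIONS - 1
            )
            ends = (rng.random(n_rollouts) < self.term_prob[s]) | (t == self.MAX_STEPS - 1)
            dies = rng.random(n_rollouts) < self.death_prob[s]
            r_step = np.where(
                ends, np.where(dies, -params.a / 2.0, params.a), r_int[s]
            )
            returns += np.where(alive, disc * r_step, 0.0)
            # transition survivors
            u2 = rng.random(n_rollouts)
            s_next = np.minimum((u2[:, None] >= drift_cum[a, s]).sum(axis=1), L - 1)
            s = np.where(ends, s, s_next)
            alive &= ~ends
            disc *= gamma
        return PolicyValue(
            value=float(returns.mean()),
            stderr=float(returns.std(ddof=1) / math.sqrt(n_rollouts)),
            n=n_rollouts,
        )


@dataclass
class GroundTruth:
    """Oracle information attached to a simulated cohort."""

    severity_paths: dict  # patient_id -> {"time_h": [...], "severity": [...]}
    optimal_actions: np.ndarray | None = None  # tabular: per-state ideal action
    transition_matrices: np.ndarray | None = None  # tabular: (18, L+1, L+1)
    env: TabularEnv | None = None

    def __post_init__(self) -> None:
        if self.transition_matrices is not None:
            rows = self.transition_matrices.sum(axis=2)
            if not np.allclose(rows, 1.0, atol=1e-12):
                raise ValueError("transition matrix rows must sum to 1")

    def to_json(self, path) -> None:
        payload = {
            "severity_paths": {
                str(pid): {"time_h": list(map(float, p["time_h"])),
                           "severity": list(map(float, p["severity"]))}
                for pid, p in self.severity_paths.items()
            },
            "optimal_actions": None
            if self.optimal_actions is None
            else [int(a) for a in self.optimal_actions],
            "transition_matrices": None
            if self.transition_matrices is None
            else self.transition_matrices.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class PolicyValue:
    """Monte-Carlo value estimate with its standard error."""

    value: float
    stderr: float
    n: int


# ---------------------------------------------------------------------------
# vital-sign emission models (severity x in [0, 4])
# ---------------------------------------------------------------------------

def _vital_mean(var: str, x: float) -> float:
    # healthy patients (x=0) sit inside the optimal SpO2/MBP target ranges;
    # deterioration pushes them out and toward the flag thresholds
    return {
        "spo2": 97.0 - 1.8 * x,
        "pao2": 95.0 - 9.0 * x,
        "ph": 7.40 - 0.04 * x,
        "mbp": 76.0 - 4.0 * x,
        "heart_rate": 72.0 + 9.0 * x,
        "resp_rate": 14.0 + 3.0 * x,
        "temperature": 36.8 + 0.3 * x,
        "lactate": math.exp(0.2 + 0.35 * x),
        "creatinine": math.exp(-0.1 + 0.15 * x),
        "wbc": 9.0 + 1.5 * x,
        "glucose": 130.0 + 10.0 * x,
        "vasopressor_dose": max(0.0, x - 2.0) * 0.15,
    }[var]


_VITAL_SD = {
    "spo2": 1.3,
    "pao2": 10.0,
    "ph": 0.025,
    "mbp": 6.0,
    "heart_rate": 8.0,
    "resp_rate": 2.5,
    "temperature": 0.4,
    "lactate": 0.5,
    "creatinine": 0.2,
    "wbc": 2.5,
    "glucose": 25.0,
    "vasopressor_dose": 0.05,
}

_VITAL_CLIP = {
    "spo2": (60.0, 100.0),
    "pao2": (25.0, 400.0),
    "ph": (6.8, 7.8),
    "mbp": (30.0, 160.0),
    "heart_rate": (25.0, 220.0),
    "resp_rate": (4.0, 60.0),
    "temperature": (32.0, 42.0),
    "lactate": (0.3, 25.0),
    "creatinine": (0.2, 18.0),
    "wbc": (0.5, 60.0),
    "glucose": (35.0, 600.0),
    "vasopressor_dose": (0.0, 3.0),
}


def _sample_vital(var: str, x: float, rng: np.random.Generator) -> float:
    v = _vital_mean(var, x) + _VITAL_SD[var] * rng.standard_normal()
    lo, hi = _VITAL_CLIP[var]
    return float(np.clip(v, lo, hi))


def _setting_values(levels: tuple[int, int, int], rng: np.random.Generator) -> dict:
    peep = {0: 5.0, 1: 10.0}[levels[0]] + 0.4 * rng.standard_normal()
    fio2 = {0: 35.0, 1: 50.0, 2: 70.0}[levels[1]] + 2.5 * rng.standard_normal()
    tv = {0: 5.5, 1: 7.0, 2: 9.0}[levels[2]] + 0.25 * rng.standard_normal()
    return {"peep": float(np.clip(peep, 0, 20)),
            "fio2": float(np.clip(fio2, 21, 100)),
            "tidal_volume": float(np.clip(tv, 3, 12))}


def _draw_statics(rng: np.random.Generator) -> dict:
    height = float(np.clip(rng.normal(170, 10), 145, 205))
    weight = float(np.clip(rng.normal(82, 18), 40, 180))
    vals = {
        "age": float(np.clip(rng.normal(64, 15), 16, 95)),
        "sex": float(rng.random() < 0.43),
        "height": height,
        "weight": weight,
        "bmi": weight / (height / 100.0) ** 2,
        "elixhauser": float(np.clip(rng.gamma(2.0, 2.2), 0, 28)),
        "sofa": float(min(rng.poisson(3), 20)),
        "sirs": float(rng.integers(0, 5)),
        "gcs": float(rng.integers(3, 16)),
        "hemoglobin": float(np.clip(rng.normal(10.5, 1.8), 4.5, 19)),
        "platelets": float(np.clip(rng.lognormal(5.3, 0.4), 15, 950)),
        "sodium": float(np.clip(rng.normal(139, 4), 115, 165)),
        "potassium": float(np.clip(rng.normal(4.1, 0.5), 2.2, 7.5)),
        "bicarbonate": float(np.clip(rng.normal(24, 4), 6, 48)),
        "bun": float(np.clip(rng.lognormal(3.1, 0.5), 3, 140)),
        "bilirubin": float(np.clip(rng.lognormal(-0.2, 0.7), 0.1, 28)),
        "albumin": float(np.clip(rng.normal(3.2, 0.5), 1.2, 5.5)),
        "pf_ratio": float(np.clip(rng.normal(250, 80), 45, 580)),
    }
    for name, p in (
        ("comorb_chf", 0.22), ("comorb_copd", 0.20), ("comorb_ckd", 0.15),
        ("comorb_diabetes", 0.28), ("comorb_liver", 0.08), ("comorb_cancer", 0.13),
        ("comorb_stroke", 0.09), ("comorb_cad", 0.20), ("comorb_immunosup", 0.07),
        ("comorb_obesity", 0.25),
    ):
        vals[name] = float(rng.random() < p)
    return vals


def _fio2_offset(statics: dict) -> int:
    return 1 if statics["elixhauser"] > 6.0 else 0


def _draw_practice_bias(config: SimulatorConfig, rng: np.random.Generator):
    """Persistent one-level practice bias of a patient's physician, or None.

    Models documented practice variation: some clinicians habitually run
    one setting a level high or low regardless of the patient's needs.
    """
    if rng.random() >= config.behavior_bias_prob:
        return None
    dim = int(rng.integers(3))
    direction = 1 if rng.random() < 0.5 else -1
    return dim, direction


def _apply_bias(levels: tuple[int, int, int], bias) -> tuple[int, int, int]:
    if bias is None:
        return levels
    counts = _ACTION_SPACE.level_counts
    lv = list(levels)
    dim, direction = bias
    lv[dim] = int(np.clip(lv[dim] + direction, 0, counts[dim] - 1))
    return tuple(lv)


def simulate_cohort(config: SimulatorConfig) -> tuple[RawEventTable, GroundTruth]:
    """Generate a cohort of mechanically ventilated synthetic patients.

    Returns the long-format event table (irregular observation times,
    per-variable missingness) with per-patient outcomes, plus the ground
    truth (hourly severity paths and, in tabular mode, the per-state
    optimal actions and exact transition matrices).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L1 = config.severity_levels - 1
    tabular = config.mode == "tabular"
    env = TabularEnv(config) if tabular else None

    rows: list[tuple] = []
    outcome_rows: list[tuple] = []
    severity_paths: dict = {}

    for i in range(config.n_patients):
        pid = f"p{i:05d}"
        statics = _draw_statics(rng)
        offset = 0 if tabular else _fio2_offset(statics)
        bias = None if tabular else _draw_practice_bias(config, rng)
        for var, val in statics.items():
            rows.append((pid, 0.0, var, val))

        x = float(rng.integers(1, min(4, L1) + 1)) if tabular else float(rng.uniform(1.0, 3.5))
        path_t, path_x = [0.0], [x]
        action = config.ideal_action(int(round(x)), offset)  # re-chosen at t=0 below
        level_at_last_set = int(round(x))
        wean_time = None
        low_hours = 0

        for t in range(config.max_hours):
            # physician reassessment: on the 4-h grid, or when the patient's
            # PERCEIVED severity level changes (clinicians estimate severity
            # from noisy charts, not from the latent state)
            if tabular:
                x_seen = x
            else:
                x_seen = float(np.clip(
                    x + config.perception_noise * rng.standard_normal(), 0, L1
                ))
            if t % 4 == 0 or int(round(x_seen)) != level_at_last_set:
                if rng.random() < config.behavior_epsilon:
                    action = int(rng.integers(N_ACTIONS))
                else:
                    lv = _apply_bias(config.ideal_levels(int(round(x_seen)), offset), bias)
                    action = int(_ACTION_SPACE.index_of(*lv))
                level_at_last_set = int(round(x_seen))
                levels = tuple(int(v) for v in _ACTION_SPACE.levels_of_index(action))
                sv = _setting_values(levels, rng)
                for var in SETTING_VARIABLES:
                    rows.append((pid, float(t), var, sv[var]))

            # observations during [t, t+1)
            for var in DYNAMIC_VARIABLES:
                lam = _OBS_RATE[var] * config.observation_rate_per_hour
                for _ in range(rng.poisson(lam)):
                    if rng.random() < config.missingness_rate:
                        continue
                    ts = float(t + rng.random())
                    rows.append((pid, ts, var, _sample_vital(var, x, rng)))

            # severity update over the hour
            s_lvl = int(round(np.clip(x, 0, L1)))
            ip, if_, it = config.ideal_levels(s_lvl, offset)
            p_lv, f_lv, t_lv = (int(v) for v in _ACTION_SPACE.levels_of_index(action))
            d = abs(p_lv - ip) + abs(f_lv - if_) + abs(t_lv - it)
            if tabular:
                if (t + 1) % 4 == 0:  # tabular severity moves on the 4-h grid
                    p_up = min(0.9, config.transition_noise + 0.08 * d)
                    p_down = max(0.02, 0.30 - 0.05 * d) if d > 0 else 0.30
                    if config.transition_noise == 0 and d == 0:
                        p_up = 0.0
                    u = rng.random()
                    if u < p_up:
                        x = min(x + 1, L1)
                    elif u < p_up + p_down:
                        x = max(x - 1, 0)
            else:
                x += (
                    config.drift_penalty * d
                    - config.recovery_rate
                    + config.transition_noise * rng.standard_normal()
                )
                x = float(np.clip(x, 0.0, L1))
            path_t.append(float(t + 1))
            path_x.append(x)

            low_hours = low_hours + 1 if x < config.wean_threshold else 0
            if t + 1 >= 24 and low_hours >= 4:
                wean_time = float(t + 1)
                break

        mortality = int(rng.random() < config.mortality_prob(x))
        outcome_rows.append((pid, mortality, wean_time if wean_time is not None else np.nan))
        severity_paths[pid] = {"time_h": path_t, "severity": path_x}

    events = pd.DataFrame(rows, columns=["patient_id", "time_h", "variable", "value"])
    events = events.sort_values(["patient_id", "time_h"], kind="stable").reset_index(drop=True)
    outcomes = pd.DataFrame(
        outcome_rows, columns=["patient_id", "hospital_mortality", "wean_time_h"]
    )
    ground = GroundTruth(
        severity_paths=severity_paths,
        optimal_actions=env.ideal_actions.copy() if env else None,
        transition_matrices=env.transition_matrices.copy() if env else None,
        env=env,
    )
    return RawEventTable(events, outcomes), ground


def optimal_policy_tabular(
    ground: GroundTruth,
    reward: RewardParams,
    discount: float,
    tol: float = 1e-10,
) -> tuple[TabularPolicy, np.ndarray]:
    """Exact value iteration on the tabular ground-truth MDP.

    Iterates to a sup-norm fixed point below ``tol`` and returns the greedy
    policy (ties broken toward the lowest action index) with the alive-state
    values.
    """
    if ground.env is None:
        raise ValueError("ground truth has no tabular environment")
    if discount >= 1.0:
        raise ValueError("discount must be < 1 for guaranteed contraction")
    env = ground.env
    P = env.transition_matrices  # (A, L+1, L+1)
    R = env.expected_rewards(reward)  # (L, A)
    L = env.n_states
    V = np.zeros(L + 1)
    for _ in range(100_000):
        Q = R.T + discount * (P[:, :L, :] @ V)  # (A, L)
        V_new = np.r_[Q.max(axis=0), 0.0]
        if np.max(np.abs(V_new - V)) < tol:
            V = V_new
            break
        V = V_new
    Q = R.T + discount * (P[:, :L, :] @ V)
    greedy = Q.argmax(axis=0)  # lowest index on ties
    return TabularPolicy(np.asarray(greedy, dtype=int)), V[:L]


def sample_tabular_transitions(
    config: SimulatorConfig,
    params: RewardParams,
    n_trajectories: int,
    seed: int,
    epsilon: float | None = None,
) -> tuple[TransitionDataset, list[dict], TabularEnv]:
    """Behavior-policy episodes from the tabular MDP as a transition dataset.

    States use the one-hot severity encoding padded to the schema width, so
    the dataset feeds the same agent code as pipeline-derived cohorts.
    """
    config.validate()
    env = TabularEnv(config)
    rng = np.random.default_rng(seed)
    behavior = env.behavior_policy(epsilon)
    trajs = env.sample_trajectories(behavior, n_trajectories, params, rng)

    states, actions, rewards, next_states, done, pids, sidx = [], [], [], [], [], [], []
    for n, tr in enumerate(trajs):
        T = len(tr["actions"])
        enc = tr["states"]
        for t in range(T):
            states.append(enc[t])
            actions.append(tr["actions"][t])
            rewards.append(tr["rewards"][t])
            last = t == T - 1
            next_states.append(np.full(enc.shape[1], np.nan) if last else enc[t + 1])
            done.append(last)
            pids.append(f"t{n:06d}")
            sidx.append(t)
    ds = TransitionDataset(
        states=np.array(states),
        actions=np.array(actions, dtype=int),
        rewards=np.array(rewards, dtype=float),
        next_states=np.array(next_states),
        done=np.array(done, dtype=bool),
        patient_ids=np.array(pids),
        step_index=np.array(sidx, dtype=int),
    )
    return ds, trajs, env


def true_policy_value(
    policy: Policy | None,
    config: SimulatorConfig,
    n_rollouts: int,
    discount: float,
    seed: int,
    params: RewardParams | None = None,
    schema: FeatureSchema | None = None,
) -> PolicyValue:
    """Monte-Carlo oracle for a policy's expected discounted return.

    ``policy=None`` evaluates the simulator's own (imperfect) behavior
    policy. In continuous mode the policy is queried every 4 simulated
    hours on the schema-normalized state built from the current
    severity-conditional vital means plus the patient's static features.
    """
    config.validate()
    params = params or RewardParams()
    if config.mode == "tabular":
        env = TabularEnv(config)
        pol = policy if policy is not None else env.behavior_policy()
        return env.rollout_value(pol, n_rollouts, discount, params, np.random.default_rng(seed))
    return _continuous_rollout_value(policy, config, n_rollouts, discount, seed, params,
                                     schema or default_schema())


def _continuous_rollout_value(
    policy: Policy | None,
    config: SimulatorConfig,
    n_rollouts: int,
    discount: float,
    seed: int,
    params: RewardParams,
    schema: FeatureSchema,
) -> PolicyValue:
    rng = np.random.default_rng(seed)
    L1 = config.severity_levels - 1
    names = schema.names
    returns = np.empty(n_rollouts)

    for n in range(n_rollouts):
        statics = _draw_statics(rng)
        offset = _fio2_offset(statics)
        bias = _draw_practice_bias(config, rng)
        x = float(rng.uniform(1.0, 3.5))
        total, disc = 0.0, 1.0
        low_hours = 0
        t = 0
        action = None
        level_at_last_set = None
        mbp_obs: list[float] = []
        spo2_obs: list[float] = []
        # observed chart values, maintained like the preprocessing pipeline:
        # an admission panel, then irregular observations carried forward
        chart = {v: _sample_vital(v, x, rng) for v in DYNAMIC_VARIABLES}
        window: dict[str, list[float]] = {v: [] for v in DYNAMIC_VARIABLES}
        ended = False
        while t < config.max_hours:
            # decision cadence identical for every policy: the 4-h grid plus
            # any perceived severity-level change (bedside reassessment on
            # the charted, not the latent, state)
            x_seen = float(np.clip(
                x + config.perception_noise * rng.standard_normal(), 0, L1
            ))
            if t % 4 == 0 or int(round(x_seen)) != level_at_last_set:
                if policy is None:
                    if rng.random() < config.behavior_epsilon:
                        action = int(rng.integers(N_ACTIONS))
                    else:
                        lv = _apply_bias(config.ideal_levels(int(round(x_seen)), offset), bias)
                        action = int(_ACTION_SPACE.index_of(*lv))
                else:
                    for v, obs in window.items():
                        if obs:
                            chart[v] = float(np.mean(obs))
                            obs.clear()
                    raw = dict(chart)
                    raw.update(statics)
                    state = np.array(
                        [schema[nm].normalize(raw[nm]) for nm in names], dtype=float
                    )
                    action = int(policy.select(state))
                    if not 0 <= action < N_ACTIONS:
                        raise ValueError(
                            f"policy emitted action {action} outside the action space"
                        )
                level_at_last_set = int(round(x_seen))
            p_lv, f_lv, t_lv = (int(v) for v in _ACTION_SPACE.levels_of_index(action))

            mbp_obs.append(_sample_vital("mbp", x, rng))
            spo2_obs.append(_sample_vital("spo2", x, rng))
            if policy is not None:
                # irregular charting at the pipeline's observation rates
                for v in DYNAMIC_VARIABLES:
                    lam = _OBS_RATE[v] * config.observation_rate_per_hour
                    k = rng.poisson(lam)
                    for _ in range(k):
                        if rng.random() >= config.missingness_rate:
                            window[v].append(_sample_vital(v, x, rng))
            s_lvl = int(round(np.clip(x, 0, L1)))
            ip, if_, it = config.ideal_levels(s_lvl, offset)
            d = abs(p_lv - ip) + abs(f_lv - if_) + abs(t_lv - it)
            x += (
                config.drift_penalty * d
                - config.recovery_rate
                + config.transition_noise * rng.standard_normal()
            )
            x = float(np.clip(x, 0.0, L1))
            t += 1
            low_hours = low_hours + 1 if x < config.wean_threshold else 0
            ended = (t >= 24 and low_hours >= 4) or t >= config.max_hours

            if t % 4 == 0 and not ended:
                # close the 4-h reward window
                r = compute_reward(
                    float(np.mean(mbp_obs)), float(np.mean(spo2_obs)), False, False, params
                )
                total += disc * float(r)
                disc *= discount
                mbp_obs, spo2_obs = [], []
            if ended:
                mortality = rng.random() < config.mortality_prob(x)
                total += disc * (-params.a / 2.0 if mortality else params.a)
                break
        returns[n] = total
    return PolicyValue(
        value=float(returns.mean()),
        stderr=float(returns.std(ddof=1) / math.sqrt(n_rollouts)),
        n=n_rollouts,
    )
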