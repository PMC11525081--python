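"""Policy interface shared by the simulator, the agent and the evaluators.

A policy maps a state vector to a probability distribution over the 18
discrete ventilator actions; deterministic policies are point masses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mdp import N_ACTIONS


class Policy:
    """Base class: subclasses implement :meth:`action_probabilities`."""

    n_actions: int = N_ACTIONS

    def action_probabilities(self, state: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def select(self, state: np.ndarray) -> int:
        """Deterministic choice: highest-probability action, lowest index on ties."""
        return int(np.argmax(self.action_probabilities(state)))

    def sample(self, state: np.ndarray, rng: np.random.Generator) -> int:
        p = self.action_probabilities(state)
        return int(rng.choice(self.n_actions, p=p))


@dataclass
class UniformRandomPolicy(Policy):
    """Every action equally likely in every state."""

    def action_probabilities(self, state: np.ndarray) -> np.ndarray:
        return np.full(self.n_actions, 1.0 / self.n_actions)


@dataclass
class ConstantActionPolicy(Policy):
    """Point mass on one fixed action (the one-size-fits-all benchmark)."""

    action: int

    def __post_init__(self) -> None:
        if not 0 <= self.action < self.n_actions:
            raise ValueError(f"action {self.action} outside 0..{self.n_actions - 1}")

    def action_probabilities(self, state: np.ndarray) -> np.ndarray:
        p = np.zeros(self.n_actions)
        p[self.action] = 1.0
        return p


def decode_tabular_state(state: np.ndarray, n_levels: int) -> int:
    """Recover the severity level from a one-hot-in-front state encoding."""
    return int(np.argmax(np.asarray(state)[:n_levels]))


@dataclass
class TabularPolicy(Policy):
    """Deterministic map severity-level -> action, read off an array."""

    actions_by_state: np.ndarray

    def action_probabilities(self, state: np.ndarray) -> np.ndarray:
        s = decode_tabular_state(state, len(self.actions_by_state))
        p = np.zeros(self.n_actions)
        p[int(self.actions_by_state[s])] = 1.0
        return p


@dataclass
class EpsilonIdealTabularPolicy(Policy):
    """Behavior policy: ideal action with prob 1 - eps, else uniform over all.

    P(a | s) = (1 - eps) * [a == ideal(s)] + eps / n_actions.
    """

    ideal_actions: np.ndarray
    epsilon: float

    def action_probabilities(self, state: np.ndarray) -> np.ndarray:
        s = decode_tabular_state(state, len(self.ideal_actions))
        p = np.full(self.n_actions, self.epsilon / self.n_actions)
        p[int(self.ideal_actions[s])] += 1.0 - self.epsilon
        return p
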