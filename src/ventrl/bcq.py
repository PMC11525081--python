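"""Discrete batch-constrained Q-learning (BCQ).

Two networks with identical architecture (two hidden layers of 256 ReLU
units) are trained jointly on logged transitions: a supervisor network
P(s, .) behavior-clones the physicians' action distribution with the
probability loss L_P = -log P(s_t, a_t), and a policy network Q(s, .)
learns action values with a temporal-difference value loss L_Q, combined
as L = L_Q + beta * L_P. At decision time the policy may only choose
actions the supervisor deems sufficiently likely — those with
P(a|s) / max_a' P(a'|s) >= tau — which keeps the learned policy close to
the clinicians' and controls extrapolation error. A slowly tracking target
network (Polyak rate alpha) stabilizes the TD targets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .mdp import N_ACTIONS, TransitionDataset
from .nets import MLP, Adam, softmax
from .policies import Policy

_MASK_EPS = 1e-12


@dataclass(frozen=True)
class BCQHyperparams:
    learning_rate: float = 3e-4
    discount: float = 0.99
    batch_size: int = 32
    tracking_rate: float = 0.01  # alpha: target-network Polyak rate
    extrapolation_threshold: float = 0.05  # tau
    loss_tradeoff: float = 1.0  # beta
    hidden_widths: tuple[int, ...] = (256, 256)
    supervisor_pretrain_iterations: int = 6000  # upper bound; early stopping applies
    supervisor_patience: int = 4  # validation checks without improvement before stopping
    supervisor_val_fraction: float = 0.1  # held-out patient fraction for early stopping
    training_iterations: int = 20000
    log_interval: int = 500
    target_clip: tuple[float, float] | None = None  # auto-set by train_bcq if None
    value_loss: str = "squared"  # "squared" | "huber"
    huber_delta: float = 1.0
    freeze_supervisor: bool = False  # supervisor pre-trains, then refines jointly
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "batch_size", "tracking_rate", "loss_tradeoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.extrapolation_threshold <= 1.0:
            raise ValueError("extrapolation_threshold must lie in [0, 1]")
        if not 0.0 <= self.discount < 1.0:
            raise ValueError("discount must lie in [0, 1)")
        if self.value_loss not in ("squared", "huber"):
            raise ValueError("value_loss must be 'squared' or 'huber'")


class BCQAgent(Policy):
    """Supervisor + policy + target networks over a fixed state width."""

    def __init__(self, n_features: int, hp: BCQHyperparams, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(hp.seed)
        self.hp = hp
        self.n_features = n_features
        sizes = (n_features, *hp.hidden_widths, N_ACTIONS)
        self.supervisor = MLP(sizes, rng)
        self.policy_net = MLP(sizes, rng)
        self.target_net = MLP(sizes, rng)
        self.target_net.copy_from(self.policy_net, rate=1.0)
        self._opt_sup = Adam(self.supervisor.params, hp.learning_rate)
        self._opt_pol = Adam(self.policy_net.params, hp.learning_rate)
        self.training_log: list[dict] = []

    # -- inference ----------------------------------------------------------

    def _check_states(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features}-dimensional states")
        if np.nanmin(X) < -1e-9 or np.nanmax(X) > 1.0 + 1e-9 or np.isnan(X).any():
            raise ValueError("states must lie in [0, 1] with no missing entries")
        return X

    def supervisor_probs(self, states: np.ndarray) -> np.ndarray:
        return softmax(self.supervisor(self._check_states(states)))

    def q_values(self, states: np.ndarray) -> np.ndarray:
        return self.policy_net(self._check_states(states))

    def constrained_mask(self, states: np.ndarray) -> np.ndarray:
        """Boolean (n, 18) mask of admissible actions: P/maxP >= tau."""
        P = self.supervisor_probs(states)
        ratio = P / P.max(axis=1, keepdims=True)
        return ratio >= self.hp.extrapolation_threshold - _MASK_EPS

    def constrained_action_set(self, state: np.ndarray) -> np.ndarray:
        return np.flatnonzero(self.constrained_mask(state)[0])

    def select_actions(self, states: np.ndarray) -> np.ndarray:
        """Constrained-greedy actions: argmax Q over the admissible set."""
        q = self.q_values(states)
        masked = np.where(self.constrained_mask(states), q, -np.inf)
        return masked.argmax(axis=1)  # argmax takes the lowest index on ties

    def select_action(self, state: np.ndarray) -> int:
        return int(self.select_actions(state)[0])

    # Policy interface: point mass on the constrained-greedy action
    def action_probabilities(self, state: np.ndarray) -> np.ndarray:
        p = np.zeros(N_ACTIONS)
        p[self.select_action(state)] = 1.0
        return p

    def select(self, state: np.ndarray) -> int:
        return self.select_action(state)

    def expected_return(self, trajectory: dict) -> float:
        """Q(s_0, pi(s_0)): the agent's value of the trajectory's initial state."""
        states = np.atleast_2d(trajectory["states"])
        if states.shape[0] == 0:
            raise ValueError("empty trajectory")
        s0 = states[:1]
        return float(self.q_values(s0)[0, self.select_action(s0)])

    # -- training -----------------------------------------------------------

    def _supervisor_step(self, states: np.ndarray, actions: np.ndarray, weight: float = 1.0) -> float:
        logits, acts = self.supervisor.forward(states, cache=True)
        P = softmax(logits)
        n = len(actions)
        l_p = float(-np.log(np.clip(P[np.arange(n), actions], 1e-12, None)).mean())
        d = P.copy()
        d[np.arange(n), actions] -= 1.0
        d *= weight / n
        self._opt_sup.step(self.supervisor.backward(acts, d))
        return l_p

    def train_supervisor(self, data: TransitionDataset, iterations: int | None = None,
                         rng: np.random.Generator | None = None,
                         early_stopping: bool = True) -> "BCQAgent":
        """Behavior-cloning pre-training of the supervisor network.

        A patient-level held-out split monitors the validation probability
        loss every 1,000 iterations; training stops once it plateaus and
        the best-scoring parameters are restored. This keeps the
        supervisor at its best-calibrated point: trained further it
        memorizes individual (state, action) pairs, which blurs the
        constraint masks toward the exploration noise in the logs.
        """
        if len(data) == 0:
            raise ValueError("dataset is empty")
        rng = rng or np.random.default_rng(self.hp.seed + 1)
        iterations = self.hp.supervisor_pretrain_iterations if iterations is None else iterations
        self._check_states(data.states)

        val_mask = np.zeros(len(data), dtype=bool)
        if early_stopping:
            patients = data.patients()
            n_val = max(1, int(round(self.hp.supervisor_val_fraction * len(patients))))
            val_patients = set(patients[rng.permutation(len(patients))[:n_val]])
            val_mask = np.isin(data.patient_ids, list(val_patients))
        train_idx = np.flatnonzero(~val_mask)
        val_idx = np.flatnonzero(val_mask)
        use_val = early_stopping and len(val_idx) > 0 and len(train_idx) > 0
        if not use_val:
            train_idx = np.arange(len(data))

        best_val = np.inf
        best_params = None
        stale = 0
        check_every = 1000
        for it in range(iterations):
            idx = train_idx[rng.integers(len(train_idx), size=self.hp.batch_size)]
            self._supervisor_step(data.states[idx], data.actions[idx])
            if use_val and (it + 1) % check_every == 0:
                P = softmax(self.supervisor(data.states[val_idx]))
                val_lp = float(-np.log(
                    np.clip(P[np.arange(len(val_idx)), data.actions[val_idx]], 1e-12, None)
                ).mean())
                if val_lp < best_val - 1e-4:
                    best_val = val_lp
                    best_params = [p.copy() for p in self.supervisor.params]
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.hp.supervisor_patience:
                        break
        if use_val and best_params is not None:
            for p, b in zip(self.supervisor.params, best_params):
                p[...] = b
        return self

    def bcq_training_step(self, batch: TransitionDataset) -> tuple[float, float]:
        """One joint optimization step; returns the loss components (L_Q, L_P)."""
        return self._step(batch.states, batch.actions, batch.rewards,
                          batch.next_states, batch.done)

    def _step(self, s, a, r, ns, done) -> tuple[float, float]:
        hp = self.hp
        n = len(a)

        alive = ~done
        n_alive = int(alive.sum())
        both = np.concatenate([s, ns[alive]], axis=0) if n_alive else s

        # one cached forward over [s; s'] serves training and the next-state argmax
        pol_logits, pol_acts = self.policy_net.forward(both, cache=True)
        sup_logits, sup_acts = self.supervisor.forward(both, cache=True)

        # TD target: y = r for terminal transitions, else r + gamma * Q_target(s', a*)
        y = np.asarray(r, dtype=float).copy()
        if n_alive:
            q_next = pol_logits[n:]
            P = softmax(sup_logits[n:])
            mask = P / P.max(axis=1, keepdims=True) >= hp.extrapolation_threshold - _MASK_EPS
            a_star = np.where(mask, q_next, -np.inf).argmax(axis=1)
            q_tgt = self.target_net(ns[alive])
            boot = q_tgt[np.arange(n_alive), a_star]
            if hp.target_clip is not None:
                # bootstrapped values cannot leave the provable return range
                # of the finite episodes; clipping blocks extrapolation-driven
                # divergence without touching achievable values
                boot = np.clip(boot, hp.target_clip[0], hp.target_clip[1])
            y[alive] += hp.discount * boot

        q_sa = pol_logits[np.arange(n), a]
        err = q_sa - y
        if hp.value_loss == "squared":
            l_q = float(0.5 * np.mean(err**2))
            g = err / n
        else:
            delta = hp.huber_delta
            abs_e = np.abs(err)
            l_q = float(np.where(abs_e <= delta, 0.5 * err**2,
                                 delta * (abs_e - 0.5 * delta)).mean())
            g = np.clip(err, -delta, delta) / n
        d_out = np.zeros_like(pol_logits)
        d_out[np.arange(n), a] = g
        self._opt_pol.step(self.policy_net.backward(pol_acts, d_out))

        Ps = softmax(sup_logits[:n])
        l_p = float(-np.log(np.clip(Ps[np.arange(n), a], 1e-12, None)).mean())
        if not self.hp.freeze_supervisor:
            d_sup = np.zeros_like(sup_logits)
            d_sup[:n] = Ps
            d_sup[np.arange(n), a] -= 1.0
            d_sup[:n] *= hp.loss_tradeoff / n
            self._opt_sup.step(self.supervisor.backward(sup_acts, d_sup))

        if not (np.isfinite(l_q) and np.isfinite(l_p)):
            raise FloatingPointError(f"non-finite loss: L_Q={l_q}, L_P={l_p}")

        self.target_net.copy_from(self.policy_net, rate=hp.tracking_rate)
        return l_q, l_p

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        for name, net in (("sup", self.supervisor), ("pol", self.policy_net),
                          ("tgt", self.target_net)):
            for i, p in enumerate(net.params):
                arrays[f"{name}_{i}"] = p
        hp = asdict(self.hp)
        hp["hidden_widths"] = list(hp["hidden_widths"])
        arrays["meta"] = np.frombuffer(
            json.dumps({"hp": hp, "n_features": self.n_features}).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "BCQAgent":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            hp_d = meta["hp"]
            hp_d["hidden_widths"] = tuple(hp_d["hidden_widths"])
            if hp_d.get("target_clip") is not None:
                hp_d["target_clip"] = tuple(hp_d["target_clip"])
            agent = cls(meta["n_features"], BCQHyperparams(**hp_d))
            for name, net in (("sup", agent.supervisor), ("pol", agent.policy_net),
                              ("tgt", agent.target_net)):
                for i, p in enumerate(net.params):
                    p[...] = z[f"{name}_{i}"]
        return agent


def return_bounds(data: TransitionDataset, discount: float) -> tuple[float, float]:
    """Provable bounds on any policy's discounted return in this dataset.

    Episodes are finite (at most the longest observed trajectory), and
    per-step rewards are bounded by the observed extremes, so
    sum_t gamma^(t-1) r_t is bounded by the extreme reward held for the
    full horizon. Used to clip TD bootstrap targets.
    """
    if len(data) == 0:
        raise ValueError("dataset is empty")
    lengths = np.bincount(pd.factorize(data.patient_ids)[0])
    horizon = int(lengths.max())
    geo = float((discount ** np.arange(max(horizon - 1, 0))).sum())
    r_int = data.rewards[~data.done]
    r_term = data.rewards[data.done]
    int_max = float(r_int.max()) if len(r_int) else 0.0
    int_min = float(r_int.min()) if len(r_int) else 0.0
    term_max = float(r_term.max()) if len(r_term) else 0.0
    term_min = float(r_term.min()) if len(r_term) else 0.0
    # the terminal reward is collected exactly once, at the episode end
    return (
        geo * min(int_min, 0.0) + min(term_min, 0.0),
        geo * max(int_max, 0.0) + max(term_max, 0.0),
    )


def train_bcq(data: TransitionDataset, hp: BCQHyperparams | None = None) -> BCQAgent:
    """Full BCQ training: supervisor pre-training, then joint minibatch steps.

    Deterministic given ``hp.seed``; the agent's ``training_log`` records
    the loss components every ``hp.log_interval`` iterations.
    """
    hp = hp or BCQHyperparams()
    if len(data) == 0:
        raise ValueError("dataset is empty")
    if hp.target_clip is None:
        hp = replace(hp, target_clip=return_bounds(data, hp.discount))
    rng = np.random.default_rng(hp.seed)
    agent = BCQAgent(data.n_features, hp, rng)
    agent.train_supervisor(data, rng=rng)
    s, a, r = data.states, data.actions, data.rewards
    ns, done = data.next_states, data.done
    for it in range(hp.training_iterations):
        idx = rng.integers(len(data), size=hp.batch_size)
        l_q, l_p = agent._step(s[idx], a[idx], r[idx], ns[idx], done[idx])
        if (it + 1) % hp.log_interval == 0 or it == 0:
            agent.training_log.append({"iteration": it + 1, "L_Q": l_q, "L_P": l_p})
    return agent


def training_log_frame(agent: BCQAgent) -> pd.DataFrame:
    return pd.DataFrame(agent.training_log)
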