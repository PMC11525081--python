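"""Discrete action space, clinically guided rewards, and transition datasets.

Ventilator settings (PEEP, FiO2, IBW-adjusted tidal volume) are discretized
into 18 joint actions. Rewards combine intermittent vital-sign terms
(mean arterial pressure and oxygen saturation inside their optimal ranges)
with a terminal survival term. Per-patient step sequences become
(state, action, reward, next_state, done) transition records for offline
Q-learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .schema import FeatureSchema, SETTING_VARIABLES

N_ACTIONS = 18


@dataclass(frozen=True)
class VentilatorActionSpace:
    """Joint discretization of (PEEP, FiO2, tidal volume) into 18 actions.

    Each dimension is cut at its ``*_edges`` thresholds (value < first edge
    -> level 0; value >= last edge -> top level). The default collapses PEEP
    to two levels (most recorded PEEP values sit at 5 cmH2O) and keeps three
    levels for FiO2 and tidal volume, so 2 x 3 x 3 = 18. Index layout:
    ``index = peep_level * 9 + fio2_level * 3 + tv_level``.
    """

    peep_edges: tuple[float, ...] = (7.5,)
    fio2_edges: tuple[float, ...] = (40.0, 60.0)
    tv_edges: tuple[float, ...] = (6.0, 8.0)

    def __post_init__(self) -> None:
        for name, edges in (
            ("peep_edges", self.peep_edges),
            ("fio2_edges", self.fio2_edges),
            ("tv_edges", self.tv_edges),
        ):
            if any(b <= a for a, b in zip(edges, edges[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if int(np.prod(self.level_counts)) != N_ACTIONS:
            raise ValueError(
                f"level counts {self.level_counts} must multiply to {N_ACTIONS}"
            )

    @property
    def level_counts(self) -> tuple[int, int, int]:
        return (
            len(self.peep_edges) + 1,
            len(self.fio2_edges) + 1,
            len(self.tv_edges) + 1,
        )

    @property
    def dimension_names(self) -> tuple[str, str, str]:
        return ("peep", "fio2", "tidal_volume")

    # -- level arithmetic ---------------------------------------------------

    @staticmethod
    def _level(value, edges) -> np.ndarray:
        return np.searchsorted(np.asarray(edges), np.asarray(value), side="right")

    def levels_of(self, peep, fio2, tv) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            self._level(peep, self.peep_edges),
            self._level(fio2, self.fio2_edges),
            self._level(tv, self.tv_edges),
        )

    def index_of(self, peep_level, fio2_level, tv_level) -> np.ndarray:
        _, n_f, n_t = self.level_counts
        return (np.asarray(peep_level) * n_f + np.asarray(fio2_level)) * n_t + np.asarray(tv_level)

    def levels_of_index(self, action) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        _, n_f, n_t = self.level_counts
        action = np.asarray(action)
        tv = action % n_t
        fio2 = (action // n_t) % n_f
        peep = action // (n_t * n_f)
        return peep, fio2, tv

    def discretize(self, peep, fio2, tv) -> np.ndarray:
        """Map raw setting values to the joint action index (vectorized)."""
        arrs = [np.asarray(x, dtype=float) for x in (peep, fio2, tv)]
        for name, arr in zip(self.dimension_names, arrs):
            if np.any(np.isnan(arr)):
                raise ValueError(
                    f"setting {name!r} has missing values; impute before discretizing"
                )
        p, f, t = self.levels_of(*arrs)
        return self.index_of(p, f, t)


@dataclass(frozen=True)
class RewardParams:
    """Parameters of the clinically guided reward.

    Non-terminal steps earn ``+b`` when MBP lies in the closed target range
    (default [70, 80] mm Hg), else ``-b/2``, plus ``+c`` when SpO2 lies in
    the open target range (default (94, 98) %), else ``-c/2``. The terminal
    step earns ``+a`` on survival to discharge and ``-a/2`` on death, with
    no intermittent component.
    """

    a: float = 10.0
    b: float = 1.0
    c: float = 1.0
    spo2_range: tuple[float, float] = (94.0, 98.0)  # open interval
    mbp_range: tuple[float, float] = (70.0, 80.0)  # closed interval

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("reward magnitudes a, b, c must be positive")
        if self.spo2_range[0] >= self.spo2_range[1]:
            raise ValueError("spo2_range is empty")
        if self.mbp_range[0] > self.mbp_range[1]:
            raise ValueError("mbp_range is empty")

    def spo2_in_range(self, spo2) -> np.ndarray:
        lo, hi = self.spo2_range
        spo2 = np.asarray(spo2, dtype=float)
        return (spo2 > lo) & (spo2 < hi)

    def mbp_in_range(self, mbp) -> np.ndarray:
        lo, hi = self.mbp_range
        mbp = np.asarray(mbp, dtype=float)
        return (mbp >= lo) & (mbp <= hi)


def compute_reward(
    mbp,
    spo2,
    terminal,
    mortality,
    params: RewardParams,
) -> np.ndarray:
    """Vectorized reward: intermittent vital-sign terms or the terminal term.

    ``terminal`` and ``mortality`` are broadcastable booleans; ``mortality``
    is only consulted where ``terminal`` is true.
    """
    mbp_term = np.where(params.mbp_in_range(mbp), params.b, -params.b / 2.0)
    spo2_term = np.where(params.spo2_in_range(spo2), params.c, -params.c / 2.0)
    terminal_term = np.where(np.asarray(mortality, dtype=bool), -params.a / 2.0, params.a)
    return np.where(np.asarray(terminal, dtype=bool), terminal_term, mbp_term + spo2_term)


@dataclass
class TransitionDataset:
    """Flat arrays of (s, a, r, s', done) transitions plus provenance columns."""

    states: np.ndarray  # (N, n_features) in [0, 1]
    actions: np.ndarray  # (N,) int in {0..17}
    rewards: np.ndarray  # (N,)
    next_states: np.ndarray  # (N, n_features); rows are NaN where done
    done: np.ndarray  # (N,) bool
    patient_ids: np.ndarray  # (N,)
    step_index: np.ndarray  # (N,) int

    def __post_init__(self) -> None:
        n = len(self.actions)
        for name in ("states", "rewards", "next_states", "done", "patient_ids", "step_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length mismatch")
        if n:
            if self.actions.min() < 0 or self.actions.max() >= N_ACTIONS:
                raise ValueError("action indices out of range")
            missing_next = np.isnan(self.next_states).all(axis=1)
            if not np.array_equal(missing_next, self.done.astype(bool)):
                raise ValueError("done must mark exactly the transitions with no next state")

    def __len__(self) -> int:
        return len(self.actions)

    @property
    def n_features(self) -> int:
        return self.states.shape[1]

    def patients(self) -> np.ndarray:
        return pd.unique(pd.Series(self.patient_ids))

    def subset(self, mask: np.ndarray) -> "TransitionDataset":
        return TransitionDataset(
            self.states[mask],
            self.actions[mask],
            self.rewards[mask],
            self.next_states[mask],
            self.done[mask],
            self.patient_ids[mask],
            self.step_index[mask],
        )

    def trajectories(self) -> list[dict]:
        """Group transitions by patient into ordered trajectory dicts."""
        order = np.lexsort((self.step_index, self.patient_ids))
        out: list[dict] = []
        pid_sorted = self.patient_ids[order]
        bounds = np.flatnonzero(
            np.r_[True, pid_sorted[1:] != pid_sorted[:-1], True]
        )
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            idx = order[lo:hi]
            out.append(
                {
                    "patient_id": pid_sorted[lo],
                    "states": self.states[idx],
                    "actions": self.actions[idx],
                    "rewards": self.rewards[idx],
                }
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        nf = self.n_features
        cols = {f"s{i}": self.states[:, i] for i in range(nf)}
        cols["action"] = self.actions
        cols["reward"] = self.rewards
        for i in range(nf):
            cols[f"ns{i}"] = self.next_states[:, i]
        cols["done"] = self.done.astype(int)
        cols["patient_id"] = self.patient_ids
        cols["step_index"] = self.step_index
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TransitionDataset":
        s_cols = sorted((c for c in df.columns if c.startswith("s") and c[1:].isdigit()),
                        key=lambda c: int(c[1:]))
        ns_cols = sorted((c for c in df.columns if c.startswith("ns") and c[2:].isdigit()),
                         key=lambda c: int(c[2:]))
        return cls(
            states=df[s_cols].to_numpy(float),
            actions=df["action"].to_numpy(int),
            rewards=df["reward"].to_numpy(float),
            next_states=df[ns_cols].to_numpy(float),
            done=df["done"].to_numpy(bool),
            patient_ids=df["patient_id"].to_numpy(),
            step_index=df["step_index"].to_numpy(int),
        )

    @classmethod
    def from_csv(cls, path) -> "TransitionDataset":
        return cls.from_frame(pd.read_csv(path))


def build_transitions(
    steps: pd.DataFrame,
    space: VentilatorActionSpace,
    params: RewardParams,
    outcomes: pd.DataFrame,
    schema: FeatureSchema,
) -> TransitionDataset:
    """Assemble the transition dataset from an imputed (raw-scale) step table.

    States are the schema-normalized feature vectors; the reward for step t
    is computed from step t's own (raw) vitals and attached to the
    transition leaving that step, except the terminal step which carries
    only the survival reward. Consecutive steps of a patient chain so that
    ``next_state[k] == state[k+1]``.
    """
    steps = steps.sort_values(["patient_id", "start_h"], kind="stable").reset_index(drop=True)
    mort = outcomes.set_index("patient_id")["hospital_mortality"]

    state_mat = np.column_stack(
        [schema[name].normalize(steps[name].to_numpy(float)) for name in schema.names]
    )
    actions = space.discretize(
        steps["peep"].to_numpy(float),
        steps["fio2"].to_numpy(float),
        steps["tidal_volume"].to_numpy(float),
    )

    pid = steps["patient_id"].to_numpy()
    last_of_patient = np.r_[pid[1:] != pid[:-1], True]
    mortality = mort.loc[pid].to_numpy(dtype=bool)
    rewards = compute_reward(
        steps["mbp"].to_numpy(float),
        steps["spo2"].to_numpy(float),
        last_of_patient,
        mortality,
        params,
    )

    next_states = np.full_like(state_mat, np.nan)
    next_states[:-1][~last_of_patient[:-1]] = state_mat[1:][~last_of_patient[:-1]]

    step_index = steps.groupby("patient_id", sort=False).cumcount().to_numpy()
    return TransitionDataset(
        states=state_mat,
        actions=np.asarray(actions, dtype=int),
        rewards=np.asarray(rewards, dtype=float),
        next_states=next_states,
        done=last_of_patient,
        patient_ids=pid,
        step_index=step_index,
    )


def split_folds(dataset: TransitionDataset, k: int, seed: int) -> np.ndarray:
    """Assign each transition a fold in {0..k-1}, splitting by patient.

    Patients are shuffled deterministically and dealt round-robin, so fold
    sizes (in patients) differ by at most one and no patient straddles folds.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    patients = dataset.patients()
    if k > len(patients):
        raise ValueError(f"k={k} exceeds the number of patients ({len(patients)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(patients))
    fold_of = {patients[j]: i % k for i, j in enumerate(perm)}
    return np.array([fold_of[p] for p in dataset.patient_ids], dtype=int)
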