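"""Benchmark policies and off-policy evaluation.

Values of counterfactual policies are estimated from physician-generated
trajectories with consistent weighted per-decision importance sampling
(CWPDIS): per-horizon importance-weight normalization keeps the estimator
consistent at much lower variance than plain trajectory-level importance
sampling. Qualitative diagnostics — the empirical return-to-outcome
mapping and the V-curve of mortality against the recommended-minus-
administered setting discrepancy — mirror how treatment policies are
inspected in the critical-care RL literature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .bcq import BCQAgent
from .mdp import N_ACTIONS, RewardParams, TransitionDataset, VentilatorActionSpace
from .policies import ConstantActionPolicy, Policy, UniformRandomPolicy

logger = logging.getLogger(__name__)


@dataclass
class OPEResult:
    """CWPDIS estimate with per-horizon weight diagnostics."""

    value_estimate: float
    per_horizon_weight_sums: np.ndarray
    effective_sample_size: float
    horizon: int


class SupervisorBehaviorPolicy(Policy):
    """Physician-policy estimate read off the trained supervisor network."""

    def __init__(self, agent: BCQAgent):
        self.agent = agent

    def action_probabilities(self, state: np.ndarray) -> np.ndarray:
        return self.agent.supervisor_probs(state)[0]


class EmpiricalClusterPolicy(Policy):
    """Physician-policy estimate: per-state-cluster action frequencies.

    States are clustered with k-means; the policy at a state is the
    Laplace-smoothed action histogram of its cluster (smoothing keeps all
    observed-data likelihoods positive for importance ratios).
    """

    def __init__(self, data: TransitionDataset, n_clusters: int = 50,
                 alpha: float = 0.5, seed: int = 0):
        n_clusters = min(n_clusters, len(data))
        self.kmeans = KMeans(n_clusters=n_clusters, n_init=3, random_state=seed)
        labels = self.kmeans.fit_predict(data.states)
        counts = np.zeros((n_clusters, N_ACTIONS))
        np.add.at(counts, (labels, data.actions), 1.0)
        counts += alpha
        self.probs = counts / counts.sum(axis=1, keepdims=True)

    def action_probabilities(self, state: np.ndarray) -> np.ndarray:
        label = self.kmeans.predict(np.atleast_2d(np.asarray(state, float)))[0]
        return self.probs[label]


def make_benchmark(kind: str, data: TransitionDataset | None = None,
                   agent: BCQAgent | None = None, **kwargs) -> Policy:
    """Construct a benchmark policy: random, one_size_fits_all, or physician."""
    if kind == "random":
        return UniformRandomPolicy()
    if data is None or len(data) == 0:
        raise ValueError(f"benchmark {kind!r} needs a non-empty dataset")
    if kind == "one_size_fits_all":
        counts = np.bincount(data.actions, minlength=N_ACTIONS)
        modal = int(counts.argmax())
        if (counts == counts[modal]).sum() > 1:
            logger.info("modal-action tie; choosing lowest index %d", modal)
        return ConstantActionPolicy(modal)
    if kind == "physician":
        if agent is not None:
            return SupervisorBehaviorPolicy(agent)
        return EmpiricalClusterPolicy(data, **kwargs)
    raise ValueError(f"unknown benchmark kind {kind!r}")


# ---------------------------------------------------------------------------
# CWPDIS
# ---------------------------------------------------------------------------

def _policy_probs_for(policy: Policy, states: np.ndarray, actions: np.ndarray) -> np.ndarray:
    return np.array(
        [policy.action_probabilities(s)[a] for s, a in zip(states, actions)], dtype=float
    )


def _importance_arrays(
    trajectories: list[dict],
    eval_policy: Policy,
    behavior_policy: Policy | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Padded (N, T_max) arrays: cumulative ratios, rewards, alive mask.

    After a trajectory ends its reward is zero and its cumulative ratio
    stays frozen at its final value, so finished trajectories keep
    contributing to later per-horizon denominators.
    """
    n = len(trajectories)
    t_max = max(len(tr["actions"]) for tr in trajectories)
    rho = np.ones((n, t_max))
    rewards = np.zeros((n, t_max))
    alive = np.zeros((n, t_max), dtype=bool)
    for i, tr in enumerate(trajectories):
        states, actions = tr["states"], np.asarray(tr["actions"])
        T = len(actions)
        pe = _policy_probs_for(eval_policy, states, actions)
        if behavior_policy is None:
            pb = np.asarray(tr["behavior_probs"], dtype=float)
        else:
            pb = _policy_probs_for(behavior_policy, states, actions)
        if np.any(pb <= 0):
            t_bad = int(np.flatnonzero(pb <= 0)[0])
            raise ValueError(
                f"behavior probability of the observed action is zero for "
                f"patient {tr.get('patient_id', i)!r} at step {t_bad}"
            )
        ratios = np.cumprod(pe / pb)
        rho[i, :T] = ratios
        rho[i, T:] = ratios[-1]
        rewards[i, :T] = tr["rewards"]
        alive[i, :T] = True
    return rho, rewards, alive


def cwpdis(
    trajectories: list[dict],
    eval_policy: Policy,
    behavior_policy: Policy | None,
    gamma: float,
    weights: np.ndarray | None = None,
) -> OPEResult:
    """Consistent weighted per-decision importance sampling.

    value = sum_t gamma^(t-1) * (sum_n w_n rho_{n,t} r_{n,t})
                              / (sum_n w_n rho_{n,t}),
    with rho_{n,t} the cumulative importance ratio of trajectory n through
    step t. ``behavior_policy=None`` reads exact behavior probabilities
    from each trajectory's ``behavior_probs``. Optional per-trajectory
    ``weights`` support evaluating on exhaustively enumerated trajectory
    sets with their exact probabilities.
    """
    if not trajectories:
        raise ValueError("no trajectories")
    rho, rewards, _ = _importance_arrays(trajectories, eval_policy, behavior_policy)
    w = np.ones(len(trajectories)) if weights is None else np.asarray(weights, dtype=float)

    num = (w[:, None] * rho * rewards).sum(axis=0)
    den = (w[:, None] * rho).sum(axis=0)
    t_max = rho.shape[1]
    disc = gamma ** np.arange(t_max)
    terms = np.zeros(t_max)
    ok = den > 0
    if not ok.all():
        logger.info("zero per-horizon weight sum at %d horizon(s); terms contribute 0",
                    int((~ok).sum()))
    terms[ok] = num[ok] / den[ok]
    value = float((disc * terms).sum())

    wfin = w * rho[:, -1]
    ess = float(wfin.sum() ** 2 / (wfin**2).sum()) if (wfin**2).sum() > 0 else 0.0
    return OPEResult(value, den, ess, t_max)


# ---------------------------------------------------------------------------
# qualitative diagnostics
# ---------------------------------------------------------------------------

def map_return_to_outcome(
    physician_returns: np.ndarray,
    outcomes: np.ndarray,
    n_bins: int,
    ai_returns: np.ndarray,
) -> tuple[float, pd.DataFrame]:
    """Estimate an outcome rate for a policy from its expected returns.

    Physician-policy returns are cut into equal-frequency bins, each bin's
    empirical outcome rate is computed, every evaluated-policy return is
    mapped to its bin (clamped to the end bins), and the mean of the mapped
    per-bin rates is the estimate. Returns (estimate, bin curve).
    """
    physician_returns = np.asarray(physician_returns, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    ai_returns = np.asarray(ai_returns, dtype=float)
    if len(physician_returns) != len(outcomes):
        raise ValueError("returns and outcomes length mismatch")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    qs = np.quantile(physician_returns, np.linspace(0, 1, n_bins + 1))
    inner = np.unique(qs[1:-1])
    if len(inner) < n_bins - 1:
        logger.info("fewer distinct returns than bins; reduced to %d bins", len(inner) + 1)

    phys_bin = np.searchsorted(inner, physician_returns, side="right")
    n_eff = len(inner) + 1
    rates = np.full(n_eff, np.nan)
    counts = np.zeros(n_eff, dtype=int)
    for b in range(n_eff):
        m = phys_bin == b
        counts[b] = m.sum()
        if counts[b]:
            rates[b] = outcomes[m].mean()
    # empty interior bins (possible with heavy ties) inherit the nearest rate
    if np.isnan(rates).any():
        idx = np.flatnonzero(~np.isnan(rates))
        rates = rates[idx[np.abs(np.arange(n_eff)[:, None] - idx[None, :]).argmin(axis=1)]]

    ai_bin = np.clip(np.searchsorted(inner, ai_returns, side="right"), 0, n_eff - 1)
    estimate = float(rates[ai_bin].mean())
    curve = pd.DataFrame({
        "bin": np.arange(n_eff),
        "return_upper_edge": np.r_[inner, np.inf],
        "outcome_rate": rates,
        "count": counts,
    })
    return estimate, curve


def v_curve(
    comparison: pd.DataFrame,
    outcomes: pd.DataFrame,
    space: VentilatorActionSpace,
) -> dict[str, pd.DataFrame]:
    """Mortality against recommended-minus-administered level differences.

    ``comparison`` has one row per step with columns patient_id,
    administered, recommended (action indices). Per dimension, the
    per-patient mean level difference is rounded to the nearest integer bin
    and the empirical mortality per bin is reported with patient counts.
    """
    adm = space.levels_of_index(comparison["administered"].to_numpy(int))
    rec = space.levels_of_index(comparison["recommended"].to_numpy(int))
    mort = outcomes.set_index("patient_id")["hospital_mortality"]

    out = {}
    for dim, a_lv, r_lv in zip(space.dimension_names, adm, rec):
        df = pd.DataFrame({
            "patient_id": comparison["patient_id"].to_numpy(),
            "diff": r_lv.astype(float) - a_lv.astype(float),
        })
        per_patient = df.groupby("patient_id")["diff"].mean()
        bins = np.rint(per_patient).astype(int)
        grp = pd.DataFrame({
            "bin": bins,
            "mortality": mort.loc[per_patient.index].to_numpy(float),
        }).groupby("bin")["mortality"].agg(["mean", "size"]).reset_index()
        grp.columns = ["level_difference", "mortality", "n_patients"]
        out[dim] = grp
    return out


def proportion_in_range(
    steps: pd.DataFrame,
    variable: str,
    vrange: tuple[float, float],
    weights: str = "per-step",
    inclusive: str = "both",
) -> float:
    """Fraction of steps (or of time) with the variable inside the range."""
    if variable not in steps.columns:
        raise KeyError(f"unknown variable {variable!r}")
    x = steps[variable].to_numpy(float)
    lo, hi = vrange
    if inclusive == "both":
        inside = (x >= lo) & (x <= hi)
    elif inclusive == "neither":
        inside = (x > lo) & (x < hi)
    else:
        raise ValueError("inclusive must be 'both' or 'neither'")
    if weights == "per-step":
        return float(inside.mean())
    if weights == "time-weighted":
        dur = (steps["end_h"] - steps["start_h"]).to_numpy(float)
        return float((inside * dur).sum() / dur.sum())
    raise ValueError("weights must be 'per-step' or 'time-weighted'")


# ---------------------------------------------------------------------------
# the full per-policy, per-fold evaluation report
# ---------------------------------------------------------------------------

def trajectories_from_steps(
    dataset: TransitionDataset,
    steps: pd.DataFrame | None = None,
) -> list[dict]:
    """Trajectory dicts, optionally annotated with raw per-step SpO2 and MBP."""
    trajs = dataset.trajectories()
    if steps is not None:
        by_pid = {pid: grp.sort_values("step_index")
                  for pid, grp in steps.groupby("patient_id", sort=False)}
        for tr in trajs:
            grp = by_pid[tr["patient_id"]]
            tr["spo2"] = grp["spo2"].to_numpy(float)
            tr["mbp"] = grp["mbp"].to_numpy(float)
    return trajs


def _weighted_proportion(
    trajectories: list[dict],
    eval_policy: Policy,
    behavior_policy: Policy,
    indicator_key: str,
    in_range,
) -> float:
    """Counterfactual in-range proportion with CWPDIS per-decision weights."""
    rho, _, alive = _importance_arrays(trajectories, eval_policy, behavior_policy)
    t_max = rho.shape[1]
    ind = np.zeros((len(trajectories), t_max))
    for i, tr in enumerate(trajectories):
        vals = np.asarray(tr[indicator_key], dtype=float)
        ind[i, : len(vals)] = in_range(vals).astype(float)
    num = (rho * ind * alive).sum()
    den = (rho * alive).sum()
    return float(num / den) if den > 0 else float("nan")


def evaluate_policies(
    dataset: TransitionDataset,
    outcomes: pd.DataFrame,
    policies: dict[str, Policy],
    behavior_policy: Policy,
    gamma: float,
    params: RewardParams,
    fold_assignment: np.ndarray,
    agent: BCQAgent | None = None,
    steps: pd.DataFrame | None = None,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Per-(policy, fold) report: CWPDIS value, two mortality estimates,
    and counterfactual optimal-range proportions for SpO2 and MBP.

    Mortality route 1 applies the CWPDIS weights to a died-at-terminal-step
    indicator (undiscounted); route 2 maps each policy's expected initial-
    state return through the physician return-to-outcome bin curve (needs
    the trained agent's Q for the expected returns; NaN otherwise).
    """
    mort = outcomes.set_index("patient_id")["hospital_mortality"]
    rows = []
    for fold in np.unique(fold_assignment):
        sub = dataset.subset(fold_assignment == fold)
        trajs = trajectories_from_steps(sub, steps)
        gammas = [gamma ** np.arange(len(tr["rewards"])) for tr in trajs]
        observed_returns = np.array(
            [float((g * tr["rewards"]).sum()) for g, tr in zip(gammas, trajs)]
        )
        traj_mort = np.array([float(mort.loc[tr["patient_id"]]) for tr in trajs])
        mort_trajs = [
            {**tr, "rewards": np.r_[np.zeros(len(tr["rewards"]) - 1), m]}
            for tr, m in zip(trajs, traj_mort)
        ]
        for name, pol in policies.items():
            res = cwpdis(trajs, pol, behavior_policy, gamma)
            mort_cw = cwpdis(mort_trajs, pol, behavior_policy, 1.0).value_estimate

            if pol is behavior_policy:
                # the physician's expected returns are the observed returns;
                # mapping them through their own bin curve recovers the
                # empirical outcome rate
                mort_mapped, _ = map_return_to_outcome(
                    observed_returns, traj_mort, n_bins, observed_returns
                )
            elif agent is not None:
                s0 = np.stack([tr["states"][0] for tr in trajs])
                q0 = agent.q_values(s0)
                pol_returns = np.array(
                    [float(q0[i] @ pol.action_probabilities(s0[i])) for i in range(len(trajs))]
                )
                mort_mapped, _ = map_return_to_outcome(
                    observed_returns, traj_mort, n_bins, pol_returns
                )
            else:
                mort_mapped = float("nan")

            if steps is not None:
                spo2_prop = _weighted_proportion(
                    trajs, pol, behavior_policy, "spo2", params.spo2_in_range
                )
                mbp_prop = _weighted_proportion(
                    trajs, pol, behavior_policy, "mbp", params.mbp_in_range
                )
            else:
                spo2_prop = mbp_prop = float("nan")

            rows.append({
                "policy": name,
                "fold": int(fold),
                "cwpdis_value": res.value_estimate,
                "effective_sample_size": res.effective_sample_size,
                "estimated_mortality_cwpdis": mort_cw,
                "estimated_mortality_mapped": mort_mapped,
                "spo2_in_range": spo2_prop,
                "mbp_in_range": mbp_prop,
            })
    return pd.DataFrame(rows)
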