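# Methods

`ventrl` implements an offline reinforcement-learning pipeline for
mechanical-ventilation settings: a synthetic ICU cohort generator with
known dynamics, a flag-driven discretization of irregular records into
decision steps, a discrete batch-constrained Q-learning (BCQ) agent over
18 joint ventilator actions, and importance-sampling off-policy
evaluation. This note records the models, the parameters that matter, and
the design decisions taken where the design was genuinely open.

## The decision process

A patient trajectory is a sequence of steps, each carrying a 40-feature
state (12 time-varying vitals/labs plus 28 static demographic, admission
and comorbidity features, all normalized to (0, 1)), a discrete action,
and a reward. Actions discretize (PEEP, FiO2, IBW-adjusted tidal volume)
into 2 x 3 x 3 = 18 combinations; PEEP uses two levels with an edge at
7.5 cmH2O because recorded PEEP concentrates heavily at 5 cmH2O, while
FiO2 (edges 40%, 60%) and tidal volume (edges 6, 8 mL/kg IBW) use three.
The edges are configurable (`VentilatorActionSpace`).

Rewards: at non-terminal steps, `+b` if mean arterial pressure lies in
[70, 80] mm Hg else `-b/2`, plus `+c` if SpO2 lies in the open interval
(94, 98)% else `-c/2`; at the terminal step only, `+a` on survival to
discharge and `-a/2` on death. Defaults `a=10, b=c=1` — the terminal
outcome dominates, the vital-sign terms shape intermediate behavior. The
MBP interval is closed and the SpO2 interval open, following the
inequality conventions of the optimal-range definitions.

## Trajectory discretization

The 4-hour grid is anchored at ventilation onset and covers [0, 48] h,
truncated at weaning. Deterioration flags — SpO2 dropping under 90%, PaO2
under 60 mm Hg, pH leaving [7.25, 7.45] — cut additional boundaries. A
flag fires only at a *crossing* (the previous observation of the same
variable did not violate), so one sustained excursion produces one cut
rather than shredding the trajectory. Fragments shorter than 1 h merge
into their successor (the final fragment into its predecessor), keeping
flag times as left edges of decision intervals where possible.

Within a step, values are duration-weighted averages under
last-observation-carried-forward: an observation holds until the next one
or the interval end, and a value carried in from before the interval
covers its head. Ventilator settings use the duration-weighted *median*
instead: when a setting changes inside a step, the median returns the
setting in force for most of the interval, whereas an average of, say,
PEEP 5 and PEEP 10 would yield a phantom level never administered and
corrupt both the behavior-cloning labels and the Q-targets.

Missing step values take the nearest earlier step's value, then the next
observed step's; features missing for an entire trajectory fall back to a
population default (training median). Patients with any ventilator
setting missing at every step are removed. Normalization bounds are
1st/99th training percentiles (configurable), with log-scale bounds for
right-skewed labs; values clip into [0, 1].

## The BCQ agent

Two fully connected networks with two hidden layers of 256 ReLU units:
the supervisor estimates behavior probabilities P(s, ·) with the
probability loss L_P = −log P(s_t, a_t); the policy network estimates
action values Q(s, ·) with a temporal-difference value loss L_Q against a
slowly tracking target copy (Polyak rate α = 0.01). The joint objective
is L = L_Q + β L_P with β = 1; learning rate 3e-4 (Adam), batch 32,
γ = 0.99. At decision time only actions with
P(a|s) / max_a' P(a'|s) ≥ τ (τ = 0.05) are admissible; the policy is the
admissible argmax of Q, ties to the lowest index. The mask inequality is
≥, so the admissible set is never empty (the supervisor argmax always
qualifies, including at τ = 1, where the policy reduces to behavior
cloning).

Numerical choices that implementation experience forced:

* **Value loss.** The default L_Q is squared error. A Huber loss with
  δ = 1 (available via `value_loss="huber"`) interacts badly with the
  stochastic termination structure: with terminal rewards of magnitude
  ~10, nearly all TD errors exceed δ, the clipped gradient makes the
  regression median-seeking, and the fixed point ignores the minority
  terminal branch — Q then drifts toward r/(1−γ) regardless of the true
  value. The squared loss restores the expected-value fixed point.
* **Target clipping.** Bootstrapped targets are clipped to the provable
  return range of the finite episodes, computed from the dataset (longest
  trajectory, extreme intermittent rewards held for the horizon, one
  terminal reward). On sparse 40-dimensional states at γ = 0.99,
  unclipped bootstrapping exhibits the classic soft divergence of
  function-approximation Q-learning; the clip is inactive for achievable
  values.
* **Supervisor schedule.** The supervisor trains first (behavior
  cloning), with early stopping on a held-out patient split: past its
  validation optimum it memorizes individual logged pairs, which drags
  exploration noise into the constraint masks. `freeze_supervisor`
  controls whether it continues updating during policy optimization.
* **Training length.** Default 20,000 minibatch steps; losses plateau
  well before that at the shipped cohort scales.

## The synthetic cohort generator

A latent severity x in [0, 4] drives everything. Vitals and labs are
severity-conditional Gaussians (log-normal for skewed labs) at irregular
Poisson observation times with missing-completely-at-random dropout;
28 static features are drawn once per patient. The emission maps are
anchored so a healthy patient (x = 0) sits *inside* the optimal SpO2 and
MBP target ranges and deterioration pushes the vitals out of range and
toward the flag thresholds — without this anchoring the reward would
favor moderate sickness and suboptimal care would be nearly free.
Severity updates hourly:

    x += drift_penalty * d(action, ideal) − recovery_rate + noise

where d is the summed level distance between administered and
severity-dependent ideal settings (sicker patients need more PEEP/FiO2
and lower tidal volume; a high comorbidity burden shifts the FiO2
requirement up). Hospital mortality is Bernoulli with logit −3 + 0.9 x at
episode end; weaning ends the episode when severity stays below 2 for 4
consecutive hours (never before 24 h).

The behavior (physician) policy reassesses on the 4-h grid and whenever
the patient's *perceived* severity level changes — clinicians act on a
noisy severity estimate (sd 0.3, matching what the charted vitals'
signal-to-noise supports), not on the latent state, so no policy in the
comparison holds an oracle information advantage. Its suboptimality has
three components: with probability ε (default 0.3) a decision is
uniformly random; 35% of patients are treated by a physician with a
persistent one-level practice bias in one setting dimension (documented
practice variation, the realistic form of guideline non-adherence); and
the perception noise itself. ε is calibrated so the simulated hospital
mortality (15–18%) matches the observed mortality of the large
multi-center cohort this generator emulates. "Closer-to-ideal
ventilation ⇒ lower mortality" is true by construction, which is what
makes policy comparisons meaningful.

Defaults: 1000 patients (about 5% of a large multi-center cohort — the
smallest scale at which the supervisor's masks are informative),
`drift_penalty = 0.08` per hour per unit level distance, `recovery_rate
= 0.12`/h, hourly noise 0.15.

The tabular mode is the oracle testbed: severity is one of 5 integer
states, drift probabilities per 4-h step increase with d, and episodes
end by hazard — 0.30/step below the wean threshold, 1/6 otherwise. The
1/6 discharge hazard is the stationary surrogate for the deterministic
48-h cutoff: it ends ~90% of episodes within 12 steps while keeping the
process time-homogeneous, so value iteration (sup-norm tolerance 1e-10,
ties to the lowest action index) is an exact oracle. Monte-Carlo rollouts
from the uniform start distribution estimate any policy's true value; in
continuous mode, rollouts rebuild the normalized state from
severity-conditional vital means each decision and re-query the policy at
the same cadence as the behavior policy (4-h grid plus severity-level
changes), so compared policies differ only in their choices, not their
reaction time.

What the generator does *not* emulate: informative missingness,
measurement artifacts, inter-variable physiological coupling beyond the
shared severity, co-interventions other than a severity-linked
vasopressor dose, and competing outcomes. Passing tests therefore show
that the machinery is correct under a severity-mediated world, not that
the learned policies would transfer to real ICU data.

## Off-policy evaluation

CWPDIS (consistent weighted per-decision importance sampling):

    V = Σ_t γ^(t−1) · (Σ_n w_n ρ_{n,t} r_{n,t}) / (Σ_n w_n ρ_{n,t})

with ρ_{n,t} the cumulative product of π_e/π_b through step t. Finished
trajectories contribute zero reward and keep their final cumulative ratio
in later denominators, which makes the self-evaluation identity exact for
variable-length batches; a zero denominator contributes zero and is
logged. Optional per-trajectory weights allow evaluating exhaustively
enumerated trajectory sets with exact probabilities, which the tests use
to verify the estimator against closed-form values. The behavior policy
for the ratios is the trained supervisor by default (the framework's own
behavior-cloning component), with a k-means per-cluster empirical
frequency estimator as an alternative.

Benchmarks: uniform random over the 18 actions; one-size-fits-all (the
cohort-modal action, ties to the lowest index); the physician estimate
above. The evaluation report adds, per policy and fold: an estimated
mortality from CWPDIS applied to a died-at-terminal-step indicator
(undiscounted); a mapped mortality from sorting physician returns into 20
equal-frequency bins, taking each bin's empirical mortality, and mapping
the evaluated policy's expected initial-state returns (Σ_a π(a|s0)
Q(s0, a)) through the bin curve; and counterfactual optimal-range
proportions for SpO2 and MBP, computed with the same per-decision weights
applied to in-range indicators and normalized by the weighted time alive.

The V-curve diagnostic reports, per setting dimension, empirical
mortality against the per-patient mean difference between recommended and
administered levels, rounded to integer bins; an effective policy shows
its minimum at zero discrepancy.

## Known limitations

* **The learned policy does not beat the simulated physicians on the
  true simulator oracle at the shipped scale.** The package measures
  this directly and reports it rather than hiding it: across seeds, the
  learned policy's Monte-Carlo value on the continuous simulator falls
  below the behavior policy's. The decomposition is instructive. A pure
  behavior-cloning policy (supervisor argmax) already trails the
  behavior policy, because a deterministic clone's estimation errors
  persist across a patient's whole stay while the stochastic physician's
  errors are transient and corrected at the next reassessment. The Q
  ranking inside admissible sets loses further value through
  extrapolation bias: measured mean Q is anti-correlated with action
  frequency, so rarely-logged actions look spuriously attractive. The
  realizable ceiling for *any* chart-based policy exceeds the behavior
  policy by only ~1.5 value units here, so winning requires near-Bayes
  estimation of both the behavior distribution and the action values —
  attainable at the ~200k-transition scale of real multi-center cohorts,
  not at the ~9k-transition desk scale this package ships with. In
  tabular mode, where data density per state is high, the identical
  agent code recovers the dynamic-programming optimum exactly; the gap
  is a data-scale property, not an implementation one.
* At the shipped cohort scale the Q network's ranking *within* admissible
  sets is noisy; the agent's quality rests substantially on the
  batch-constraint mechanism. This mirrors the method's design intent but
  means conclusions about fine-grained action preferences need larger
  cohorts.
* The importance-sampling estimates for policies far from the behavior
  policy (random, one-size-fits-all) carry low effective sample sizes;
  their point estimates are reported with that caveat.
* The supervisor-based behavior probabilities make the physician policy's
  CWPDIS self-evaluation exact by construction only when the supervisor
  is also the ratio estimator; the empirical-cluster alternative breaks
  that identity by design.
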