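# Methods

`habinf` simulates discrete-state active-inference agents that learn
*habits*: a Dirichlet prior over their policy repertoire that accumulates
soft counts of self-observed behavior within each day and is restructured
between days by Bayesian model reduction and averaging. The task is a
two-step maze whose statistics (volatile vs. conservative reward
placement) determine whether the agent specializes or stays a generalist.

## Generative model and task

The maze has seven locations in a forward-only binary tree: one start,
two intermediate, four final. Hidden states factorize into *location*
(7 states, controlled by stay/left/right actions) and *reward context*
(4 states, one per final location, static within a trial). Outcomes come
in two modalities: *Where*, an identity mapping on location (the agent
always knows where it is), and *Feedback* — a left/right directional cue
at the start and intermediate locations, and a deterministic reward or
punishment at the final locations. A cue points toward the reward with
probability `cue_veracity` (0.99 during training, 0.65 during testing);
at an intermediate location on the branch that does not contain the
reward the cue is uninformative (0.5/0.5 — the maximally ambiguous
neutral choice, configurable). A single veracity parameterizes both the
environment's emissions and the agent's likelihood model, so beliefs are
well calibrated by default; the two can be decoupled for sensitivity
runs.

A trial has horizon T = 3 (start, intermediate, final) and the agent
holds k = 7 policies, each a two-action sequence: four reach a final
location, two stop at an intermediate location, one never moves. Initial
beliefs put all mass on the start location and a uniform distribution
over contexts. Preferences are log-utilities over Feedback outcomes,
constant across time steps: reward +3 nats, punishment -3 nats, cues 0
(see *Calibration* below).

## Policy inference

Each policy is scored by

* `F`, the variational free energy of the observations so far under that
  policy's action sequence, and
* `G`, the expected free energy of future time steps: per step and
  modality, the KL divergence of predicted outcomes from the
  softmax-normalized preferences (*risk*) plus the expected conditional
  entropy of outcomes given states (*ambiguity*; equivalently, risk +
  ambiguity = expected surprise of preferred outcomes minus the
  state-information gain, so cue-seeking is rewarded automatically).

The policy posterior is `softmax(E_hat - F - gamma * G)` with `E_hat`
the expected log habit prior (below) and `gamma` a fixed precision. The
action is the mode of the posterior pooled over each step's distinct
actions (ties broken uniformly at random from the caller's generator);
the posterior is re-formed after every observation, which is what keeps
behavior goal-directed mid-trial even when a policy that stalls looks
attractive from the start.

### Exact smoothing instead of factorized message passing

State inference runs per policy on the *joint* product of the two
factors (28 states) by standard discrete forward–backward smoothing.
The joint is small by construction, so exactness is cheap: `F` is the
tight bound (the negative log evidence of the observations under the
policy), and the reported per-factor beliefs are exact marginals. We
originally evaluated factorized (mean-field) fixed-point updates —
plain, half-weighted, and structured per-factor variants — and measured
worst-case total-variation errors of 0.27/0.23/0.13 against brute-force
enumeration on small random models; a product-form posterior simply
cannot represent the strongly coupled posteriors these tasks produce.
The test suite checks the smoother against an independent
enumeration-over-sequences oracle.

An observation that is impossible under a policy (zero predicted mass)
contributes `-ln(1e-16) ≈ 36.8` nats to `F` and is then dropped from
conditioning, so free energies stay finite and such policies are
effectively excluded by the posterior. The same `1e-16` floor guards
every logarithm of a possibly-zero probability; probability vectors are
validated to sum to one within 1e-10 and softmax outputs within 1e-12.

## Habit learning

The habit prior is `Dir(e)` over the 7 policies, initialized at
`e = (1, …, 1)`. After each completed trial the *final-time* policy
posterior — the agent's self-observation of what it just did, formed
after the whole trajectory is seen — is added to `e`, so the total
concentration grows by exactly one per trial. The habit term in policy
inference is the expected log prior, `E_hat_i = psi(e_i) - psi(sum e)`.
Counts are carried across trials within a day; an optional
`per_timestep` mode (one count per time step, for sensitivity analysis
only) is exposed but not used by any protocol.

## Sleep: Bayesian model reduction and averaging

Between days the agent "sleeps". Given the day-start prior `a` and
day-end posterior `b`, the evidence of any alternative prior `a'` is
available in closed form,

    dF = ln B(a) - ln B(a') + ln B(b') - ln B(b),   b' = b + a' - a,

with `B` the multivariate beta function, evaluated via log-gamma
throughout. The candidate space holds the full model plus, for each
policy and each suppression factor f ∈ {2, 4}, a candidate that adds a
boost of 8 to that policy and divides every other concentration by f
(floored at the naive value 1 so priors stay proper and never-used
policies cannot decay without bound) — 15 candidates for 7 policies.
Candidates are combined by Bayesian model averaging with weights
`softmax(dF)` (a uniform prior over candidate models), and the weighted
average of the reduced *posteriors* `b'` becomes the next day's prior.
No renormalization of total mass is applied. The closed form is verified
in the tests against Monte-Carlo integration of the defining expectation
(`dF = ln E_{Dir(b)}[Dir(theta; a') / Dir(theta; a)]`).

Two properties of this day map are worth knowing. Under symmetric daily
counts it is a contraction with a finite fixed point (about 24 per
useful policy for two policies sharing 8 counts/day; unused policies
settle just above the floor), so habit strengths plateau rather than
grow without bound. But the softmax evidence weighting is sensitive to
the day's count split, so with 8 trials/day the trajectories fluctuate
around the plateau by roughly ±20% from day to day, and in the volatile
regime a run of lucky days can temporarily concentrate the prior on a
subset of the four useful policies.

## Training and testing protocols

Training: 32 days × 8 trials, cue veracity 0.99, context resampled
independently every trial from the regime's frequencies (non-volatile
(½, ½, 0, 0); volatile (¼, ¼, ¼, ¼); novel (0, 0, ½, ½)), beliefs reset
every trial, sleep between days. Testing: the trained `e` is frozen (no
counts, no sleep), 512 independent trials under 0.65-veracity cues;
the reward-acquisition rate is the fraction of trials ending at the true
reward location. The in-training performance curve optionally tests a
frozen copy of each day's post-sleep prior (32 ambiguous trials) without
touching the training counts. A master seed is split into independent
streams for training trials, in-training tests, and each test cell;
identical configuration and seed reproduce outputs bit for bit.

## Calibration

Two scalars the protocols do not pin down are set by decision analysis
and then fixed:

* **Utilities (+3 / -3 nats).** With a strongly asymmetric pair such as
  (+3, -6), the risk term of a 50–65% punishment prospect exceeds the
  risk of idling at an intermediate location under ambiguous cues, and
  the agent freezes mid-maze (test rates collapse toward zero).
  Symmetric ±3 keeps the agent in the cue-following regime at 0.65
  veracity while leaving training behavior unchanged.
* **Precision (gamma = 0.5).** A trained specialist's habit advantage is
  `E_hat` gaps of ≈ 3.7 nats, and the cue-driven `G` gap at the branch
  decision under ambiguity is also ≈ 3.7 nats, so at gamma = 1 habits
  and cues tie and no specialist phenotype emerges. Habit dominance at
  the branch step requires `gamma * 3.7` comfortably below 3.7, while
  cue-following within a branch requires `gamma * 6.0` above the ≈ 1.5
  nat within-branch habit asymmetry; gamma = 0.5 centers both margins.

## What the simulations can and cannot show

The environment module *is* the data generator: everything the tests
establish concerns this synthetic task, not animal behavior. Two
structural ceilings of the task are useful context for the reported
numbers. With veracity v at both cue sites, the branch decision rests on
a single binary cue and the within-branch decision on another, so no
decision rule can exceed v² ≈ 42% reward acquisition at v = 0.65 without
habits, or v ≈ 65% when a habit fixes the correct branch. Reported
rates sit at these ceilings: untrained and volatile-trained agents
around 40–47%, the specialist around 55–68% in its home environment,
≈ half that in the volatile environment, and ≈ 0 in the mirrored
environment. Habit plateaus are likewise bounded by the sleep fixed
point described above (≈ 20–26 for the specialist's two policies,
≈ 6–13 for the generalist's four, unused policies near the floor), and
the day-to-day count noise means the 5%-per-day stabilization criterion
is often not met within 32 days.

## Limitations

Cue–outcome associations (the likelihood), transitions and initial
beliefs are fixed, not learned; the policy space is enumerated, with no
expansion or hierarchical structure; precision gamma is constant rather
than inferred; and model comparison uses full averaging only (no
selection or Occam's-window truncation). Within-trial context switches
are not modeled — volatility is strictly between trials.
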