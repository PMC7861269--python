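"""Training, sleep scheduling, testing protocols and study-level summaries.

An agent is *trained* by running days of trials in one environment regime
under near-veridical cues, accumulating habit pseudo-counts within each
day and applying sleep-phase Bayesian model reduction between days.  It is
*tested* with a frozen habit prior under ambiguous cues, with beliefs and
environment state reset every trial, and scored by the reward-acquisition
rate: the fraction of trials whose final location holds the reward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import maze
from .bmr import sleep
from .habits import (
    DirichletPolicyPrior,
    expected_log_policy_prior,
    update_policy_counts,
)
from .inference import Engine, TrialRecord, run_trial
from .maze import ENVIRONMENTS, EnvironmentSpec, build_maze_model

#: Calibrated model defaults shared by every protocol in this module.
DEFAULT_MODEL_PARAMS: dict[str, float] = {
    "reward_utility": 3.0,
    "punishment_utility": -3.0,
    "gamma": 0.5,
}

TRAIN_VERACITY = 0.99
TEST_VERACITY = 0.65


@dataclass
class TrainingResult:
    """Day-by-day habit-concentration trajectory and the final prior."""

    spec: EnvironmentSpec
    e_trajectory: np.ndarray  # (days + 1, k); row 0 is the naive prior
    final_prior: DirichletPolicyPrior
    seed: int
    daily_test_rates: np.ndarray | None = None

    def trajectory_frame(self) -> pd.DataFrame:
        days, k = self.e_trajectory.shape
        rows = [
            {"day": d, "policy": p + 1,
             "concentration": float(self.e_trajectory[d, p])}
            for d in range(days) for p in range(k)
        ]
        return pd.DataFrame(rows)


@dataclass
class TestResult:
    """Reward-acquisition summary over independent frozen-prior trials."""

    n_trials: int
    n_rewarded: int
    seed: int
    block_rates: np.ndarray | None = None

    @property
    def rate(self) -> float:
        return self.n_rewarded / self.n_trials


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _make_engine(cue_veracity: float,
                 model_params: dict[str, float] | None = None) -> Engine:
    params = dict(DEFAULT_MODEL_PARAMS)
    if model_params:
        params.update(model_params)
    return Engine(build_maze_model(cue_veracity, **params))


def run_training_trial(engine: Engine, prior: DirichletPolicyPrior,
                       spec: EnvironmentSpec, rng: np.random.Generator,
                       count_update: str = "per_trial"
                       ) -> tuple[TrialRecord, DirichletPolicyPrior]:
    """One trial plus the habit-count update from its policy posterior.

    ``count_update`` is ``"per_trial"`` (one soft count from the final-time
    posterior, the default self-observation rule) or ``"per_timestep"``
    (one count per time step, exposed for sensitivity analysis only).
    """
    state = maze.initial_state(spec, rng)
    record = run_trial(engine, expected_log_policy_prior(prior), state,
                       spec, rng)
    if count_update == "per_trial":
        prior = update_policy_counts(prior, record.final_posterior)
    elif count_update == "per_timestep":
        for post in record.posteriors:
            prior = update_policy_counts(prior, post.posterior)
    else:
        raise ValueError(f"unknown count_update {count_update!r}")
    return record, prior


def train_agent(spec: EnvironmentSpec, days: int = 32,
                trials_per_day: int = 8,
                cue_veracity: float = TRAIN_VERACITY,
                seed: int = 0,
                model_params: dict[str, float] | None = None,
                boost: float = 8.0,
                suppression_factors: tuple[float, ...] = (2.0, 4.0),
                daily_test_trials: int = 0,
                daily_test_veracity: float = TEST_VERACITY,
                count_update: str = "per_trial",
                model_veracity: float | None = None) -> TrainingResult:
    """Train a habit prior from scratch in one environment regime.

    Each day runs ``trials_per_day`` trials (context resampled and beliefs
    reset per trial, pseudo-counts accumulated per trial) followed by a
    sleep phase of Bayesian model reduction and averaging.  Starting prior
    is the naive unit vector.  If ``daily_test_trials`` is positive, a
    frozen copy of each day's post-sleep prior is additionally tested under
    ambiguous cues in the same regime (the in-training performance curve);
    these test trials never touch the training counts.

    ``model_veracity`` decouples the agent's believed cue reliability from
    the environment's emission veracity (sensitivity runs); by default the
    two are shared.
    """
    train_spec = spec.with_veracity(cue_veracity)
    engine = _make_engine(cue_veracity if model_veracity is None
                          else model_veracity, model_params)
    trial_rng, test_rng = _streams(seed, 2)

    prior = DirichletPolicyPrior.naive(engine.model.n_policies)
    traj = [prior.e.copy()]
    daily_rates: list[float] = []
    for _day in range(days):
        day_start = prior
        for _trial in range(trials_per_day):
            _, prior = run_training_trial(engine, prior, train_spec,
                                          trial_rng, count_update)
        prior = sleep(day_start, prior, boost=boost,
                      suppression_factors=suppression_factors)
        traj.append(prior.e.copy())
        if daily_test_trials > 0:
            res = test_agent(prior, spec, n_trials=daily_test_trials,
                             cue_veracity=daily_test_veracity,
                             seed=int(test_rng.integers(2**31)),
                             model_params=model_params)
            daily_rates.append(res.rate)

    return TrainingResult(
        spec=spec, e_trajectory=np.asarray(traj), final_prior=prior,
        seed=seed,
        daily_test_rates=np.asarray(daily_rates) if daily_rates else None,
    )


def test_agent(prior: DirichletPolicyPrior, spec: EnvironmentSpec,
               n_trials: int = 512, cue_veracity: float = TEST_VERACITY,
               seed: int = 0,
               model_params: dict[str, float] | None = None,
               model_veracity: float | None = None) -> TestResult:
    """Evaluate a frozen habit prior: no count updates, no sleep.

    Beliefs and environment state are reset each trial, making the
    ``n_trials`` trials independent replications.
    """
    test_spec = spec.with_veracity(cue_veracity)
    engine = _make_engine(cue_veracity if model_veracity is None
                          else model_veracity, model_params)
    E_hat = expected_log_policy_prior(prior)
    (rng,) = _streams(seed, 1)
    rewarded = 0
    for _ in range(n_trials):
        state = maze.initial_state(test_spec, rng)
        record = run_trial(engine, E_hat, state, test_spec, rng)
        rewarded += int(record.reward_obtained)
    return TestResult(n_trials=n_trials, n_rewarded=rewarded, seed=seed)


def reward_rate_distribution(prior: DirichletPolicyPrior,
                             spec: EnvironmentSpec, blocks: int = 16,
                             block_size: int = 32,
                             cue_veracity: float = TEST_VERACITY,
                             seed: int = 0,
                             model_params: dict[str, float] | None = None
                             ) -> TestResult:
    """Block-wise reward rates for distributional (box-plot) summaries.

    Runs ``blocks`` independent blocks of ``block_size`` trials each; the
    pooled rate equals the mean of the block rates.
    """
    rates = []
    rewarded = 0
    rngs = _streams(seed, blocks)
    test_spec = spec.with_veracity(cue_veracity)
    engine = _make_engine(cue_veracity, model_params)
    E_hat = expected_log_policy_prior(prior)
    for rng in rngs:
        block_hits = 0
        for _ in range(block_size):
            state = maze.initial_state(test_spec, rng)
            record = run_trial(engine, E_hat, state, test_spec, rng)
            block_hits += int(record.reward_obtained)
        rates.append(block_hits / block_size)
        rewarded += block_hits
    return TestResult(n_trials=blocks * block_size, n_rewarded=rewarded,
                      seed=seed, block_rates=np.asarray(rates))


def stabilization_day(e_trajectory: np.ndarray, rel_tol: float = 0.05,
                      top: int = 2) -> int | None:
    """Earliest day after which the habit trajectory has settled.

    A trajectory is settled from day ``d`` on when, for every later day,
    each policy's concentration changes by less than ``rel_tol`` of its
    previous value and the identity of the ``top`` strongest policies is
    constant.  Returns the day number (1-based; row 0 is the pre-training
    prior) or None if the criterion is never met.  The final day never
    qualifies on its own: at least one later day must corroborate it.
    """
    days = e_trajectory.shape[0] - 1
    top_sets = [frozenset(np.argsort(e_trajectory[d])[-top:])
                for d in range(e_trajectory.shape[0])]
    for d in range(1, days):
        ok = True
        for later in range(d + 1, days + 1):
            change = np.abs(e_trajectory[later] - e_trajectory[later - 1])
            if np.any(change >= rel_tol * e_trajectory[later - 1]):
                ok = False
                break
            if top_sets[later] != top_sets[d]:
                ok = False
                break
        if ok:
            return d
    return None


AGENTS = ("specialist", "generalist", "naive")
TEST_ENVIRONMENTS = {
    "specialized": "nonvolatile",
    "general": "volatile",
    "novel": "novel",
}


@dataclass
class StudyResult:
    """Outputs of the full specialist/generalist/naive study."""

    config: dict[str, Any]
    rate_matrix: pd.DataFrame  # agents x test environments, reward rates
    trainings: dict[str, TrainingResult]
    tests: dict[tuple[str, str], TestResult]
    seed: int

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rate_matrix.to_csv(out / "rate_matrix.csv")
        rows = [
            {"agent": agent, "environment": env, "n": t.n_trials,
             "rate": t.rate}
            for (agent, env), t in self.tests.items()
        ]
        pd.DataFrame(rows).to_csv(out / "rates.csv", index=False)
        for name, tr in self.trainings.items():
            tr.trajectory_frame().to_csv(out / f"e_trajectory_{name}.csv",
                                         index=False)
        with open(out / "study.json", "w") as fh:
            json.dump({"config": self.config, "seed": self.seed,
                       "rate_matrix": {a: dict(r) for a, r in
                                       self.rate_matrix.iterrows()}},
                      fh, indent=2, default=float)


def run_full_study(seed: int = 0, days: int = 32, trials_per_day: int = 8,
                   train_veracity: float = TRAIN_VERACITY,
                   test_veracity: float = TEST_VERACITY,
                   n_test_trials: int = 512,
                   daily_test_trials: int = 0,
                   model_params: dict[str, float] | None = None,
                   boost: float = 8.0,
                   suppression_factors: tuple[float, ...] = (2.0, 4.0)
                   ) -> StudyResult:
    """Train specialist and generalist agents and cross-test all agents.

    Evaluates {specialist, generalist, naive} x {specialized, general,
    novel} reward-acquisition rates at ``n_test_trials`` trials per cell
    under ambiguous cues, and returns the 3x3 rate matrix together with
    the habit trajectories.
    """
    ss = np.random.SeedSequence(seed)
    train_seeds, test_seeds = ss.spawn(2)
    tseeds = [int(s.generate_state(1)[0] % 2**31) for s in train_seeds.spawn(2)]
    cell_seeds = [int(s.generate_state(1)[0] % 2**31)
                  for s in test_seeds.spawn(len(AGENTS) * len(TEST_ENVIRONMENTS))]

    trainings = {
        "specialist": train_agent(
            maze.nonvolatile_spec(), days=days, trials_per_day=trials_per_day,
            cue_veracity=train_veracity, seed=tseeds[0],
            model_params=model_params, boost=boost,
            suppression_factors=suppression_factors,
            daily_test_trials=daily_test_trials,
            daily_test_veracity=test_veracity),
        "generalist": train_agent(
            maze.volatile_spec(), days=days, trials_per_day=trials_per_day,
            cue_veracity=train_veracity, seed=tseeds[1],
            model_params=model_params, boost=boost,
            suppression_factors=suppression_factors,
            daily_test_trials=daily_test_trials,
            daily_test_veracity=test_veracity),
    }
    k = trainings["specialist"].final_prior.k
    priors = {
        "specialist": trainings["specialist"].final_prior,
        "generalist": trainings["generalist"].final_prior,
        "naive": DirichletPolicyPrior.naive(k),
    }

    tests: dict[tuple[str, str], TestResult] = {}
    matrix = pd.DataFrame(index=list(AGENTS),
                          columns=list(TEST_ENVIRONMENTS), dtype=float)
    i = 0
    for agent in AGENTS:
        for env_name, regime in TEST_ENVIRONMENTS.items():
            spec = ENVIRONMENTS[regime]()
            res = test_agent(priors[agent], spec, n_trials=n_test_trials,
                             cue_veracity=test_veracity, seed=cell_seeds[i],
                             model_params=model_params)
            tests[(agent, env_name)] = res
            matrix.loc[agent, env_name] = res.rate
            i += 1

    config = {
        "days": days, "trials_per_day": trials_per_day,
        "train_veracity": train_veracity, "test_veracity": test_veracity,
        "n_test_trials": n_test_trials,
        "daily_test_trials": daily_test_trials,
        "model_params": dict(DEFAULT_MODEL_PARAMS) | dict(model_params or {}),
        "boost": boost, "suppression_factors": list(suppression_factors),
    }
    return StudyResult(config=config, rate_matrix=matrix,
                       trainings=trainings, tests=tests, seed=seed)
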