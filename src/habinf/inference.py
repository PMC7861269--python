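"""Per-policy state inference, free energies, policy posterior and trials.

Policy inference follows the planning-as-inference scheme: for each
enumerated policy the agent infers hidden-state trajectories under that
policy's transitions, scores the policy by the variational free energy
``F`` of past observations and the expected free energy ``G`` of future
outcomes, and forms the policy posterior

    pi = softmax(E_hat - F - gamma * G)

where ``E_hat`` is the expected log of the Dirichlet habit prior.  The
next action is the mode of the posterior marginal over that step's
actions.

State inference is carried out *exactly* on the joint product of the
hidden-state factors (28 states for the maze) by discrete forward-backward
smoothing per policy; the joint is small by construction, so the
variational bound is tight and ``F`` equals the negative log evidence of
the observations under the policy.  Per-factor marginals of the smoothed
posterior are what the rest of the package consumes.

``G`` decomposes per future time step and modality into *risk*, the KL
divergence of predicted outcomes from (softmax-normalized) preferences,
plus *ambiguity*, the expected conditional entropy of outcomes given
states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product as _iterproduct
from typing import Sequence

import numpy as np

from .model import GenerativeModel, LOG_EPS, log_softmax, softmax, stable_log


@dataclass
class Beliefs:
    """Smoothed per-policy beliefs: joint and per-factor marginals."""

    joint: list[np.ndarray]              # per tau, shape = factor cards
    marginals: list[list[np.ndarray]]    # per tau, per factor
    log_evidence: float                  # ln P(observed outcomes | policy)

    def __getitem__(self, tau: int) -> list[np.ndarray]:
        return self.marginals[tau]


@dataclass
class PolicyPosterior:
    """Per-policy path free energy, expected free energy and posterior."""

    F: np.ndarray
    G: np.ndarray
    posterior: np.ndarray
    gamma: float


@dataclass
class TrialRecord:
    """Everything observed, believed and done over one trial."""

    observations: list[tuple[int, ...]]
    actions: list[np.ndarray]
    beliefs: list[list[Beliefs]]  # per decision step, per policy (optional)
    posteriors: list[PolicyPosterior]
    reward_obtained: bool
    final_location: int
    context: int

    @property
    def final_posterior(self) -> np.ndarray:
        """Policy posterior after the last observation (the self-observation
        used for habit-count updates)."""
        return self.posteriors[-1].posterior

    def to_json(self) -> str:
        return json.dumps({
            "observations": [list(o) for o in self.observations],
            "actions": [a.tolist() for a in self.actions],
            "policy_posteriors": [p.posterior.tolist() for p in self.posteriors],
            "F": [p.F.tolist() for p in self.posteriors],
            "G": [p.G.tolist() for p in self.posteriors],
            "reward_obtained": self.reward_obtained,
            "final_location": self.final_location,
            "context": self.context,
        })


class Engine:
    """Inference engine bound to one generative model.

    Precomputes joint transition matrices per distinct action vector,
    flattened likelihoods, outcome entropies and normalized log-preferences
    so trial loops stay cheap.
    """

    def __init__(self, model: GenerativeModel):
        self.model = model
        self.n_factors = len(model.factors)
        self.n_modalities = len(model.modalities)
        self.T = model.horizon
        self.cards = model.factor_cards
        self.n_joint = int(np.prod(self.cards))
        # flattened likelihood per modality: (n_outcomes, n_joint)
        self._A_flat = [a.reshape(a.shape[0], -1) for a in model.A]
        # H[m]: conditional outcome entropy per joint state
        self._H = []
        for a in self._A_flat:
            with np.errstate(divide="ignore", invalid="ignore"):
                plogp = np.where(a > 0, a * np.log(np.maximum(a, 1e-300)), 0.0)
            self._H.append(-plogp.sum(axis=0))
        self._lnC = [log_softmax(c, axis=0) for c in model.C]
        self._pol = model.policies
        self._D_joint = self._outer([d for d in model.D]).ravel()
        # joint transition per distinct action vector appearing in policies
        self._trans: dict[tuple[int, ...], np.ndarray] = {}
        for step_actions in model.policies.reshape(-1, self.n_factors):
            key = tuple(int(u) for u in step_actions)
            if key not in self._trans:
                M = np.array([[1.0]])
                for f in range(self.n_factors):
                    M = np.kron(M, model.B[f][key[f]])
                self._trans[key] = M

    def _outer(self, vecs: list[np.ndarray]) -> np.ndarray:
        out = vecs[0]
        for v in vecs[1:]:
            out = np.multiply.outer(out, v)
        return out

    def _evidence(self, obs: tuple[int, ...]) -> np.ndarray:
        ev = self._A_flat[0][obs[0]].copy()
        for m in range(1, self.n_modalities):
            ev *= self._A_flat[m][obs[m]]
        return ev

    def _marginals(self, joint_flat: np.ndarray) -> list[np.ndarray]:
        joint = joint_flat.reshape(self.cards)
        out = []
        for f in range(self.n_factors):
            axes = tuple(g for g in range(self.n_factors) if g != f)
            out.append(joint.sum(axis=axes) if axes else joint.copy())
        return out

    def infer_states(self, policy: int,
                     observations: Sequence[tuple[int, ...]]) -> Beliefs:
        """Exact smoothed beliefs Q(s_tau | pi) for all tau in 1..T.

        ``observations`` holds outcome tuples (one index per modality) for
        times 1..t; those times condition on the likelihood, later times
        are predictive under the policy's transition sequence.  If an
        observation is impossible under the policy (zero predicted mass),
        the log evidence is floored at ``ln(LOG_EPS)`` for that step and
        filtering continues from the unconditioned prediction, so free
        energies stay finite.
        """
        t_obs = len(observations)
        if t_obs > self.T:
            raise ValueError("more observations than time steps")
        actions = [tuple(int(u) for u in self._pol[policy, tau])
                   for tau in range(self.T - 1)]

        # forward filtering with per-step normalization
        alpha = []
        log_ev = 0.0
        pred = self._D_joint
        for tau in range(self.T):
            if tau > 0:
                pred = self._trans[actions[tau - 1]] @ alpha[tau - 1]
            if tau < t_obs:
                post = pred * self._evidence(observations[tau])
                c = float(post.sum())
                if c <= 0.0:
                    log_ev += np.log(LOG_EPS)
                    post = pred.copy()
                    c = float(post.sum())
                else:
                    log_ev += np.log(c)
            else:
                post = pred.copy()
                c = float(post.sum())
            alpha.append(post / c)

        # backward smoothing
        beta = [np.ones(self.n_joint) for _ in range(self.T)]
        for tau in range(self.T - 2, -1, -1):
            if tau + 1 < t_obs:
                ev = self._evidence(observations[tau + 1])
                if float((ev * (self._trans[actions[tau]] @ alpha[tau])).sum()) <= 0.0:
                    ev = np.ones(self.n_joint)  # impossible step: uninformative
                msg = ev * beta[tau + 1]
            else:
                msg = beta[tau + 1]
            b = self._trans[actions[tau]].T @ msg
            s = float(b.sum())
            beta[tau] = b / s if s > 0 else np.ones(self.n_joint)

        joint = []
        for tau in range(self.T):
            g = alpha[tau] * beta[tau]
            joint.append(g / g.sum())
        return Beliefs(joint=joint,
                       marginals=[self._marginals(j) for j in joint],
                       log_evidence=log_ev)

    # -- free energies -----------------------------------------------------

    def path_free_energy(self, policy: int,
                         observations: Sequence[tuple[int, ...]],
                         beliefs: Beliefs | None = None) -> float:
        """Variational free energy of past observations under one policy.

        ``F = E_Q[ln Q(s) - ln P(o, s | pi)]``; at the exact posterior this
        is the negative log evidence of the observed outcomes.  Zero in the
        deterministic, fully predicted limit and of order ``-ln(LOG_EPS)``
        per observation that is impossible under the policy.
        """
        if beliefs is None:
            beliefs = self.infer_states(policy, observations)
        return -beliefs.log_evidence

    def expected_free_energy(self, policy: int, beliefs: Beliefs,
                             from_tau: int) -> float:
        """Risk plus ambiguity summed over future time steps ``tau >= from_tau``."""
        G = 0.0
        for tau in range(from_tau, self.T):
            joint = beliefs.joint[tau]
            for m in range(self.n_modalities):
                Qo = self._A_flat[m] @ joint
                risk = float(Qo @ (stable_log(Qo) - self._lnC[m][:, tau]))
                ambiguity = float(joint @ self._H[m])
                G += risk + ambiguity
        return G

    # -- policy posterior and action ---------------------------------------

    def policy_posterior(self, F: np.ndarray, G: np.ndarray,
                         E_hat: np.ndarray,
                         gamma: float | None = None) -> PolicyPosterior:
        """``softmax(E_hat - F - gamma G)`` with components kept for audit."""
        F = np.asarray(F, dtype=float)
        G = np.asarray(G, dtype=float)
        E_hat = np.asarray(E_hat, dtype=float)
        if not (F.shape == G.shape == E_hat.shape):
            raise ValueError("F, G and E_hat must share one length")
        g = self.model.gamma if gamma is None else gamma
        return PolicyPosterior(F=F, G=G, posterior=softmax(E_hat - F - g * G),
                               gamma=g)

    def select_action(self, posterior: PolicyPosterior, t: int,
                      rng: np.random.Generator) -> np.ndarray:
        """Mode of the posterior marginal over step-``t`` action vectors.

        Policy mass is pooled per distinct joint action (one index per
        factor) at step ``t``; exact ties are broken uniformly at random.
        """
        if t >= self.T - 1:
            raise ValueError("no action at the final time step")
        acts = self._pol[:, t, :]  # (k, n_factors)
        uniq, inv = np.unique(acts, axis=0, return_inverse=True)
        mass = np.zeros(len(uniq))
        np.add.at(mass, inv, posterior.posterior)
        best = np.flatnonzero(mass >= mass.max() - 1e-12)
        pick = best[0] if len(best) == 1 else int(rng.choice(best))
        return uniq[pick].copy()


def run_trial(engine: Engine, E_hat: np.ndarray, env_state,
              env_spec, rng: np.random.Generator,
              wrong_branch_uniform: bool = True,
              record_beliefs: bool = False) -> TrialRecord:
    """Execute one trial of the maze task.

    At each of the T time steps the agent observes, infers states under
    every policy, scores F over observed times and G over future times,
    forms the policy posterior with the habit term ``E_hat``, and (except
    after the final observation) takes the modal action.  The habit prior
    itself is never mutated here.
    """
    from . import maze  # local import to avoid a cycle

    model = engine.model
    if model.A[0].shape[0] != maze.N_LOCATIONS:
        raise ValueError("model does not match the maze topology")
    state = env_state
    observations: list[tuple[int, ...]] = []
    actions: list[np.ndarray] = []
    posteriors: list[PolicyPosterior] = []
    belief_snaps: list[list[Beliefs]] = []
    k = model.n_policies

    for t in range(engine.T):
        obs = maze.emit_observation(state, env_spec.cue_veracity, rng,
                                    wrong_branch_uniform)
        observations.append(obs)
        F = np.zeros(k)
        G = np.zeros(k)
        all_beliefs = []
        for p in range(k):
            beliefs = engine.infer_states(p, observations)
            F[p] = -beliefs.log_evidence
            G[p] = engine.expected_free_energy(p, beliefs, from_tau=t + 1)
            all_beliefs.append(beliefs)
        post = engine.policy_posterior(F, G, E_hat)
        posteriors.append(post)
        if record_beliefs:
            belief_snaps.append(all_beliefs)
        if t < engine.T - 1:
            action = engine.select_action(post, t, rng)
            actions.append(action)
            state = maze.step_environment(state, int(action[0]))

    return TrialRecord(
        observations=observations,
        actions=actions,
        beliefs=belief_snaps,
        posteriors=posteriors,
        reward_obtained=observations[-1][1] == maze.REWARD,
        final_location=state.location,
        context=state.context,
    )


def enumerate_posterior(model: GenerativeModel, policy: int,
                        observations: Sequence[tuple[int, ...]]
                        ) -> list[list[np.ndarray]]:
    """Exact per-time, per-factor posterior marginals by brute enumeration.

    Enumerates every joint state sequence; intended for small models and
    as an independent check on the smoothing implementation.
    """
    cards = model.factor_cards
    T = model.horizon
    t_obs = len(observations)
    actions = model.policies[policy]
    states = list(_iterproduct(*[range(c) for c in cards]))
    n_f = len(cards)

    marginals = [[np.zeros(c) for c in cards] for _ in range(T)]
    total = 0.0
    for seq in _iterproduct(states, repeat=T):
        p = 1.0
        for f in range(n_f):
            p *= model.D[f][seq[0][f]]
        for tau in range(1, T):
            for f in range(n_f):
                p *= model.B[f][actions[tau - 1, f], seq[tau][f], seq[tau - 1][f]]
        for tau in range(t_obs):
            for m in range(len(model.modalities)):
                p *= model.A[m][(observations[tau][m],) + seq[tau]]
        if p == 0.0:
            continue
        total += p
        for tau in range(T):
            for f in range(n_f):
                marginals[tau][f][seq[tau][f]] += p
    if total <= 0:
        raise ValueError("observations have zero probability under this policy")
    return [[v / total for v in row] for row in marginals]
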