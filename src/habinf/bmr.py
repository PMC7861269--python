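"""Sleep-phase Bayesian model reduction and averaging for habit priors.

Given a day's starting Dirichlet prior ``a`` and end-of-day posterior
``b`` (prior plus accumulated policy counts), the evidence for a reduced
model with alternative prior ``a'`` is available in closed form:

    dF = ln B(a) - ln B(a') + ln B(b') - ln B(b),   b' = b + a' - a

where ``B(x) = prod_i Gamma(x_i) / Gamma(sum_i x_i)`` is the multivariate
beta function (evaluated via log-gamma throughout).  The candidate space
follows a boost-and-suppress scheme: for each policy, its concentration is
increased by a fixed boost while all others are divided by each of a set
of suppression factors (floored at one so priors stay proper).  The
candidates' reduced posteriors are then combined by softmax(dF)-weighted
model averaging to produce the next day's prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .model import softmax
from .habits import DirichletPolicyPrior

#: Suppressed concentrations never drop below the naive count of one.
CONCENTRATION_FLOOR = 1.0


def log_multivariate_beta(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(gammaln(x).sum() - gammaln(x.sum()))


def dirichlet_evidence_delta(a: np.ndarray, b: np.ndarray,
                             a_reduced: np.ndarray) -> float:
    """Log-evidence difference of the reduced prior ``a_reduced`` vs ``a``.

    Exact for Dirichlet-categorical models; requires the implied reduced
    posterior ``b' = b + a' - a`` to stay positive.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ar = np.asarray(a_reduced, dtype=float)
    if not (a.shape == b.shape == ar.shape):
        raise ValueError("a, b and a_reduced must share one length")
    if np.any(ar <= 0):
        raise ValueError("reduced prior must be positive")
    br = b + ar - a
    if np.any(br <= 0):
        raise ValueError("invalid reduction: b + a' - a has nonpositive entries")
    return (log_multivariate_beta(a) - log_multivariate_beta(ar)
            + log_multivariate_beta(br) - log_multivariate_beta(b))


def generate_candidates(a: np.ndarray, boost: float = 8.0,
                        suppression_factors: tuple[float, ...] = (2.0, 4.0),
                        floor: float = CONCENTRATION_FLOOR) -> list[np.ndarray]:
    """Full model plus one boost-and-suppress candidate per (policy, factor).

    Candidate (i, f) sets ``a'_i = a_i + boost`` and
    ``a'_j = max(a_j / f, floor)`` for every other policy j.  With k
    policies and two suppression factors this yields ``2 k + 1`` candidates
    (15 for the seven-policy maze).
    """
    a = np.asarray(a, dtype=float)
    candidates = [a.copy()]
    for i in range(a.size):
        for f in suppression_factors:
            c = np.maximum(a / f, floor)
            c[i] = a[i] + boost
            candidates.append(c)
    return candidates


@dataclass
class ReducedModelCandidate:
    """One candidate prior with its reduced posterior, evidence and weight."""

    reduced_prior: np.ndarray
    reduced_posterior: np.ndarray
    delta_F: float
    weight: float


def bayesian_model_average(candidates: list[np.ndarray], a: np.ndarray,
                           b: np.ndarray
                           ) -> tuple[np.ndarray, list[ReducedModelCandidate]]:
    """softmax(dF)-weighted average of the candidates' reduced posteriors.

    Returns the averaged concentration vector (the next prior) and the
    per-candidate audit trail.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    deltas = np.array([dirichlet_evidence_delta(a, b, c) for c in candidates])
    weights = softmax(deltas)
    posteriors = [b + c - a for c in candidates]
    new_prior = np.einsum("m,mk->k", weights, np.asarray(posteriors))
    audit = [
        ReducedModelCandidate(reduced_prior=c, reduced_posterior=p,
                              delta_F=float(dF), weight=float(w))
        for c, p, dF, w in zip(candidates, posteriors, deltas, weights)
    ]
    return new_prior, audit


def sleep(prior_at_day_start: DirichletPolicyPrior,
          posterior_at_day_end: DirichletPolicyPrior,
          boost: float = 8.0,
          suppression_factors: tuple[float, ...] = (2.0, 4.0),
          return_audit: bool = False):
    """Between-day structure learning over the habit prior.

    Composes candidate generation, closed-form evidence evaluation and
    Bayesian model averaging; deterministic given its inputs.
    """
    a = prior_at_day_start.e
    b = posterior_at_day_end.e
    candidates = generate_candidates(a, boost=boost,
                                     suppression_factors=suppression_factors)
    new_e, audit = bayesian_model_average(candidates, a, b)
    new_prior = DirichletPolicyPrior(new_e)
    if return_audit:
        return new_prior, audit
    return new_prior


def audit_to_json(audit: list[ReducedModelCandidate]) -> str:
    import json

    return json.dumps([
        {"reduced_prior": c.reduced_prior.tolist(),
         "reduced_posterior": c.reduced_posterior.tolist(),
         "delta_F": c.delta_F, "weight": c.weight}
        for c in audit
    ])
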