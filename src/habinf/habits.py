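"""Dirichlet habit prior over policies and its pseudo-count updates.

The agent keeps a Dirichlet distribution ``Dir(e)`` over its policy
simplex.  After each completed trial it "observes itself" having pursued
policies in proportion to the final-time policy posterior and adds that
probability vector to the concentration parameters — a soft count.  The
expected log prior

    E_hat_i = psi(e_i) - psi(sum_j e_j)

(with ``psi`` the digamma function) is the habit term entering policy
inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma


@dataclass(frozen=True)
class DirichletPolicyPrior:
    """Concentration parameters ``e`` over the k policies."""

    e: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.e, dtype=float)
        if e.ndim != 1 or e.size < 1:
            raise ValueError("e must be a non-empty vector")
        if np.any(e <= 0) or not np.all(np.isfinite(e)):
            raise ValueError("concentration parameters must be positive finite")
        object.__setattr__(self, "e", e)

    @classmethod
    def naive(cls, k: int) -> "DirichletPolicyPrior":
        """The untrained prior: one pseudo-count per policy."""
        return cls(np.ones(k))

    @property
    def k(self) -> int:
        return int(self.e.size)

    @property
    def total(self) -> float:
        return float(self.e.sum())


def expected_log_policy_prior(prior: DirichletPolicyPrior) -> np.ndarray:
    """``E_hat_i = psi(e_i) - psi(sum e)``; negative, order-preserving in e."""
    return digamma(prior.e) - digamma(prior.e.sum())


def update_policy_counts(prior: DirichletPolicyPrior,
                         trial_posterior: np.ndarray,
                         tol: float = 1e-6) -> DirichletPolicyPrior:
    """Add one trial's final-time policy posterior to the pseudo-counts.

    The total count grows by exactly one per trial.
    """
    pi = np.asarray(trial_posterior, dtype=float)
    if pi.shape != prior.e.shape:
        raise ValueError(f"posterior length {pi.size} != prior length {prior.k}")
    if np.any(pi < 0) or abs(float(pi.sum()) - 1.0) > tol:
        raise ValueError("trial posterior must be a probability vector")
    return DirichletPolicyPrior(prior.e + pi)
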