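"""Core generative-model containers and numerical primitives.

A discrete-state generative model for planning-as-inference consists of

* a likelihood mapping ``A`` (one array per outcome modality, giving
  P(outcome | joint hidden state)),
* transition models ``B`` (one array per hidden-state factor, giving
  P(s' | s, action); uncontrollable factors carry a single action slot),
* log-preferences ``C`` over outcomes (per modality, per time step),
* initial-state beliefs ``D`` (per factor), and
* an enumerated policy space, each policy a fixed action sequence.

The containers here are deliberately thin: validation lives in
:func:`validate_model`, inference in :mod:`habinf.inference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import yaml

#: Floor applied before taking logs of possibly-zero probabilities.  Keeps
#: free energies finite without materially perturbing inference.
LOG_EPS = 1e-16

#: Tolerance for "columns sum to one" stochasticity checks.
STOCHASTIC_TOL = 1e-10


def stable_log(v: np.ndarray) -> np.ndarray:
    """Elementwise ``ln(max(v, LOG_EPS))`` for nonnegative arrays.

    Guarantees finite output for any probability vector, so downstream
    free-energy sums never produce ``-inf``.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("stable_log expects nonnegative entries")
    return np.log(np.maximum(v, LOG_EPS))


def softmax(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shift-invariant softmax; output is positive and sums to one."""
    v = np.asarray(v, dtype=float)
    shifted = v - np.max(v, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=axis, keepdims=True)


def log_softmax(v: np.ndarray, axis: int = -1) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    shifted = v - np.max(v, axis=axis, keepdims=True)
    return shifted - np.log(np.sum(np.exp(shifted), axis=axis, keepdims=True))


@dataclass(frozen=True)
class StateFactor:
    """A hidden-state factor (e.g. "where am I", "where is the reward")."""

    label: str
    cardinality: int
    controllable: bool = False


@dataclass(frozen=True)
class OutcomeModality:
    """An outcome modality (e.g. exteroceptive location, feedback cue)."""

    label: str
    cardinality: int


@dataclass
class ValidationReport:
    ok: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


@dataclass
class GenerativeModel:
    """Agent-side model: A/B/C/D components plus policies, horizon and precision.

    Attributes
    ----------
    A : list of arrays, one per modality, shape ``(n_outcomes, *factor_cards)``.
    B : list of arrays, one per factor, shape ``(n_actions, card, card)``;
        ``B[f][u][i, j] = P(s' = i | s = j, action u)``.  Uncontrollable
        factors have a single action slot.
    C : list of arrays, one per modality, shape ``(n_outcomes, T)``;
        log-preferences in nats (relative, unnormalized).
    D : list of arrays, one per factor; initial-state beliefs.
    policies : integer array ``(k, T - 1, n_factors)``; column entries for
        uncontrollable factors must be zero.
    horizon : number of time steps T (so policies hold T - 1 actions).
    gamma : precision (inverse temperature) on expected free energy.
    """

    factors: list[StateFactor]
    modalities: list[OutcomeModality]
    A: list[np.ndarray]
    B: list[np.ndarray]
    C: list[np.ndarray]
    D: list[np.ndarray]
    policies: np.ndarray
    horizon: int
    gamma: float = 1.0

    @property
    def n_policies(self) -> int:
        return int(self.policies.shape[0])

    @property
    def factor_cards(self) -> tuple[int, ...]:
        return tuple(f.cardinality for f in self.factors)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "factors": [
                {"label": f.label, "cardinality": f.cardinality,
                 "controllable": f.controllable}
                for f in self.factors
            ],
            "modalities": [
                {"label": m.label, "cardinality": m.cardinality}
                for m in self.modalities
            ],
            "A": [a.tolist() for a in self.A],
            "B": [b.tolist() for b in self.B],
            "C": [c.tolist() for c in self.C],
            "D": [d.tolist() for d in self.D],
            "policies": self.policies.tolist(),
            "horizon": int(self.horizon),
            "gamma": float(self.gamma),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GenerativeModel":
        return cls(
            factors=[StateFactor(**f) for f in d["factors"]],
            modalities=[OutcomeModality(**m) for m in d["modalities"]],
            A=[np.asarray(a, dtype=float) for a in d["A"]],
            B=[np.asarray(b, dtype=float) for b in d["B"]],
            C=[np.asarray(c, dtype=float) for c in d["C"]],
            D=[np.asarray(v, dtype=float) for v in d["D"]],
            policies=np.asarray(d["policies"], dtype=int),
            horizon=int(d["horizon"]),
            gamma=float(d["gamma"]),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "GenerativeModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _check_simplex(name: str, v: np.ndarray, out: list[str]) -> None:
    if np.any(np.asarray(v) < 0):
        out.append(f"{name}: negative entry")
    if abs(float(np.sum(v)) - 1.0) > STOCHASTIC_TOL:
        out.append(f"{name}: sums to {float(np.sum(v)):.12g}, expected 1")


def validate_model(model: GenerativeModel) -> ValidationReport:
    """Check shape consistency and stochasticity of every component.

    Returns a report object; never raises.  Violations name the offending
    component and index so factory bugs are easy to localize.
    """
    v: list[str] = []
    cards = model.factor_cards
    n_f = len(model.factors)

    for f in model.factors:
        if f.cardinality < 1:
            v.append(f"factor {f.label}: cardinality {f.cardinality} < 1")
    for m in model.modalities:
        if m.cardinality < 1:
            v.append(f"modality {m.label}: cardinality {m.cardinality} < 1")

    # A: (n_outcomes, *cards); conditional outcome vectors are simplices
    if len(model.A) != len(model.modalities):
        v.append(f"A: {len(model.A)} arrays for {len(model.modalities)} modalities")
    else:
        for m, a in zip(model.modalities, model.A):
            want = (m.cardinality,) + cards
            if a.shape != want:
                v.append(f"A[{m.label}]: shape {a.shape}, expected {want}")
                continue
            flat = a.reshape(m.cardinality, -1)
            for j in range(flat.shape[1]):
                col = flat[:, j]
                if np.any(col < 0) or abs(float(col.sum()) - 1.0) > STOCHASTIC_TOL:
                    idx = np.unravel_index(j, cards)
                    v.append(f"A[{m.label}]: column {idx} not a probability vector")

    # B: per factor, (n_actions, card, card) column-stochastic
    if len(model.B) != n_f:
        v.append(f"B: {len(model.B)} arrays for {n_f} factors")
    else:
        for f, b in zip(model.factors, model.B):
            if b.ndim != 3 or b.shape[1:] != (f.cardinality, f.cardinality):
                v.append(f"B[{f.label}]: shape {b.shape}, expected (u, "
                         f"{f.cardinality}, {f.cardinality})")
                continue
            if not f.controllable and b.shape[0] != 1:
                v.append(f"B[{f.label}]: uncontrollable factor with "
                         f"{b.shape[0]} action slots")
            for u in range(b.shape[0]):
                for j in range(f.cardinality):
                    col = b[u, :, j]
                    if np.any(col < 0) or abs(float(col.sum()) - 1.0) > STOCHASTIC_TOL:
                        v.append(f"B[{f.label}]: column (u={u}, s={j}) not stochastic")

    # C: per modality, (n_outcomes, T), finite
    if len(model.C) != len(model.modalities):
        v.append(f"C: {len(model.C)} arrays for {len(model.modalities)} modalities")
    else:
        for m, c in zip(model.modalities, model.C):
            if c.shape != (m.cardinality, model.horizon):
                v.append(f"C[{m.label}]: shape {c.shape}, expected "
                         f"({m.cardinality}, {model.horizon})")
            elif not np.all(np.isfinite(c)):
                v.append(f"C[{m.label}]: non-finite entries")

    # D: per factor, a simplex
    if len(model.D) != n_f:
        v.append(f"D: {len(model.D)} arrays for {n_f} factors")
    else:
        for f, d in zip(model.factors, model.D):
            if d.shape != (f.cardinality,):
                v.append(f"D[{f.label}]: shape {d.shape}, expected ({f.cardinality},)")
            else:
                _check_simplex(f"D[{f.label}]", d, v)

    # policies: (k, T-1, n_factors), valid action indices, distinct rows
    p = model.policies
    if p.ndim != 3 or p.shape[1] != model.horizon - 1 or p.shape[2] != n_f:
        v.append(f"policies: shape {p.shape}, expected (k, {model.horizon - 1}, {n_f})")
    else:
        if p.shape[0] < 1:
            v.append("policies: empty policy space")
        for f_i, (f, b) in enumerate(zip(model.factors, model.B)):
            col = p[:, :, f_i]
            if not f.controllable:
                if np.any(col != 0):
                    v.append(f"policies: nonzero actions for uncontrollable "
                             f"factor {f.label}")
            elif b.ndim == 3 and (np.any(col < 0) or np.any(col >= b.shape[0])):
                v.append(f"policies: action index out of range for factor {f.label}")
        seen = {tuple(row.ravel()) for row in p}
        if len(seen) != p.shape[0]:
            v.append("policies: duplicate policies")

    if model.gamma <= 0:
        v.append(f"gamma: {model.gamma} not positive")
    if model.horizon < 1:
        v.append(f"horizon: {model.horizon} < 1")

    return ValidationReport(ok=not v, violations=v)
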