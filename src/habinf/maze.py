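"""Two-step maze: generative process and matching generative-model factory.

The maze has 7 locations arranged in a forward-only binary tree::

                0            (initial)
              /   \\
             1     2         (intermediate)
            / \\   / \\
           3   4 5   6       (final)

Indices are zero-based here; the final location for reward context ``c``
(0..3) is ``3 + c``, so contexts 0-1 live in the left branch and 2-3 in
the right branch.

The agent receives two outcome modalities each time step: its location
("Where", always veridical) and a "Feedback" signal.  At the initial and
intermediate locations, Feedback is a directional cue that points toward
the reward with probability ``cue_veracity``; at an intermediate location
of the branch that does *not* contain the reward, the cue is uninformative
(left/right with equal probability).  At final locations, Feedback is a
deterministic reward or punishment.

The same parameterization builds both the environment's emission rules and
the agent's likelihood model, so by default the agent's beliefs about cue
reliability match the world that generates them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import (
    GenerativeModel,
    OutcomeModality,
    StateFactor,
)

# Actions for the controllable location factor.
STAY, LEFT, RIGHT = 0, 1, 2

# Feedback outcomes.
CUE_LEFT, CUE_RIGHT, REWARD, PUNISH = 0, 1, 2, 3

N_LOCATIONS = 7
N_CONTEXTS = 4
FINAL_LOCATIONS = (3, 4, 5, 6)

#: NEXT[action][location] under the forward-only topology; final locations
#: are absorbing under every action.
_NEXT = {
    STAY: (0, 1, 2, 3, 4, 5, 6),
    LEFT: (1, 3, 5, 3, 4, 5, 6),
    RIGHT: (2, 4, 6, 3, 4, 5, 6),
}

#: The 7 policies: four reach a final location, two stop at an intermediate
#: location, one never moves.
MAZE_POLICIES = (
    (LEFT, LEFT),    # -> final 3
    (LEFT, RIGHT),   # -> final 4
    (RIGHT, LEFT),   # -> final 5
    (RIGHT, RIGHT),  # -> final 6
    (LEFT, STAY),    # -> intermediate 1
    (RIGHT, STAY),   # -> intermediate 2
    (STAY, STAY),    # -> initial 0
)


@dataclass(frozen=True)
class EnvironmentSpec:
    """An environment regime: reward-context frequencies and cue veracity."""

    name: str
    context_frequencies: tuple[float, float, float, float]
    cue_veracity: float

    def __post_init__(self) -> None:
        freqs = np.asarray(self.context_frequencies, dtype=float)
        if freqs.shape != (N_CONTEXTS,) or np.any(freqs < 0) or \
                abs(float(freqs.sum()) - 1.0) > 1e-10:
            raise ValueError("context_frequencies must be a length-4 simplex")
        if not (0.0 < self.cue_veracity <= 1.0):
            raise ValueError("cue_veracity must lie in (0, 1]")

    def with_veracity(self, cue_veracity: float) -> "EnvironmentSpec":
        return replace(self, cue_veracity=cue_veracity)


def nonvolatile_spec(cue_veracity: float = 0.99) -> EnvironmentSpec:
    """Conservative regime: reward only at the two left final locations."""
    return EnvironmentSpec("nonvolatile", (0.5, 0.5, 0.0, 0.0), cue_veracity)


def volatile_spec(cue_veracity: float = 0.99) -> EnvironmentSpec:
    """Volatile regime: reward at any of the four final locations."""
    return EnvironmentSpec("volatile", (0.25, 0.25, 0.25, 0.25), cue_veracity)


def novel_spec(cue_veracity: float = 0.99) -> EnvironmentSpec:
    """Novel regime: reward only at the two right final locations."""
    return EnvironmentSpec("novel", (0.0, 0.0, 0.5, 0.5), cue_veracity)


ENVIRONMENTS = {
    "nonvolatile": nonvolatile_spec,
    "volatile": volatile_spec,
    "novel": novel_spec,
}


@dataclass(frozen=True)
class EnvironmentState:
    """Per-trial ground truth: agent location and reward context."""

    location: int
    context: int

    @property
    def reward_location(self) -> int:
        return 3 + self.context


def feedback_probs(location: int, context: int, cue_veracity: float,
                   wrong_branch_uniform: bool = True) -> np.ndarray:
    """P(Feedback outcome | location, context) as a length-4 vector.

    ``wrong_branch_uniform`` controls the cue at an intermediate location
    when the reward sits in the other branch: uniform left/right by default
    (maximally ambiguous), otherwise pointing toward the reward branch with
    the configured veracity.
    """
    v = cue_veracity
    p = np.zeros(4)
    if location in FINAL_LOCATIONS:
        p[REWARD if location == 3 + context else PUNISH] = 1.0
        return p
    if location == 0:
        correct = CUE_LEFT if context < 2 else CUE_RIGHT
    elif location == 1:
        if context == 0:
            correct = CUE_LEFT
        elif context == 1:
            correct = CUE_RIGHT
        else:  # reward in the right branch
            if wrong_branch_uniform:
                p[CUE_LEFT] = p[CUE_RIGHT] = 0.5
                return p
            correct = CUE_RIGHT
    else:  # location == 2
        if context == 2:
            correct = CUE_LEFT
        elif context == 3:
            correct = CUE_RIGHT
        else:
            if wrong_branch_uniform:
                p[CUE_LEFT] = p[CUE_RIGHT] = 0.5
                return p
            correct = CUE_LEFT
    p[correct] = v
    p[CUE_RIGHT if correct == CUE_LEFT else CUE_LEFT] = 1.0 - v
    return p


def sample_context(spec: EnvironmentSpec, rng: np.random.Generator) -> int:
    """Draw a reward context for a new trial (between-trial volatility)."""
    return int(rng.choice(N_CONTEXTS, p=np.asarray(spec.context_frequencies)))


def initial_state(spec: EnvironmentSpec, rng: np.random.Generator) -> EnvironmentState:
    return EnvironmentState(location=0, context=sample_context(spec, rng))


def emit_observation(state: EnvironmentState, cue_veracity: float,
                     rng: np.random.Generator,
                     wrong_branch_uniform: bool = True) -> tuple[int, int]:
    """Sample the (Where, Feedback) outcome pair for the current state.

    The Where outcome is always the true location; Feedback is drawn from
    :func:`feedback_probs`.
    """
    p = feedback_probs(state.location, state.context, cue_veracity,
                       wrong_branch_uniform)
    feedback = int(rng.choice(4, p=p))
    return state.location, feedback


def step_environment(state: EnvironmentState, action: int) -> EnvironmentState:
    """Apply a movement action; context never changes within a trial."""
    if action not in _NEXT:
        raise ValueError(f"invalid action {action}")
    return EnvironmentState(location=_NEXT[action][state.location],
                            context=state.context)


def build_maze_model(cue_veracity: float,
                     reward_utility: float = 3.0,
                     punishment_utility: float = -3.0,
                     gamma: float = 1.0,
                     wrong_branch_uniform: bool = True) -> GenerativeModel:
    """Construct the agent's generative model of the two-step maze.

    Parameters
    ----------
    cue_veracity : probability the agent believes a cue points toward the
        reward (shared with the emission process unless the caller builds
        the environment with a different value).
    reward_utility, punishment_utility : log-preferences (nats) assigned to
        the reward and punishment outcomes at every time step; cues carry
        zero utility.
    gamma : precision on expected free energy in policy inference.
    """
    if not (0.0 < cue_veracity <= 1.0):
        raise ValueError("cue_veracity must lie in (0, 1]")
    T = 3
    factors = [
        StateFactor("location", N_LOCATIONS, controllable=True),
        StateFactor("context", N_CONTEXTS, controllable=False),
    ]
    modalities = [
        OutcomeModality("where", N_LOCATIONS),
        OutcomeModality("feedback", 4),
    ]

    a_where = np.zeros((N_LOCATIONS, N_LOCATIONS, N_CONTEXTS))
    for loc in range(N_LOCATIONS):
        a_where[loc, loc, :] = 1.0  # the agent always knows where it is

    a_feedback = np.zeros((4, N_LOCATIONS, N_CONTEXTS))
    for loc in range(N_LOCATIONS):
        for ctx in range(N_CONTEXTS):
            a_feedback[:, loc, ctx] = feedback_probs(
                loc, ctx, cue_veracity, wrong_branch_uniform)

    b_loc = np.zeros((3, N_LOCATIONS, N_LOCATIONS))
    for u, nxt in _NEXT.items():
        for j, i in enumerate(nxt):
            b_loc[u, i, j] = 1.0
    b_ctx = np.eye(N_CONTEXTS)[None, :, :]  # context is static within a trial

    c_where = np.zeros((N_LOCATIONS, T))
    c_feedback = np.zeros((4, T))
    c_feedback[REWARD, :] = reward_utility
    c_feedback[PUNISH, :] = punishment_utility

    d = [np.eye(N_LOCATIONS)[0], np.full(N_CONTEXTS, 1.0 / N_CONTEXTS)]

    policies = np.zeros((len(MAZE_POLICIES), T - 1, 2), dtype=int)
    policies[:, :, 0] = np.asarray(MAZE_POLICIES)

    return GenerativeModel(
        factors=factors, modalities=modalities,
        A=[a_where, a_feedback], B=[b_loc, b_ctx],
        C=[c_where, c_feedback], D=d,
        policies=policies, horizon=T, gamma=gamma,
    )
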