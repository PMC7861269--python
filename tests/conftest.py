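import numpy as np
import pytest

import habinf as hi


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def maze_model_unambiguous():
    return hi.build_maze_model(0.99)


@pytest.fixture(scope="session")
def specialist_training():
    """Full-length training in the conservative regime (shared, expensive)."""
    return hi.train_agent(hi.nonvolatile_spec(), days=32, trials_per_day=8,
                          cue_veracity=0.99, seed=11)


@pytest.fixture(scope="session")
def generalist_training():
    """Full-length training in the volatile regime (shared, expensive)."""
    return hi.train_agent(hi.volatile_spec(), days=32, trials_per_day=8,
                          cue_veracity=0.99, seed=12)


def random_toy_model(rng, cards=(3, 4), n_outcomes=(3, 2), T=3,
                     n_actions=2):
    """A small random two-factor model for enumeration cross-checks."""
    from habinf.model import (
        GenerativeModel, OutcomeModality, StateFactor,
    )

    factors = [hi.StateFactor("f0", cards[0], controllable=True),
               hi.StateFactor("f1", cards[1], controllable=False)]
    modalities = [hi.OutcomeModality(f"m{i}", n) for i, n in enumerate(n_outcomes)]

    def col_stochastic(shape):
        x = rng.uniform(0.05, 1.0, size=shape)
        return x / x.sum(axis=0, keepdims=True)

    A = [col_stochastic((n,) + tuple(cards)).reshape((n,) + tuple(cards))
         for n in n_outcomes]
    B = [np.stack([col_stochastic((cards[0], cards[0]))
                   for _ in range(n_actions)]),
         col_stochastic((cards[1], cards[1]))[None]]
    C = [rng.normal(size=(n, T)) for n in n_outcomes]
    D = [col_stochastic((c, 1))[:, 0] for c in cards]
    pol = np.zeros((3, T - 1, 2), dtype=int)
    pol[:, :, 0] = rng.integers(0, n_actions, size=(3, T - 1))
    while len({tuple(p.ravel()) for p in pol}) < 3:  # ensure distinct
        pol[:, :, 0] = rng.integers(0, n_actions, size=(3, T - 1))
    return GenerativeModel(factors=factors, modalities=modalities,
                           A=A, B=B, C=C, D=D, policies=pol,
                           horizon=T, gamma=1.0)
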