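import numpy as np
import pytest

from discreg import TabularMDP


def random_mdp(rng: np.random.Generator, n_states: int = 5, n_actions: int = 2,
               gamma: float = 0.9) -> TabularMDP:
    """Dense random MDP with Dirichlet transition rows and U[0,1] rewards."""
    t = rng.dirichlet(np.ones(n_states), size=(n_states, n_actions))
    r = rng.uniform(0.0, 1.0, size=(n_states, n_actions))
    return TabularMDP(r, t, gamma)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_mdp(rng):
    return random_mdp(rng, n_states=5, n_actions=2, gamma=0.9)
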