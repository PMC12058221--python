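"""Seedable benchmark environments.

Three tabular environments spanning different structure and reward shapes —
a randomly generated 10-state chain, the six-state River Swim with its
stochastic swim-upstream action, and a 4×4 GridWorld with per-state slip
probabilities — plus a one-dimensional continuous-state River Swim.  The
tabular generators return :class:`~discreg.mdp_core.TabularMDP` objects;
the continuous one returns a small simulator (reward function, stochastic
step function, bounds) together with a helper that discretizes its exact
dynamics onto a uniform grid for evaluation.

River Swim numeric parameters are not uniquely standardized; the defaults
below follow the common construction (tiny reward for loitering at the
left bank, reward 1 for reaching the right bank against the current) and
every number can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .mdp_core import TabularMDP

__all__ = [
    "EnvParams",
    "ContinuousSimulator",
    "make_random_chain",
    "make_river_swim",
    "make_gridworld",
    "make_continuous_river_swim",
    "make_environment",
    "discretize_continuous",
]

DEFAULT_GAMMA = 0.99


@dataclass
class EnvParams:
    """Named environment plus seed and parameter overrides."""

    name: str
    seed: int = 0
    overrides: dict = field(default_factory=dict)


def make_environment(params: EnvParams) -> "TabularMDP | ContinuousSimulator":
    builders = {
        "random_chain": lambda: make_random_chain(params.seed, **params.overrides),
        "river_swim": lambda: make_river_swim(**params.overrides),
        "gridworld": lambda: make_gridworld(params.seed, **params.overrides),
        "continuous_river_swim": lambda: make_continuous_river_swim(**params.overrides),
    }
    if params.name not in builders:
        raise ValueError(f"unknown environment {params.name!r}")
    return builders[params.name]()


def make_random_chain(seed: int = 0, gamma: float = DEFAULT_GAMMA) -> TabularMDP:
    """Random 10-state, 2-action MDP.

    For each (s, a), 5 successor states are chosen at random to carry
    nonzero probability; their probabilities are drawn Uniform[0,1] and
    normalized.  Rewards are Uniform[0,1].  A fresh MDP should be drawn
    per replicate when benchmarking.
    """
    rng = np.random.default_rng(seed)
    ns, na, k = 10, 2, 5
    t = np.zeros((ns, na, ns))
    for s in range(ns):
        for a in range(na):
            succ = rng.choice(ns, size=k, replace=False)
            p = rng.uniform(0.0, 1.0, size=k)
            t[s, a, succ] = p / p.sum()
    rewards = rng.uniform(0.0, 1.0, size=(ns, na))
    return TabularMDP(rewards, t, gamma)


def make_river_swim(
    n_states: int = 6,
    gamma: float = DEFAULT_GAMMA,
    reward_left: float = 0.005,
    reward_right: float = 1.0,
    p_right: float = 0.3,
    p_stay: float = 0.6,
    p_slip: float = 0.1,
) -> TabularMDP:
    """Six-state River Swim: swim left with the current or right against it.

    Action 0 (left) moves one state left deterministically (stays at the
    left bank).  Action 1 (right) succeeds with probability ``p_right``,
    stays with ``p_stay`` and slips left with ``p_slip``; at the banks the
    blocked mass is folded into staying.  Reward ``reward_left`` for the
    left action at the leftmost state, ``reward_right`` for the right
    action at the rightmost state, zero elsewhere.
    """
    if not np.isclose(p_right + p_stay + p_slip, 1.0):
        raise ValueError("p_right + p_stay + p_slip must equal 1")
    if min(p_right, p_stay, p_slip) < 0:
        raise ValueError("transition probabilities must be nonnegative")
    ns, na = n_states, 2
    t = np.zeros((ns, na, ns))
    for s in range(ns):
        t[s, 0, max(s - 1, 0)] = 1.0  # left: deterministic, with the current
        right = min(s + 1, ns - 1)
        left = max(s - 1, 0)
        t[s, 1, right] += p_right if right != s else 0.0
        t[s, 1, left] += p_slip if left != s else 0.0
        t[s, 1, s] += 1.0 - t[s, 1].sum()  # blocked mass stays
    rewards = np.zeros((ns, na))
    rewards[0, 0] = reward_left
    rewards[ns - 1, 1] = reward_right
    return TabularMDP(rewards, t, gamma)


def make_gridworld(seed: int = 0, side: int = 4, gamma: float = DEFAULT_GAMMA) -> TabularMDP:
    """4×4 GridWorld with per-state slip-to-random-successor dynamics.

    Actions are left/right/up/down.  Each state draws p_s ~ Uniform[0,1]:
    with probability p_s the agent moves in the intended direction if
    possible (otherwise stays), and with 1 − p_s it jumps to a random
    successor fixed per state at construction.  One random state has
    reward 1; the rest draw rewards Uniform[−0.5, 0.5].
    """
    rng = np.random.default_rng(seed)
    ns, na = side * side, 4
    moves = {0: (0, -1), 1: (0, 1), 2: (-1, 0), 3: (1, 0)}  # left, right, up, down
    p_s = rng.uniform(0.0, 1.0, size=ns)
    jump_to = rng.integers(0, ns, size=ns)
    t = np.zeros((ns, na, ns))
    for s in range(ns):
        r, c = divmod(s, side)
        for a in range(na):
            dr, dc = moves[a]
            nr, nc = r + dr, c + dc
            target = nr * side + nc if 0 <= nr < side and 0 <= nc < side else s
            t[s, a, target] += p_s[s]
            t[s, a, jump_to[s]] += 1.0 - p_s[s]
    rewards = rng.uniform(-0.5, 0.5, size=ns)
    rewards[rng.integers(0, ns)] = 1.0
    return TabularMDP(np.tile(rewards[:, None], (1, na)), t, gamma)


# ---------------------------------------------------------------------------
# Continuous River Swim
# ---------------------------------------------------------------------------


@dataclass
class ContinuousSimulator:
    """One-dimensional continuous-state environment on [lo, hi].

    ``reward_fn(s)`` is a state reward shared across actions; ``step_fn``
    draws a stochastic next state; ``transition_density(s, a)`` returns the
    (lo, hi) support of the uniform next-state distribution before clipping,
    which lets evaluation code integrate the dynamics exactly.
    """

    reward_fn: Callable[[np.ndarray], np.ndarray]
    step_fn: Callable[[np.ndarray, int, np.random.Generator], np.ndarray]
    bounds: tuple[float, float]
    n_actions: int
    gamma: float
    transition_support: Callable[[np.ndarray, int], tuple[np.ndarray, np.ndarray]]


def make_continuous_river_swim(
    gamma: float = DEFAULT_GAMMA,
    drift: float = 0.05,
    noise_up: float = 0.2,
    noise_down: float = 0.05,
    reward_low: float = 0.1,
    reward_high: float = 1.0,
) -> ContinuousSimulator:
    """Continuous River Swim on s ∈ [0, 1].

    Action 0 swims against the current: drift +``drift`` with uniform noise
    of total width ``noise_up``.  Action 1 swims with the current: drift
    −``drift`` with narrower noise ``noise_down``.  Next states are clipped
    to [0, 1].  The reward is a function of state only: a small bump of
    height ``reward_low`` at the low end and a large bump of height
    ``reward_high`` at the high end::

        r(s) = reward_low·max(0, 1 − s/0.1) + reward_high·max(0, (s − 0.9)/0.1)
    """

    def reward_fn(s):
        s = np.asarray(s, dtype=float)
        return reward_low * np.maximum(0.0, 1.0 - s / 0.1) + reward_high * np.maximum(
            0.0, (s - 0.9) / 0.1
        )

    def support(s, a):
        s = np.asarray(s, dtype=float)
        if a == 0:
            center, width = s + drift, noise_up
        else:
            center, width = s - drift, noise_down
        return center - width / 2.0, center + width / 2.0

    def step_fn(s, a, rng):
        lo, hi = support(s, a)
        return np.clip(rng.uniform(lo, hi), 0.0, 1.0)

    return ContinuousSimulator(
        reward_fn=reward_fn,
        step_fn=step_fn,
        bounds=(0.0, 1.0),
        n_actions=2,
        gamma=gamma,
        transition_support=support,
    )


def discretize_continuous(sim: ContinuousSimulator, n_bins: int = 201) -> TabularMDP:
    """Project the continuous simulator onto a uniform grid of bin centers.

    The uniform next-state noise is integrated exactly over the bins, with
    out-of-range mass assigned to the boundary bins (matching the clipping
    in ``step_fn``).  Used to evaluate continuous-state policies exactly.
    """
    lo, hi = sim.bounds
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    t = np.zeros((n_bins, sim.n_actions, n_bins))
    for a in range(sim.n_actions):
        s_lo, s_hi = sim.transition_support(centers, a)
        width = s_hi - s_lo
        for b in range(n_bins):
            # mass of U[s_lo, s_hi] falling in bin b, before clipping
            overlap = np.clip(np.minimum(s_hi, edges[b + 1]) - np.maximum(s_lo, edges[b]), 0, None)
            t[:, a, b] = overlap / width
        t[:, a, 0] += np.clip(np.minimum(s_hi, lo) - s_lo, 0, None) / width  # clipped below
        t[:, a, -1] += np.clip(s_hi - np.maximum(s_lo, hi), 0, None) / width  # clipped above
    rewards = np.tile(sim.reward_fn(centers)[:, None], (1, sim.n_actions))
    return TabularMDP(rewards, t, sim.gamma)
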