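"""Batch data generation and transition-model estimation.

Offline RL starts from a fixed batch of (state, action, next_state, reward)
tuples.  This module samples such batches from a true tabular MDP under
three schemes (equal per-pair counts, uniformly random state-action pairs,
or behavior-policy trajectories), tallies them into a count tensor
c(s, a, s'), and turns counts into transition estimates: the per-row MLE
or the posterior mean under a Dirichlet prior.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .mdp_core import Policy, TabularMDP

__all__ = [
    "TransitionDataset",
    "CountTensor",
    "DirichletPrior",
    "sample_dataset",
    "count_transitions",
    "mle_transition",
    "dirichlet_posterior_mean",
]

Scheme = Literal["equal_counts", "uniform_sa", "trajectories"]

DATASET_COLUMNS = ["replicate", "step", "state", "action", "reward", "next_state"]


@dataclass(frozen=True)
class TransitionDataset:
    """A batch of (s, a, s', r) tuples with its generating seed and scheme."""

    states: np.ndarray
    actions: np.ndarray
    next_states: np.ndarray
    rewards: np.ndarray
    seed: int
    scheme: str

    def __post_init__(self):
        for name in ("states", "actions", "next_states"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=int))
        object.__setattr__(self, "rewards", np.asarray(self.rewards, dtype=float))
        n = len(self.states)
        if not (len(self.actions) == len(self.next_states) == len(self.rewards) == n):
            raise ValueError("dataset columns must have equal length")

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterable[tuple[int, int, int, float]]:
        return zip(self.states, self.actions, self.next_states, self.rewards)

    def to_csv(self, path: str | Path, replicate: int = 0) -> None:
        """Write the interchange CSV (replicate,step,state,action,reward,next_state)."""
        pd.DataFrame(
            {
                "replicate": replicate,
                "step": np.arange(len(self)),
                "state": self.states,
                "action": self.actions,
                "reward": self.rewards,
                "next_state": self.next_states,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, replicate: int | None = None) -> "TransitionDataset":
        df = pd.read_csv(path)
        missing = set(DATASET_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"dataset CSV missing columns: {sorted(missing)}")
        if replicate is not None:
            df = df[df["replicate"] == replicate]
        return cls(
            states=df["state"].to_numpy(),
            actions=df["action"].to_numpy(),
            next_states=df["next_state"].to_numpy(),
            rewards=df["reward"].to_numpy(),
            seed=-1,
            scheme="csv",
        )


@dataclass(frozen=True)
class CountTensor:
    """Per-(s, a, s') transition counts c and marginals n(s,a) = Σ_k c(s,a,k)."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ValueError("counts must be a (Ns, Na, Ns) tensor")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n_sa(self) -> np.ndarray:
        """Marginal count n(s,a), shape (Ns, Na)."""
        return self.counts.sum(axis=2)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class DirichletPrior:
    """Dirichlet prior over each transition row; scalar α means a uniform prior."""

    alpha: np.ndarray | float

    def as_tensor(self, n_states: int, n_actions: int) -> np.ndarray:
        a = np.asarray(self.alpha, dtype=float)
        if a.ndim == 0:
            if a <= 0:
                raise ValueError("scalar alpha must be positive")
            return np.full((n_states, n_actions, n_states), float(a))
        if a.shape != (n_states, n_actions, n_states):
            raise ValueError(f"alpha shape {a.shape} does not match the MDP")
        if np.any(a <= 0):
            raise ValueError("all alpha entries must be positive")
        return a


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _replicate_rng(seed: int, replicate: int = 0) -> np.random.Generator:
    # deterministic substream: replicate index mixed into the master seed
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate)]))


def sample_dataset(
    mdp: TabularMDP,
    scheme: Scheme = "uniform_sa",
    size_spec: int | tuple = 1,
    rng_seed: int = 0,
    replicate: int = 0,
    behavior_policy: Policy | None = None,
) -> TransitionDataset:
    """Sample a batch dataset from the true MDP.

    scheme='equal_counts': ``size_spec`` is the per-(s,a) count; every pair
    gets exactly that many transitions.  scheme='uniform_sa': ``size_spec``
    is the total number of tuples, each with (s,a) uniform at random.
    scheme='trajectories': ``size_spec`` is ``(n_trajectories, length)``;
    actions follow ``behavior_policy`` or, by default, uniform-random
    actions from a uniform start state.

    Rewards attached to tuples are the known R(s,a).  Sampling is
    bit-reproducible given (rng_seed, replicate).
    """
    rng = _replicate_rng(rng_seed, replicate)
    ns, na = mdp.n_states, mdp.n_actions

    if scheme == "equal_counts":
        per = int(size_spec)
        if per <= 0:
            raise ValueError("equal_counts requires a positive per-(s,a) count")
        s = np.repeat(np.arange(ns), na * per)
        a = np.tile(np.repeat(np.arange(na), per), ns)
    elif scheme == "uniform_sa":
        total = int(size_spec)
        if total <= 0:
            raise ValueError("uniform_sa requires a positive total size")
        sa = rng.integers(0, ns * na, size=total)
        s, a = sa // na, sa % na
    elif scheme == "trajectories":
        try:
            n_traj, length = int(size_spec[0]), int(size_spec[1])
        except (TypeError, IndexError):
            raise ValueError("trajectories requires size_spec=(n_trajectories, length)")
        if n_traj <= 0 or length <= 0:
            raise ValueError("trajectory counts and lengths must be positive")
        s_list, a_list, sp_list = [], [], []
        for _ in range(n_traj):
            state = int(rng.integers(0, ns))
            for _ in range(length):
                if behavior_policy is not None:
                    action = int(behavior_policy.actions[state])
                else:
                    action = int(rng.integers(0, na))
                nxt = int(rng.choice(ns, p=mdp.transitions[state, action]))
                s_list.append(state)
                a_list.append(action)
                sp_list.append(nxt)
                state = nxt
        s = np.asarray(s_list)
        a = np.asarray(a_list)
        sp = np.asarray(sp_list)
        return TransitionDataset(s, a, sp, mdp.rewards[s, a], rng_seed, scheme)
    else:
        raise ValueError(f"unknown sampling scheme {scheme!r}")

    # vectorized categorical draw via inverse-CDF on the relevant rows
    cdf = np.cumsum(mdp.transitions[s, a], axis=1)
    u = rng.random(len(s))
    sp = (u[:, None] > cdf).sum(axis=1)
    return TransitionDataset(s, a, sp, mdp.rewards[s, a], rng_seed, scheme)


def count_transitions(ds: TransitionDataset, n_states: int, n_actions: int) -> CountTensor:
    """Tally a dataset into the count tensor c(s, a, s')."""
    for name, arr, hi in (
        ("state", ds.states, n_states),
        ("action", ds.actions, n_actions),
        ("next_state", ds.next_states, n_states),
    ):
        if len(arr) and (arr.min() < 0 or arr.max() >= hi):
            raise ValueError(f"dataset contains out-of-range {name} indices")
    flat = (ds.states * n_actions + ds.actions) * n_states + ds.next_states
    counts = np.bincount(flat, minlength=n_states * n_actions * n_states)
    return CountTensor(counts.reshape(n_states, n_actions, n_states))


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------


def mle_transition(
    counts: CountTensor, zero_row_mode: Literal["uniform", "flag"] = "uniform"
) -> np.ndarray | tuple[np.ndarray, list[tuple[int, int]]]:
    """Per-row maximum-likelihood transition estimate c(s,a,·)/n(s,a).

    Rows with no observations become uniform (``zero_row_mode='uniform'``,
    the default) or are returned alongside the estimate as a list of
    unobserved (s, a) pairs (``'flag'``; those rows are uniform too so the
    result is always a valid kernel).
    """
    if zero_row_mode not in ("uniform", "flag"):
        raise ValueError("zero_row_mode must be 'uniform' or 'flag'")
    c = counts.counts.astype(float)
    n = c.sum(axis=2, keepdims=True)
    ns = c.shape[2]
    with np.errstate(invalid="ignore"):
        t = np.where(n > 0, c / np.where(n > 0, n, 1), 1.0 / ns)
    if zero_row_mode == "flag":
        zero = np.argwhere(counts.n_sa == 0)
        return t, [tuple(map(int, ij)) for ij in zero]
    return t


def dirichlet_posterior_mean(counts: CountTensor, prior: DirichletPrior) -> np.ndarray:
    """Posterior-mean transition rows (c + α)/(n + Σα) under a Dirichlet prior.

    Algebraically identical to shrinking the MLE toward the prior mean with
    per-row weight ε = Σα/(n + Σα) — the weighted-average view that links
    Dirichlet smoothing to discount regularization.
    """
    c = counts.counts.astype(float)
    ns, na, _ = c.shape
    a = prior.as_tensor(ns, na)
    return (c + a) / (c + a).sum(axis=2, keepdims=True)
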