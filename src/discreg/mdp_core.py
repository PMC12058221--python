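"""Exact planning and evaluation for finite Markov decision processes.

This module provides the tabular MDP container and the exact operations the
regularization methods are built on: value iteration for the optimal policy,
direct linear-solve policy evaluation, the policy-loss metric used to score
learned policies against the true optimum, and the λ-return decomposition
that connects discount regularization to truncated eligibility-trace returns.

Conventions
-----------
States and actions are 0-indexed integers.  Greedy policies break ties by
the lowest action index so that provably-equivalent solvers return identical
policies.  ``rewards`` is an ``(n_states, n_actions)`` array and
``transitions`` an ``(n_states, n_actions, n_states)`` row-stochastic tensor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "TabularMDP",
    "Policy",
    "QTable",
    "ValueVector",
    "LambdaReturnInput",
    "ConvergenceError",
    "solve_optimal",
    "evaluate_policy",
    "policy_loss",
    "lambda_return",
    "discount_regularized_return",
]

ROW_SUM_TOL = 1e-9


class ConvergenceError(RuntimeError):
    """Raised when an iterative solver fails to reach its tolerance."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        self.max_iter = max_iter
        super().__init__(
            f"value iteration did not converge within {max_iter} iterations "
            f"(sup-norm residual {residual:.3e})"
        )


@dataclass(frozen=True)
class TabularMDP:
    """A finite MDP: rewards R(s,a), transition kernel T(s,a,s') and true γ.

    The discount factor stored here is the *true* discount under which
    policies are evaluated; planning may use a lower one.
    """

    rewards: np.ndarray
    transitions: np.ndarray
    gamma: float

    def __post_init__(self):
        r = np.asarray(self.rewards, dtype=float)
        t = np.asarray(self.transitions, dtype=float)
        object.__setattr__(self, "rewards", r)
        object.__setattr__(self, "transitions", t)
        if r.ndim != 2:
            raise ValueError("rewards must be a (n_states, n_actions) matrix")
        if t.shape != (r.shape[0], r.shape[1], r.shape[0]):
            raise ValueError(
                f"transitions shape {t.shape} inconsistent with rewards {r.shape}"
            )
        if not np.all(np.isfinite(r)):
            raise ValueError("rewards must be finite")
        if np.any(t < -ROW_SUM_TOL) or np.any(t > 1 + ROW_SUM_TOL):
            raise ValueError("transition entries must lie in [0, 1]")
        row_sums = t.sum(axis=2)
        if not np.allclose(row_sums, 1.0, atol=ROW_SUM_TOL):
            worst = float(np.abs(row_sums - 1.0).max())
            raise ValueError(f"transition rows must sum to 1 (worst error {worst:.2e})")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")

    @property
    def n_states(self) -> int:
        return self.rewards.shape[0]

    @property
    def n_actions(self) -> int:
        return self.rewards.shape[1]

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize to the row-major JSON interchange format."""
        payload = {
            "n_states": self.n_states,
            "n_actions": self.n_actions,
            "gamma": self.gamma,
            "rewards": self.rewards.ravel().tolist(),
            "transitions": self.transitions.ravel().tolist(),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TabularMDP":
        try:
            is_file = Path(str(source)).exists()
        except OSError:
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        d = json.loads(text)
        ns, na = d["n_states"], d["n_actions"]
        return cls(
            rewards=np.asarray(d["rewards"], dtype=float).reshape(ns, na),
            transitions=np.asarray(d["transitions"], dtype=float).reshape(ns, na, ns),
            gamma=float(d["gamma"]),
        )


@dataclass(frozen=True)
class Policy:
    """Deterministic policy: one action index per state."""

    actions: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.actions, dtype=int)
        object.__setattr__(self, "actions", a)
        if a.ndim != 1:
            raise ValueError("policy must be a flat vector of action indices")

    def __len__(self) -> int:
        return len(self.actions)

    def __eq__(self, other) -> bool:
        return isinstance(other, Policy) and np.array_equal(self.actions, other.actions)

    def validate_for(self, mdp: TabularMDP) -> None:
        if len(self.actions) != mdp.n_states:
            raise ValueError("policy length does not match the state space")
        if np.any(self.actions < 0) or np.any(self.actions >= mdp.n_actions):
            raise ValueError("policy contains out-of-range action indices")


@dataclass(frozen=True)
class QTable:
    """State-action values, shape (n_states, n_actions)."""

    q: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))

    def greedy(self) -> Policy:
        return Policy(np.argmax(self.q, axis=1))

    def values(self) -> "ValueVector":
        return ValueVector(self.q.max(axis=1))


@dataclass(frozen=True)
class ValueVector:
    """State values, shape (n_states,)."""

    v: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))


# ---------------------------------------------------------------------------
# Planning and evaluation
# ---------------------------------------------------------------------------


def solve_optimal(
    mdp: TabularMDP,
    planning_gamma: float | None = None,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> tuple[QTable, Policy]:
    """Optimal Q and greedy policy by value iteration under ``planning_gamma``.

    ``planning_gamma`` defaults to the MDP's true discount; passing a lower
    value performs discount regularization.  Stops when the sup-norm Bellman
    residual falls below ``tol``; ties in the greedy policy break toward the
    lowest action index.
    """
    g = mdp.gamma if planning_gamma is None else float(planning_gamma)
    if not 0.0 <= g < 1.0:
        raise ValueError("planning_gamma must lie in [0, 1)")
    if tol <= 0:
        raise ValueError("tol must be positive")
    r, t = mdp.rewards, mdp.transitions
    q = np.zeros_like(r)
    for _ in range(max_iter):
        v = q.max(axis=1)
        q_new = r + g * (t @ v)
        residual = float(np.abs(q_new - q).max())
        q = q_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(residual, max_iter)
    table = QTable(q)
    return table, table.greedy()


def evaluate_policy(
    mdp: TabularMDP, policy: Policy, eval_gamma: float | None = None
) -> ValueVector:
    """Exact value of ``policy``: direct solve of V = R_π + γ T_π V."""
    policy.validate_for(mdp)
    g = mdp.gamma if eval_gamma is None else float(eval_gamma)
    if not 0.0 <= g < 1.0:
        raise ValueError("eval_gamma must lie in [0, 1)")
    idx = np.arange(mdp.n_states)
    r_pi = mdp.rewards[idx, policy.actions]
    t_pi = mdp.transitions[idx, policy.actions]
    v = np.linalg.solve(np.eye(mdp.n_states) - g * t_pi, r_pi)
    return ValueVector(v)


def policy_loss(true_mdp: TabularMDP, candidate: Policy) -> float:
    """Mean over states of V^{π*}(s) − V^{candidate}(s) in the true MDP.

    Both policies are evaluated exactly in ``true_mdp`` under its true
    discount; the result is nonnegative up to solver tolerance.
    """
    _, pi_star = solve_optimal(true_mdp)
    v_star = evaluate_policy(true_mdp, pi_star).v
    v_cand = evaluate_policy(true_mdp, candidate).v
    return float(np.mean(v_star - v_cand))


# ---------------------------------------------------------------------------
# λ-returns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LambdaReturnInput:
    """Reward/value sequences and (γ, λ) for a truncated λ-return.

    ``rewards[k]`` is R_{t+k+1} and ``values[k]`` is V^π(S_{t+k+1}); the
    return is truncated after ``horizon`` terms of each geometric sum.
    """

    rewards: Sequence[float]
    values: Sequence[float]
    gamma: float
    lam: float
    horizon: int = field(default=0)

    def __post_init__(self):
        r = np.asarray(self.rewards, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "rewards", r)
        object.__setattr__(self, "values", v)
        h = self.horizon if self.horizon > 0 else len(r)
        object.__setattr__(self, "horizon", h)
        if len(r) != len(v):
            raise ValueError("rewards and values must have equal length")
        if h > len(r):
            raise ValueError("horizon exceeds sequence length")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")


def lambda_return(inp: LambdaReturnInput) -> tuple[float, float, float]:
    """Decompose the λ-return into a truncated discounted sum plus bias.

    Returns ``(full, truncated, bias)`` where::

        truncated = Σ_{k<H} (γλ)^k R_{t+k+1}
        bias      = (1−λ) γ Σ_{k<H} (γλ)^k V^π(S_{t+k+1})
        full      = truncated + bias

    ``truncated`` is exactly the return computed under discount
    regularization with planning discount γp = γλ; ``bias`` is what that
    approximation discards.  ``full`` equals the definitional λ-return
    (the (1−λ)-weighted average of k-step returns) up to the geometric
    truncation tail.
    """
    h = inp.horizon
    w = (inp.gamma * inp.lam) ** np.arange(h)
    truncated = float(w @ inp.rewards[:h])
    bias = float((1.0 - inp.lam) * inp.gamma * (w @ inp.values[:h]))
    return truncated + bias, truncated, bias


def discount_regularized_return(rewards: Sequence[float], gamma_p: float) -> float:
    """Truncated discounted return Σ_k γp^k R_{t+k+1}.

    Equals the ``truncated`` component of :func:`lambda_return` when
    γp = γλ.
    """
    if not 0.0 <= gamma_p < 1.0:
        raise ValueError("gamma_p must lie in [0, 1)")
    r = np.asarray(rewards, dtype=float)
    return float((gamma_p ** np.arange(len(r))) @ r)
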