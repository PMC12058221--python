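"""Model-based regularizers for certainty-equivalence planning.

Planning with a lowered discount γp < γ (discount regularization) produces
the same optimal policy as planning at the true γ with every transition row
shrunk toward a single shared row v with weight ε = (γ − γp)/γ.  That shared
row can in turn be read as the mean of a Dirichlet prior whose magnitude
grows with the per-pair data count n(s,a) — so discount regularization
regularizes *more* where there is *more* data.  This module implements the
whole family:

* the ε ↔ (γ, γp) mapping and the implied Dirichlet prior magnitude;
* weighted-average transition shrinkage with global or per-(s,a) ε;
* the per-row bias/variance MSE of the shrunk estimator (uniform target)
  and its closed-form minimizer ε* = K/(K + n),
  K = Σ_k T_k(1−T_k) / Σ_k (1/Ns − T_k)²,
  with the conventions ε* = 0 for a deterministic row (no variance to
  remove) and ε* = 1 for a uniform row or an unobserved pair;
* plug-in / oracle / posterior-sampling estimators of ε* from count data;
* the planner dispatch that turns counts + a regularization spec into a
  certainty-equivalence policy;
* a machine check of the discount ↔ weighted-average policy equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import minimize_scalar

from .estimation import CountTensor, DirichletPrior, dirichlet_posterior_mean, mle_transition
from .mdp_core import Policy, TabularMDP, solve_optimal

__all__ = [
    "RegularizationSpec",
    "EpsilonStarReport",
    "epsilon_from_gammas",
    "prior_magnitude_from_counts",
    "weighted_average_transition",
    "row_mse",
    "epsilon_star_row",
    "epsilon_star_from_data",
    "regularized_policy",
    "verify_theorem1",
]

Method = Literal["discount", "weighted_average", "dirichlet_prior", "sa_specific"]
EpsSource = Literal["oracle_T", "mle_plugin", "posterior_sample"]


@dataclass
class RegularizationSpec:
    """Which regularizer to apply and its parameters.

    method='discount' plans under ``gamma_p``; the other methods plan under
    the true γ with a modified transition estimate.  ``epsilon`` may be a
    scalar or a per-(s,a) matrix; ``t_reg_row`` is the shared regularization
    row (default uniform), optionally per-action as an (Na, Ns) matrix.
    """

    method: Method = "discount"
    gamma_p: float | None = None
    epsilon: float | np.ndarray | None = None
    t_reg_row: np.ndarray | None = None
    prior: DirichletPrior | None = None
    eps_source: EpsSource = "mle_plugin"
    n_samples: int = 50
    rng_seed: int = 0

    def resolved_t_reg(self, n_states: int, n_actions: int) -> np.ndarray:
        """The regularization row(s) broadcast to shape (Na, Ns)."""
        if self.t_reg_row is None:
            row = np.full((n_actions, n_states), 1.0 / n_states)
            return row
        row = np.asarray(self.t_reg_row, dtype=float)
        if row.ndim == 1:
            row = np.tile(row, (n_actions, 1))
        if row.shape != (n_actions, n_states):
            raise ValueError("t_reg_row must be a length-Ns row or an (Na, Ns) matrix")
        if np.any(row < 0) or not np.allclose(row.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("regularization rows must be probability vectors")
        return row


@dataclass(frozen=True)
class EpsilonStarReport:
    """Per-(s,a) ε* values with the K statistics and counts behind them."""

    epsilon_star: np.ndarray
    k_values: np.ndarray
    n_values: np.ndarray
    source: str

    def __post_init__(self):
        e = np.asarray(self.epsilon_star, dtype=float)
        if np.any(e < -1e-12) or np.any(e > 1 + 1e-12):
            raise ValueError("epsilon_star entries must lie in [0, 1]")
        object.__setattr__(self, "epsilon_star", np.clip(e, 0.0, 1.0))


# ---------------------------------------------------------------------------
# The discount <-> shrinkage <-> prior mappings
# ---------------------------------------------------------------------------


def epsilon_from_gammas(gamma: float, gamma_p: float) -> float:
    """Shrinkage weight ε = (γ − γp)/γ implied by a planning discount γp."""
    if gamma <= 0:
        raise ValueError("epsilon is undefined at gamma = 0")
    if not 0.0 <= gamma_p <= gamma < 1.0:
        raise ValueError("require 0 <= gamma_p <= gamma < 1")
    return (gamma - gamma_p) / gamma


def prior_magnitude_from_counts(
    gamma: float, gamma_p: float, counts: CountTensor, n_states: int | None = None
) -> DirichletPrior:
    """The uniform Dirichlet prior equivalent to discount regularization.

    Per pair, the total prior magnitude is Σ_k α = ((γ − γp)/γp)·n(s,a),
    split uniformly across next states.  Planning with the posterior mean
    of this prior at the true γ reproduces the discount-regularized policy
    exactly (the ε implied by the prior is then (γ − γp)/γ for every pair).
    The magnitude grows with n(s,a): pairs with more data are shrunk more.
    """
    if gamma_p <= 0:
        raise ValueError(
            "gamma_p = 0 implies an infinite-magnitude prior (the contextual-"
            "bandit limit ignores the future entirely); no finite Dirichlet "
            "prior reproduces it"
        )
    if not gamma_p <= gamma < 1.0:
        raise ValueError("require 0 < gamma_p <= gamma < 1")
    ns = counts.counts.shape[2] if n_states is None else int(n_states)
    total = (gamma - gamma_p) / gamma_p * counts.n_sa.astype(float)
    alpha = np.repeat(total[:, :, None] / ns, ns, axis=2)
    return DirichletPrior(alpha)


def weighted_average_transition(t_hat: np.ndarray, spec: RegularizationSpec) -> np.ndarray:
    """Shrink every row of ``t_hat`` toward the spec's regularization row.

    Row (s, a) becomes (1 − ε_{s,a})·t_hat[s,a] + ε_{s,a}·t_reg; ε may be a
    scalar or an (Ns, Na) matrix.
    """
    t_hat = np.asarray(t_hat, dtype=float)
    ns, na, _ = t_hat.shape
    t_reg = spec.resolved_t_reg(ns, na)  # (Na, Ns)
    eps = np.asarray(0.0 if spec.epsilon is None else spec.epsilon, dtype=float)
    if eps.ndim == 0:
        eps = np.full((ns, na), float(eps))
    if eps.shape != (ns, na):
        raise ValueError("epsilon must be scalar or an (Ns, Na) matrix")
    if np.any(eps < 0) or np.any(eps > 1):
        raise ValueError("epsilon entries must lie in [0, 1]")
    return (1.0 - eps)[:, :, None] * t_hat + eps[:, :, None] * t_reg[None, :, :]


# ---------------------------------------------------------------------------
# Row MSE and its minimizer
# ---------------------------------------------------------------------------


def _check_row(t_row: np.ndarray) -> np.ndarray:
    t = np.asarray(t_row, dtype=float)
    if t.ndim != 1 or np.any(t < 0) or abs(t.sum() - 1.0) > 1e-8:
        raise ValueError("t_row must be a probability vector")
    return t


def row_mse(t_row: np.ndarray, n: int, epsilon: float) -> tuple[float, float, float]:
    """Bias²+variance of a uniform-target shrunk empirical row.

    For the estimator (1−ε)·T̂_MLE + ε·uniform with n multinomial draws from
    the true row T::

        variance = (1−ε)² (1/n) Σ_k T_k (1 − T_k)
        bias²    = ε² Σ_k (1/Ns − T_k)²

    Returns ``(mse, variance, bias²)``.
    """
    t = _check_row(t_row)
    ns = len(t)
    if n < 1:
        raise ValueError("the variance term requires n >= 1")
    variance = (1.0 - epsilon) ** 2 * float(np.sum(t * (1.0 - t))) / n
    bias2 = epsilon**2 * float(np.sum((1.0 / ns - t) ** 2))
    return variance + bias2, variance, bias2


def epsilon_star_row(t_row: np.ndarray, n: int) -> float:
    """Closed-form MSE-minimizing shrinkage weight ε* = K/(K + n).

    K = Σ_k T_k(1−T_k) / Σ_k (1/Ns − T_k)².  Conventions: a deterministic
    row has K = 0 hence ε* = 0; a uniform row (zero bias denominator) and
    an unobserved pair (n = 0) both give ε* = 1.
    """
    t = _check_row(t_row)
    ns = len(t)
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n == 0:
        return 1.0
    var_sum = float(np.sum(t * (1.0 - t)))
    bias_sum = float(np.sum((1.0 / ns - t) ** 2))
    if bias_sum == 0.0:
        return 1.0  # uniform row: shrinkage is free of bias
    k = var_sum / bias_sum
    return k / (k + n)


def _posterior_sample_eps(
    c_row: np.ndarray, n: int, rng: np.random.Generator, n_samples: int
) -> float:
    """ε minimizing the average row MSE across Dirichlet(1 + c) samples."""
    rows = rng.dirichlet(1.0 + c_row, size=n_samples)
    ns = rows.shape[1]
    # averaged quadratic coefficients of (1-e)^2 * v/n + e^2 * b
    v = float(np.mean(np.sum(rows * (1.0 - rows), axis=1))) / n
    b = float(np.mean(np.sum((1.0 / ns - rows) ** 2, axis=1)))

    def avg_mse(e: float) -> float:
        return (1.0 - e) ** 2 * v + e**2 * b

    grid = np.linspace(0.0, 1.0, 1001)
    best = grid[np.argmin((1.0 - grid) ** 2 * v + grid**2 * b)]
    lo, hi = max(0.0, best - 1e-3), min(1.0, best + 1e-3)
    res = minimize_scalar(avg_mse, bounds=(lo, hi), method="bounded")
    return float(np.clip(res.x, 0.0, 1.0))


def epsilon_star_from_data(
    counts: CountTensor,
    mode: EpsSource = "mle_plugin",
    true_T: np.ndarray | None = None,
    n_samples: int = 50,
    rng_seed: int = 0,
) -> EpsilonStarReport:
    """Per-(s,a) ε* estimated from count data.

    mode='oracle_T' evaluates the closed form at the true transition rows
    (data counts still supply n); 'mle_plugin' evaluates it at the MLE rows;
    'posterior_sample' draws ``n_samples`` rows from the Dirichlet(1 + c)
    posterior per pair and minimizes the sample-averaged MSE.  Unobserved
    pairs get ε* = 1 in every mode.
    """
    c = counts.counts
    ns, na, _ = c.shape
    n_sa = counts.n_sa
    if mode == "oracle_T":
        if true_T is None:
            raise ValueError("oracle_T mode requires true_T")
        rows = np.asarray(true_T, dtype=float)
    elif mode == "mle_plugin":
        rows = mle_transition(counts)
    elif mode == "posterior_sample":
        rows = None
    else:
        raise ValueError(f"unknown epsilon-star mode {mode!r}")

    eps = np.empty((ns, na))
    kmat = np.full((ns, na), np.nan)
    rng = np.random.default_rng(rng_seed)
    for i in range(ns):
        for j in range(na):
            n = int(n_sa[i, j])
            if n == 0:
                eps[i, j] = 1.0
                continue
            if mode == "posterior_sample":
                eps[i, j] = _posterior_sample_eps(c[i, j].astype(float), n, rng, n_samples)
            else:
                t = rows[i, j]
                eps[i, j] = epsilon_star_row(t, n)
                bias_sum = float(np.sum((1.0 / ns - t) ** 2))
                if bias_sum > 0:
                    kmat[i, j] = float(np.sum(t * (1.0 - t))) / bias_sum
    return EpsilonStarReport(eps, kmat, n_sa.copy(), mode)


# ---------------------------------------------------------------------------
# Certainty-equivalence planning with regularization
# ---------------------------------------------------------------------------


def regularized_policy(
    counts: CountTensor,
    rewards: np.ndarray,
    gamma: float,
    spec: RegularizationSpec,
    true_T: np.ndarray | None = None,
    tol: float = 1e-10,
) -> Policy:
    """Certainty-equivalence optimal policy under the requested regularizer.

    'discount' plans on the MLE model under γp; 'weighted_average' shrinks
    the MLE rows by the spec's ε; 'dirichlet_prior' plans on the posterior
    mean; 'sa_specific' computes per-pair ε* (per ``spec.eps_source``) and
    shrinks with it.  All but 'discount' plan under the true γ.
    """
    rewards = np.asarray(rewards, dtype=float)
    t_mle = mle_transition(counts)
    if spec.method == "discount":
        if spec.gamma_p is None:
            raise ValueError("discount method requires gamma_p")
        mdp = TabularMDP(rewards, t_mle, gamma)
        _, pi = solve_optimal(mdp, planning_gamma=spec.gamma_p, tol=tol)
        return pi
    if spec.method == "weighted_average":
        t = weighted_average_transition(t_mle, spec)
    elif spec.method == "dirichlet_prior":
        if spec.prior is None:
            raise ValueError("dirichlet_prior method requires a prior")
        t = dirichlet_posterior_mean(counts, spec.prior)
    elif spec.method == "sa_specific":
        report = epsilon_star_from_data(
            counts,
            mode=spec.eps_source,
            true_T=true_T,
            n_samples=spec.n_samples,
            rng_seed=spec.rng_seed,
        )
        sa_spec = RegularizationSpec(
            method="weighted_average",
            epsilon=report.epsilon_star,
            t_reg_row=spec.t_reg_row,
        )
        t = weighted_average_transition(t_mle, sa_spec)
    else:
        raise ValueError(f"unknown regularization method {spec.method!r}")
    mdp = TabularMDP(rewards, t, gamma)
    _, pi = solve_optimal(mdp, tol=tol)
    return pi


# ---------------------------------------------------------------------------
# Equivalence check
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TheoremReport:
    """Outcome of a policy-equivalence check, with any Q-gap disagreements."""

    equivalent: bool
    disagreements: list = field(default_factory=list)


def verify_theorem1(
    mdp: TabularMDP,
    epsilon: float,
    t_reg_row: np.ndarray | None = None,
    tol: float = 1e-8,
) -> TheoremReport:
    """Check that discount and shared-row shrinkage planning agree.

    Compares the greedy policies of (T, γ(1−ε)) and ((1−ε)T + εT_reg, γ)
    where T_reg repeats one shared row for every (s, a).  States whose
    actions differ are counted as disagreement only when the Q-gap of the
    swap exceeds ``tol`` (numerical ties are accepted).
    """
    if not 0.0 < epsilon <= 1.0:
        raise ValueError("epsilon must lie in (0, 1]")
    spec = RegularizationSpec(method="weighted_average", epsilon=epsilon, t_reg_row=t_reg_row)
    t_mix = weighted_average_transition(mdp.transitions, spec)
    q1, pi1 = solve_optimal(mdp, planning_gamma=mdp.gamma * (1.0 - epsilon))
    mdp2 = TabularMDP(mdp.rewards, t_mix, mdp.gamma)
    q2, pi2 = solve_optimal(mdp2)
    disagreements = []
    for s in np.nonzero(pi1.actions != pi2.actions)[0]:
        gap1 = q1.q[s, pi1.actions[s]] - q1.q[s, pi2.actions[s]]
        gap2 = q2.q[s, pi2.actions[s]] - q2.q[s, pi1.actions[s]]
        gap = max(abs(gap1), abs(gap2))
        if gap > tol:
            disagreements.append((int(s), int(pi1.actions[s]), int(pi2.actions[s]), float(gap)))
    return TheoremReport(equivalent=not disagreements, disagreements=disagreements)
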