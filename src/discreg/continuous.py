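"""Continuous-state regularized fitted value iteration.

The tabular machinery extends to a one-dimensional continuous state space
by modeling only the *expected* next state with per-action Nadaraya–Watson
kernel regression, then planning by fitted value iteration (FVI) with the
same weighted-average backup used in the tabular model-free case:

    Q(s, a) = R(s, a) + γ(1 − ε*(s,a)) V(ŝ'(s,a)) + γ ε*(s,a) · mean_n V(s_n)

The per-(state, action) weight comes from the kernel-regression error bars:

    ε*(s, a) = se²(s, a) / ((T_reg_mean − T̂_NW(s, a))² + se²(s, a))

where se is the standard error of the kernel estimate at s and T_reg_mean
the mean of the chosen regularization transition distribution (0.5 for the
uniform distribution on [0, 1]).  Where the kernel estimate is noisy the
backup leans on the global mean value; where it is precise and far from
the regularization mean it trusts the data.

The noise scale σ̂ per action is estimated from first differences of the
next states after ordering by current state:
σ̂² = (1/(2(n−1))) Σ_d (s'_{d+1} − s'_d)².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Protocol

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor

from .environments import ContinuousSimulator

__all__ = [
    "ContinuousDataset",
    "KernelTransitionModel",
    "ValueModel",
    "ExtraTreesValueModel",
    "sample_continuous_dataset",
    "fit_kernel_model",
    "nw_predict_with_se",
    "epsilon_star_continuous",
    "fvi_regularized",
]

SEForm = Literal["kernel_norm", "kernel_sum"]


@dataclass(frozen=True)
class ContinuousDataset:
    """Batch of (s, a, s') tuples on a bounded one-dimensional state space."""

    states: np.ndarray
    actions: np.ndarray
    next_states: np.ndarray
    seed: int = -1
    bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        object.__setattr__(self, "states", np.asarray(self.states, dtype=float))
        object.__setattr__(self, "actions", np.asarray(self.actions, dtype=int))
        object.__setattr__(self, "next_states", np.asarray(self.next_states, dtype=float))
        lo, hi = self.bounds
        for arr in (self.states, self.next_states):
            if len(arr) and (arr.min() < lo - 1e-12 or arr.max() > hi + 1e-12):
                raise ValueError("states fall outside the declared bounds")

    def __len__(self) -> int:
        return len(self.states)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"state": self.states, "action": self.actions, "next_state": self.next_states}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, bounds=(0.0, 1.0)) -> "ContinuousDataset":
        df = pd.read_csv(path)
        return cls(
            df["state"].to_numpy(), df["action"].to_numpy(), df["next_state"].to_numpy(),
            bounds=bounds,
        )


def sample_continuous_dataset(
    sim: ContinuousSimulator, n_tuples: int, rng_seed: int = 0, replicate: int = 0
) -> ContinuousDataset:
    """Sample (s, a, s') tuples with s uniform on the state space and a uniform."""
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), int(replicate)]))
    lo, hi = sim.bounds
    s = rng.uniform(lo, hi, size=n_tuples)
    a = rng.integers(0, sim.n_actions, size=n_tuples)
    sp = np.empty(n_tuples)
    for k in range(sim.n_actions):
        mask = a == k
        sp[mask] = sim.step_fn(s[mask], k, rng)
    return ContinuousDataset(s, a, sp, seed=rng_seed, bounds=sim.bounds)


# ---------------------------------------------------------------------------
# Kernel transition model
# ---------------------------------------------------------------------------


@dataclass
class KernelTransitionModel:
    """Per-action kernel-regression model of expected next state.

    ``s[a]``/``s_next[a]`` hold the action-a data ordered by current state;
    ``sigma_hat[a]`` is the first-difference noise estimate and
    ``bandwidth[a]`` the Gaussian kernel bandwidth.  ``t_reg_mean`` is the
    mean of the regularization transition distribution.  ``se_form``
    selects the standard-error expression: 'kernel_norm' (default) uses
    σ̂·sqrt(ΣK_i²)/(ΣK_j), the effective-kernel ℓ2-norm form; 'kernel_sum'
    uses σ̂·(ΣK_i)/(ΣK_j)² read literally from the alternative layout.
    """

    s: dict = field(default_factory=dict)
    s_next: dict = field(default_factory=dict)
    sigma_hat: dict = field(default_factory=dict)
    bandwidth: dict = field(default_factory=dict)
    t_reg_mean: float = 0.5
    se_form: SEForm = "kernel_norm"

    @property
    def actions(self) -> list[int]:
        return sorted(self.s)


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    std = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(std, iqr / 1.34) if iqr > 0 else std
    if scale <= 0:
        scale = max(abs(float(np.mean(x))), 1.0) * 1e-2
    return 0.9 * scale * n ** (-1.0 / 5.0)


def _loocv_bandwidth(s: np.ndarray, sp: np.ndarray) -> float:
    """Leave-one-out cross-validated Gaussian bandwidth for NW regression.

    Minimizes the leave-one-out squared prediction error over a geometric
    grid from roughly the data spacing up to the sample range.  Regression
    bandwidths must track the scale of the *regression function*, not the
    covariate density; density-style rules (Silverman) oversmooth
    transition maps whose drift per step is much smaller than the state
    range, which flattens the planning dynamics for every downstream
    method.
    """
    n = len(s)
    span = float(s.max() - s.min())
    if span <= 0:
        return 1.0
    lo = max(span / n, 1e-4)
    grid = np.geomspace(lo, span, 25)
    d2 = (s[:, None] - s[None, :]) ** 2
    best_h, best_j = grid[-1], np.inf
    for h in grid:
        w = np.exp(-0.5 * d2 / h**2)
        np.fill_diagonal(w, 0.0)
        sw = w.sum(axis=1)
        if np.any(sw <= 0):
            continue
        j = float(np.mean((sp - (w @ sp) / sw) ** 2))
        if j < best_j:
            best_j, best_h = j, float(h)
    return best_h


def fit_kernel_model(
    ds: ContinuousDataset,
    bandwidth_rule: str | float = "loocv",
    t_reg_mean: float = 0.5,
    se_form: SEForm = "kernel_norm",
) -> KernelTransitionModel:
    """Fit per-action Nadaraya–Watson models with noise estimates.

    ``bandwidth_rule`` is 'loocv' (leave-one-out cross-validation, the
    default), 'silverman', or a fixed positive number applied to every
    action.  Each action needs at least two tuples (the noise estimate
    uses first differences).
    """
    model = KernelTransitionModel(t_reg_mean=t_reg_mean, se_form=se_form)
    for a in np.unique(ds.actions):
        mask = ds.actions == a
        s, sp = ds.states[mask], ds.next_states[mask]
        if len(s) < 2:
            raise ValueError(f"action {int(a)} has fewer than 2 tuples; cannot fit")
        order = np.argsort(s, kind="stable")
        s, sp = s[order], sp[order]
        n = len(s)
        sigma2 = float(np.sum(np.diff(sp) ** 2)) / (2.0 * (n - 1))
        if isinstance(bandwidth_rule, str):
            if bandwidth_rule == "loocv":
                h = _loocv_bandwidth(s, sp)
            elif bandwidth_rule == "silverman":
                h = _silverman_bandwidth(s)
            else:
                raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
        else:
            h = float(bandwidth_rule)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
        a = int(a)
        model.s[a], model.s_next[a] = s, sp
        model.sigma_hat[a] = float(np.sqrt(sigma2))
        model.bandwidth[a] = h
    return model


def _kernel_weights(model: KernelTransitionModel, s, a: int) -> np.ndarray:
    if a not in model.s:
        raise ValueError(f"model was not fit for action {a}")
    s = np.atleast_1d(np.asarray(s, dtype=float))
    h = model.bandwidth[a]
    z = (s[:, None] - model.s[a][None, :]) / h
    return np.exp(-0.5 * z**2)


def nw_predict_with_se(
    model: KernelTransitionModel, s, a: int
) -> tuple[np.ndarray, np.ndarray]:
    """Nadaraya–Watson expected next state and its standard error at s.

    Vectorized over query points; scalars in give scalars out.  Raises if
    all kernel weights underflow to zero at some query point (the
    bandwidth is too small for the data spacing).
    """
    scalar = np.isscalar(s) or np.ndim(s) == 0
    w = _kernel_weights(model, s, a)
    sw = w.sum(axis=1)
    if np.any(sw <= 0.0):
        raise FloatingPointError(
            "all kernel weights underflow to zero at a query point; "
            "increase the bandwidth"
        )
    mean = (w @ model.s_next[a]) / sw
    sigma = model.sigma_hat[a]
    if model.se_form == "kernel_norm":
        se = sigma * np.sqrt((w**2).sum(axis=1)) / sw
    else:  # kernel_sum: literal alternative reading
        se = sigma * sw / sw**2
    if scalar:
        return float(mean[0]), float(se[0])
    return mean, se


def epsilon_star_continuous(model: KernelTransitionModel, s, a: int):
    """Per-(state, action) shrinkage weight se²/((T_reg_mean − T̂_NW)² + se²).

    Equals 0 where the estimate is exact (se = 0) and disagrees with the
    regularization mean, 1 where the estimate matches the regularization
    mean, and 1 by convention when both se = 0 and the gap is 0.
    """
    scalar = np.isscalar(s) or np.ndim(s) == 0
    mean, se = nw_predict_with_se(model, np.atleast_1d(s), a)
    gap2 = (model.t_reg_mean - mean) ** 2
    se2 = np.asarray(se) ** 2
    denom = gap2 + se2
    eps = np.where(denom > 0, np.divide(se2, np.where(denom > 0, denom, 1.0)), 1.0)
    if scalar:
        return float(eps[0])
    return eps


# ---------------------------------------------------------------------------
# Value models
# ---------------------------------------------------------------------------


class ValueModel(Protocol):
    """Regression model for the state-value function: fit then predict."""

    def fit(self, states: np.ndarray, targets: np.ndarray) -> None: ...

    def predict(self, states: np.ndarray) -> np.ndarray: ...


class ExtraTreesValueModel:
    """Randomized-tree ensemble value model (default FVI regressor)."""

    def __init__(self, n_estimators: int = 50, random_state: int = 0, **kwargs):
        self._kwargs = dict(n_estimators=n_estimators, random_state=random_state, **kwargs)
        self._est: ExtraTreesRegressor | None = None

    def fit(self, states: np.ndarray, targets: np.ndarray) -> None:
        self._est = ExtraTreesRegressor(**self._kwargs)
        self._est.fit(np.asarray(states, dtype=float).reshape(-1, 1), np.asarray(targets))

    def predict(self, states: np.ndarray) -> np.ndarray:
        if self._est is None:
            raise RuntimeError("value model has not been fit")
        return self._est.predict(np.asarray(states, dtype=float).reshape(-1, 1))


# ---------------------------------------------------------------------------
# Regularized fitted value iteration
# ---------------------------------------------------------------------------


def fvi_regularized(
    ds: ContinuousDataset,
    reward_fn: Callable[[np.ndarray], np.ndarray],
    gamma: float,
    n_actions: int = 2,
    n_sample_states: int = 200,
    n_iterations: int = 50,
    value_model: ValueModel | None = None,
    mode: Literal["sa_specific", "global"] = "sa_specific",
    epsilon_global: float = 0.0,
    rng_seed: int = 0,
    bandwidth_rule: str | float = "loocv",
    t_reg_mean: float = 0.5,
    state_sampling: Literal["grid", "uniform"] = "grid",
) -> tuple[ValueModel, Callable[[np.ndarray], np.ndarray]]:
    """Fitted value iteration with the weighted-average regularized backup.

    Samples ``n_sample_states`` support states (a deterministic uniform
    grid by default, or seeded uniform draws), fits the per-action kernel
    transition model, precomputes the predicted next state and ε* for every
    (support state, action) pair once, then iterates the backup

        Q(s_n, a_k) = R(s_n) + γ(1−ε*) V(ŝ'_{n,k}) + γ ε* · mean_n' V(s_n')

    refitting ``value_model`` on (s_n, max_k Q) each iteration.  In
    ``mode='global'`` the fixed ``epsilon_global`` replaces ε* everywhere,
    which reproduces discount regularization at γp = γ(1−ε).

    ``reward_fn`` maps an array of states to state rewards (shared across
    actions).  Returns the fitted value model and a greedy policy function
    mapping an array of states to action indices.
    """
    if not 0.0 <= epsilon_global <= 1.0:
        raise ValueError("epsilon_global must lie in [0, 1]")
    lo, hi = ds.bounds
    rng = np.random.default_rng(rng_seed)
    if state_sampling == "grid":
        support = np.linspace(lo, hi, n_sample_states)
    elif state_sampling == "uniform":
        support = np.sort(rng.uniform(lo, hi, size=n_sample_states))
    else:
        raise ValueError(f"unknown state_sampling {state_sampling!r}")

    model = fit_kernel_model(ds, bandwidth_rule=bandwidth_rule, t_reg_mean=t_reg_mean)
    if value_model is None:
        value_model = ExtraTreesValueModel(random_state=rng_seed)

    # Alg. line 4-5: next states and epsilons computed once, before iterating
    next_state = np.empty((n_sample_states, n_actions))
    eps = np.empty((n_sample_states, n_actions))
    for a in range(n_actions):
        mean, _ = nw_predict_with_se(model, support, a)
        next_state[:, a] = np.clip(mean, lo, hi)
        if mode == "sa_specific":
            eps[:, a] = epsilon_star_continuous(model, support, a)
        elif mode == "global":
            eps[:, a] = epsilon_global
        else:
            raise ValueError(f"unknown mode {mode!r}")

    r = np.asarray(reward_fn(support), dtype=float)
    v_support = np.zeros(n_sample_states)
    v_next = np.zeros((n_sample_states, n_actions))
    for it in range(n_iterations):
        v_avg = float(v_support.mean())
        q = r[:, None] + gamma * (1.0 - eps) * v_next + gamma * eps * v_avg
        targets = q.max(axis=1)
        if not np.all(np.isfinite(targets)):
            raise FloatingPointError(
                f"non-finite value targets at iteration {it}; "
                "check rewards and the value model"
            )
        value_model.fit(support, targets)
        v_support = value_model.predict(support)
        for a in range(n_actions):
            v_next[:, a] = value_model.predict(next_state[:, a])

    v_avg_final = float(v_support.mean())

    def greedy_policy(s: np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        q = np.empty((len(s), n_actions))
        r_s = np.asarray(reward_fn(s), dtype=float)
        for a in range(n_actions):
            mean, _ = nw_predict_with_se(model, s, a)
            if mode == "sa_specific":
                e = epsilon_star_continuous(model, s, a)
            else:
                e = epsilon_global
            v_n = value_model.predict(np.clip(mean, lo, hi))
            q[:, a] = r_s + gamma * (1.0 - e) * v_n + gamma * e * v_avg_final
        return np.argmax(q, axis=1)

    return value_model, greedy_policy
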