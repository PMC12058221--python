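"""Replicated regularizer sweeps and loss aggregation.

The evaluation harness repeats, per replicate: (re)sample the environment
where it is a distribution over MDPs, sample one batch dataset (shared by
all methods so curves are paired), fit and regularize per method and
regularization strength, and score each resulting certainty-equivalence
policy with the policy-loss metric — the mean over states of the value gap
to the true optimal policy, evaluated in the true environment under the
true discount.  Global methods trace a loss curve over the ε grid;
state-action-specific methods contribute a single parameter-free loss.

Method names accepted in ``SweepConfig.methods``:

* ``discount`` — plan the MLE model at γp = γ(1−ε) for each grid ε;
* ``uniform_prior`` — posterior mean of a uniform Dirichlet prior whose
  magnitude is constant across pairs, matched to grid ε through the mean
  per-pair count (Σα = ε·n̄/(1−ε));
* ``weighted_average`` — shrink every MLE row by the shared grid ε;
* ``sa_specific`` / ``sa_oracle`` — per-pair ε* from the posterior-sampled
  (resp. true-T oracle) row-MSE minimizer, one loss per replicate;
* ``fqi_discount`` / ``fqi_weighted_average`` — FQI at γ(1−ε) resp. the
  weighted-average update at γ, per grid ε;
* ``fqi_sa_sse`` / ``fqi_sa_multinomial`` — FQI with per-pair ε refreshed
  each iteration, one loss per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .continuous import fvi_regularized, sample_continuous_dataset
from .environments import (
    ContinuousSimulator,
    EnvParams,
    discretize_continuous,
    make_environment,
)
from .estimation import count_transitions, mle_transition, sample_dataset
from .mdp_core import Policy, TabularMDP, evaluate_policy, solve_optimal
from .model_based_reg import DirichletPrior, RegularizationSpec, regularized_policy
from .model_free_reg import FQIConfig, fqi_regularized

__all__ = ["SweepConfig", "SweepResult", "run_sweep", "run_continuous_sweep", "summarize"]

TABULAR_METHODS = (
    "discount",
    "uniform_prior",
    "weighted_average",
    "sa_specific",
    "sa_oracle",
    "fqi_discount",
    "fqi_weighted_average",
    "fqi_sa_sse",
    "fqi_sa_multinomial",
)
GRID_METHODS = ("discount", "uniform_prior", "weighted_average", "fqi_discount", "fqi_weighted_average")


@dataclass
class SweepConfig:
    """Full specification of a replicated sweep."""

    environment: EnvParams
    n_replicates: int = 200
    data_scheme: str = "uniform_sa"
    data_size: int | tuple = 100
    methods: tuple = ("discount", "uniform_prior", "sa_specific")
    epsilon_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.linspace(0.0, 0.9, 10), 10)
    )
    master_seed: int = 0
    resample_env: bool = True
    fqi_iterations: int = 100
    on_error: str = "fatal"  # or "skip"

    def __post_init__(self):
        self.epsilon_grid = np.asarray(self.epsilon_grid, dtype=float)
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if np.any(self.epsilon_grid < 0) or np.any(self.epsilon_grid >= 1):
            raise ValueError("epsilon grid values must lie in [0, 1)")
        unknown = set(self.methods) - set(TABULAR_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SweepConfig":
        raw = yaml.safe_load(Path(path).read_text())
        env = EnvParams(**raw.pop("environment"))
        if "epsilon_grid" in raw:
            raw["epsilon_grid"] = np.asarray(raw["epsilon_grid"], dtype=float)
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(environment=env, **raw)


@dataclass
class SweepResult:
    """Long-format per-replicate losses; NaN param marks parameter-free methods."""

    frame: pd.DataFrame
    failures: list = field(default_factory=list)

    def aggregates(self) -> pd.DataFrame:
        return summarize(self)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def _matched_prior_magnitude(n_sa: np.ndarray, eps: float) -> float:
    """Constant prior magnitude whose average shrinkage equals the grid ε.

    The per-pair shrinkage A/(n(s,a) + A) is convex in the count, so fixing
    A from the mean count alone would over-regularize relative to the
    discount curve at the same nominal ε.  Instead A solves
    mean over observed pairs of A/(n + A) = ε, making the two curves
    comparable point by point at equal average strength.
    """
    from scipy.optimize import brentq

    n = n_sa[n_sa > 0].astype(float)
    if len(n) == 0:
        raise ValueError("cannot match a prior magnitude with no observed pairs")

    def gap(a: float) -> float:
        return float(np.mean(a / (n + a))) - eps

    hi = 1.0
    while gap(hi) < 0:
        hi *= 10.0
        if hi > 1e12:
            break
    return float(brentq(gap, 0.0, hi))


def _child_seed(master: int, *idx: int) -> int:
    ss = np.random.SeedSequence([int(master), *map(int, idx)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _losses_for_replicate(
    cfg: SweepConfig, mdp: TabularMDP, replicate: int
) -> list[tuple[str, float, float]]:
    ds = sample_dataset(
        mdp, scheme=cfg.data_scheme, size_spec=cfg.data_size,
        rng_seed=cfg.master_seed, replicate=replicate,
    )
    counts = count_transitions(ds, mdp.n_states, mdp.n_actions)
    gamma = mdp.gamma
    n_bar = max(counts.total / (mdp.n_states * mdp.n_actions), 1e-12)

    # value of the true optimal policy, shared across methods
    _, pi_star = solve_optimal(mdp)
    v_star = evaluate_policy(mdp, pi_star).v

    def loss(policy: Policy) -> float:
        return float(np.mean(v_star - evaluate_policy(mdp, policy).v))

    def fqi_loss(gamma_plan: float, mode: str, eps_global: float = 0.0) -> float:
        fcfg = FQIConfig(
            gamma=gamma_plan,
            n_iterations=cfg.fqi_iterations,
            epsilon_mode=mode,
            epsilon_global=eps_global,
            rng_seed=_child_seed(cfg.master_seed, replicate, 7),
        )
        _, pi, _ = fqi_regularized(ds, mdp.rewards, fcfg)
        return loss(pi)

    out: list[tuple[str, float, float]] = []
    for method in cfg.methods:
        if method == "discount":
            for eps in cfg.epsilon_grid:
                spec = RegularizationSpec(method="discount", gamma_p=gamma * (1.0 - eps))
                out.append((method, eps, loss(regularized_policy(counts, mdp.rewards, gamma, spec))))
        elif method == "uniform_prior":
            for eps in cfg.epsilon_grid:
                if eps == 0.0:
                    spec = RegularizationSpec(method="weighted_average", epsilon=0.0)
                else:
                    mag = _matched_prior_magnitude(counts.n_sa, eps)
                    spec = RegularizationSpec(
                        method="dirichlet_prior",
                        prior=DirichletPrior(mag / mdp.n_states),
                    )
                out.append((method, eps, loss(regularized_policy(counts, mdp.rewards, gamma, spec))))
        elif method == "weighted_average":
            for eps in cfg.epsilon_grid:
                spec = RegularizationSpec(method="weighted_average", epsilon=eps)
                out.append((method, eps, loss(regularized_policy(counts, mdp.rewards, gamma, spec))))
        elif method in ("sa_specific", "sa_oracle"):
            spec = RegularizationSpec(
                method="sa_specific",
                eps_source="posterior_sample" if method == "sa_specific" else "oracle_T",
                rng_seed=_child_seed(cfg.master_seed, replicate, 3),
            )
            pi = regularized_policy(counts, mdp.rewards, gamma, spec, true_T=mdp.transitions)
            out.append((method, np.nan, loss(pi)))
        elif method == "fqi_discount":
            for eps in cfg.epsilon_grid:
                out.append((method, eps, fqi_loss(gamma * (1.0 - eps), "global", 0.0)))
        elif method == "fqi_weighted_average":
            for eps in cfg.epsilon_grid:
                out.append((method, eps, fqi_loss(gamma, "global", eps)))
        elif method == "fqi_sa_sse":
            out.append((method, np.nan, fqi_loss(gamma, "per_sa_sse")))
        elif method == "fqi_sa_multinomial":
            out.append((method, np.nan, fqi_loss(gamma, "per_sa_multinomial")))
    return out


def run_sweep(cfg: SweepConfig, progress: bool = False) -> SweepResult:
    """Run the full replicated sweep; fully reproducible from master_seed."""
    env = make_environment(cfg.environment)
    if isinstance(env, ContinuousSimulator):
        raise TypeError("use run_continuous_sweep for continuous environments")
    rows, failures = [], []
    for r in range(cfg.n_replicates):
        if cfg.resample_env and cfg.environment.name in ("random_chain", "gridworld"):
            mdp = make_environment(
                EnvParams(
                    cfg.environment.name,
                    seed=_child_seed(cfg.master_seed, r, 1),
                    overrides=cfg.environment.overrides,
                )
            )
        else:
            mdp = env
        try:
            for method, param, loss_val in _losses_for_replicate(cfg, mdp, r):
                rows.append((method, param, r, loss_val))
        except Exception as exc:  # noqa: BLE001 - per-config failure policy
            if cfg.on_error == "fatal":
                raise
            failures.append((r, repr(exc)))
        if progress:
            import sys

            print(f"replicate {r + 1}/{cfg.n_replicates}", file=sys.stderr)
    frame = pd.DataFrame(rows, columns=["method", "param", "replicate", "loss"])
    return SweepResult(frame, failures)


def run_continuous_sweep(
    sim: ContinuousSimulator,
    n_replicates: int = 100,
    n_tuples: int = 100,
    methods: tuple = ("fvi_unregularized", "fvi_sa_specific"),
    epsilon_grid: np.ndarray | None = None,
    n_sample_states: int = 200,
    n_iterations: int = 50,
    master_seed: int = 0,
    n_eval_bins: int = 201,
) -> SweepResult:
    """Replicated FVI comparison on a continuous-state simulator.

    Policies are scored against a fine uniform discretization of the exact
    dynamics: the greedy policy function is evaluated at the bin centers
    and its exact value in the discretized true MDP is compared with the
    discretized optimum, averaged across bins.  Method names:
    ``fvi_unregularized`` (global ε = 0), ``fvi_global`` (one run per grid
    ε), ``fvi_sa_specific`` (kernel-error-bar ε*).
    """
    eval_mdp = discretize_continuous(sim, n_bins=n_eval_bins)
    _, pi_star = solve_optimal(eval_mdp)
    v_star = evaluate_policy(eval_mdp, pi_star).v
    centers = (np.linspace(*sim.bounds, n_eval_bins + 1)[:-1] + np.linspace(*sim.bounds, n_eval_bins + 1)[1:]) / 2

    def loss_of(policy_fn) -> float:
        pi = Policy(policy_fn(centers))
        return float(np.mean(v_star - evaluate_policy(eval_mdp, pi).v))

    rows = []
    grid = np.asarray([] if epsilon_grid is None else epsilon_grid, dtype=float)
    for r in range(n_replicates):
        ds = sample_continuous_dataset(sim, n_tuples, rng_seed=master_seed, replicate=r)
        seed = _child_seed(master_seed, r, 11)
        for method in methods:
            if method == "fvi_unregularized":
                _, pol = fvi_regularized(
                    ds, sim.reward_fn, sim.gamma, n_actions=sim.n_actions,
                    n_sample_states=n_sample_states, n_iterations=n_iterations,
                    mode="global", epsilon_global=0.0, rng_seed=seed,
                )
                rows.append((method, 0.0, r, loss_of(pol)))
            elif method == "fvi_sa_specific":
                _, pol = fvi_regularized(
                    ds, sim.reward_fn, sim.gamma, n_actions=sim.n_actions,
                    n_sample_states=n_sample_states, n_iterations=n_iterations,
                    mode="sa_specific", rng_seed=seed,
                )
                rows.append((method, np.nan, r, loss_of(pol)))
            elif method == "fvi_global":
                for eps in grid:
                    _, pol = fvi_regularized(
                        ds, sim.reward_fn, sim.gamma, n_actions=sim.n_actions,
                        n_sample_states=n_sample_states, n_iterations=n_iterations,
                        mode="global", epsilon_global=float(eps), rng_seed=seed,
                    )
                    rows.append((method, float(eps), r, loss_of(pol)))
            else:
                raise ValueError(f"unknown continuous method {method!r}")
    frame = pd.DataFrame(rows, columns=["method", "param", "replicate", "loss"])
    return SweepResult(frame)


def summarize(result: SweepResult, plot_path: str | Path | None = None) -> pd.DataFrame:
    """Mean loss and standard error per (method, parameter).

    With a single replicate the standard error is reported as NaN.  If
    ``plot_path`` is given (and matplotlib is available) a loss-curve
    figure is written: one curve per grid method, horizontal lines for
    parameter-free methods.
    """
    if result.frame.empty:
        raise ValueError("cannot summarize an empty sweep result")
    df = result.frame.copy()
    df["param"] = df["param"].fillna(np.inf)  # group NaN params together
    agg = (
        df.groupby(["method", "param"])["loss"]
        .agg(mean_loss="mean", sd="std", n="count")
        .reset_index()
    )
    agg["se"] = agg["sd"] / np.sqrt(agg["n"])
    agg.loc[agg["n"] < 2, "se"] = np.nan
    agg["param"] = agg["param"].replace(np.inf, np.nan)
    agg = agg.drop(columns="sd")
    if plot_path is not None:
        _plot(agg, plot_path)
    return agg


def _plot(agg: pd.DataFrame, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for method, grp in agg.groupby("method"):
        if grp["param"].notna().all() and len(grp) > 1:
            ax.errorbar(grp["param"], grp["mean_loss"], yerr=grp["se"], label=method)
        else:
            ax.axhline(grp["mean_loss"].iloc[0], linestyle="--", label=method)
    ax.set_xlabel("regularization strength ε")
    ax.set_ylabel("mean policy loss")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
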