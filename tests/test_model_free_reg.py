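"""Regularized fitted Q-iteration and the per-pair target-error minimizers."""

import numpy as np
import pytest

from discreg import (
    FQIConfig,
    Policy,
    QTable,
    TabularMDP,
    count_transitions,
    epsilon_star_multinomial,
    epsilon_star_sse,
    fqi_regularized,
    mle_transition,
    sample_dataset,
    solve_optimal,
    sse_matrices,
    verify_theorem2,
)
from discreg.environments import make_river_swim

from conftest import random_mdp


def _exhaustive_dataset(mdp, per_pair=200, seed=0):
    return sample_dataset(mdp, "equal_counts", per_pair, rng_seed=seed)


# ---------------------------------------------------------------------------
# FQI core behavior
# ---------------------------------------------------------------------------


def test_fqi_first_iteration_from_zero_is_mean_reward(rng, small_mdp):
    ds = sample_dataset(small_mdp, "uniform_sa", 200, rng_seed=1)
    cfg = FQIConfig(gamma=0.9, n_iterations=1, epsilon_mode="global", epsilon_global=0.0)
    q, _, _ = fqi_regularized(ds, small_mdp.rewards, cfg)
    counts = count_transitions(ds, 5, 2)
    observed = counts.n_sa > 0
    np.testing.assert_allclose(q.q[observed], small_mdp.rewards[observed])
    np.testing.assert_allclose(q.q[~observed], 0.0)


def test_fqi_unregularized_matches_planning_on_empirical_model(rng, small_mdp):
    """Model-based oracle: ε = 0 FQI is value iteration on the MLE model."""
    ds = _exhaustive_dataset(small_mdp, per_pair=100, seed=2)
    cfg = FQIConfig(gamma=0.9, n_iterations=400, epsilon_mode="global", epsilon_global=0.0)
    q, pi, _ = fqi_regularized(ds, small_mdp.rewards, cfg)
    counts = count_transitions(ds, 5, 2)
    mdp_hat = TabularMDP(small_mdp.rewards, mle_transition(counts), 0.9)
    q_vi, pi_vi = solve_optimal(mdp_hat, tol=1e-12)
    np.testing.assert_allclose(q.q, q_vi.q, atol=1e-6)
    np.testing.assert_array_equal(pi.actions, pi_vi.actions)


def test_fqi_full_shrinkage_is_reward_plus_constant(rng, small_mdp):
    ds = _exhaustive_dataset(small_mdp, per_pair=20, seed=3)
    cfg = FQIConfig(gamma=0.9, n_iterations=300, epsilon_mode="global", epsilon_global=1.0)
    q, pi, _ = fqi_regularized(ds, small_mdp.rewards, cfg)
    # Q(s,a) − R(s,a) is the same constant for every pair
    diff = q.q - small_mdp.rewards
    assert np.ptp(diff) < 1e-6
    np.testing.assert_array_equal(pi.actions, np.argmax(small_mdp.rewards, axis=1))


def test_fqi_unobserved_pairs_stay_at_initialization(small_mdp):
    from discreg import TransitionDataset

    ds = TransitionDataset([0, 1], [0, 0], [1, 2], [0.1, 0.2], seed=0, scheme="csv")
    cfg = FQIConfig(gamma=0.9, n_iterations=10, epsilon_mode="global")
    q, _, hist = fqi_regularized(ds, small_mdp.rewards, cfg)
    assert (0, 1) in hist.unobserved and (3, 0) in hist.unobserved
    assert q.q[0, 1] == 0.0 and q.q[3, 0] == 0.0


def test_fqi_deterministic_given_seed(rng, small_mdp):
    ds = sample_dataset(small_mdp, "uniform_sa", 100, rng_seed=5)
    cfg = FQIConfig(gamma=0.9, n_iterations=30, epsilon_mode="per_sa_sse", rng_seed=17)
    q1, p1, _ = fqi_regularized(ds, small_mdp.rewards, cfg)
    q2, p2, _ = fqi_regularized(ds, small_mdp.rewards, cfg)
    np.testing.assert_array_equal(q1.q, q2.q)
    np.testing.assert_array_equal(p1.actions, p2.actions)


# ---------------------------------------------------------------------------
# SSE minimizer (Method 1)
# ---------------------------------------------------------------------------


def test_sse_epsilon_degenerate_next_values():
    """All next-state values equal the mean value ⇒ SSE flat in ε ⇒ ε = 0."""
    counts = count_transitions(
        __import__("discreg").TransitionDataset([0, 1], [0, 0], [1, 0], [0, 0], seed=0, scheme="csv"),
        2, 1,
    )
    q = QTable(np.array([[2.0], [2.0]]))  # constant values
    pi = Policy(np.array([0, 0]))
    eps = epsilon_star_sse(counts, q, pi, np.zeros((2, 1)), gamma=0.9)
    np.testing.assert_allclose(eps, 0.0)


def test_sse_epsilon_single_tuple_hand_algebra():
    """One tuple: minimize (R + γ(1−ε)w + γε v̄ − q)² by hand.

    States 0, 1 with V(0) = 1.75, V(1) = 4 so v̄ = 2.875; the single tuple
    leaves state 0 (q = 1.75) for state 1 (w = 4) with R = 0, γ = 0.5:
    error(ε) = 0.5[(1−ε)·4 + ε·2.875] − 1.75 = 0.25 − 0.5625ε,
    zero (hence minimal) at ε* = 0.25/0.5625 = 4/9.
    """
    from discreg import TransitionDataset

    ds = TransitionDataset([0], [0], [1], [0.0], seed=0, scheme="csv")
    counts = count_transitions(ds, 2, 1)
    q = QTable(np.array([[1.75], [4.0]]))
    pi = Policy(np.array([0, 0]))
    eps = epsilon_star_sse(counts, q, pi, np.zeros((2, 1)), gamma=0.5)
    assert eps[0, 0] == pytest.approx(4.0 / 9.0, abs=1e-12)


def test_sse_epsilon_matches_grid_search(rng):
    """Grid-search oracle on the full SSE objective, per pair."""
    mdp = random_mdp(rng, n_states=4, n_actions=2, gamma=0.9)
    ds = sample_dataset(mdp, "uniform_sa", 120, rng_seed=3)
    counts = count_transitions(ds, 4, 2)
    q = QTable(rng.normal(size=(4, 2)))
    pi = Policy(rng.integers(0, 2, size=4))
    eps = epsilon_star_sse(counts, q, pi, mdp.rewards, 0.9)
    v = q.q[np.arange(4), pi.actions]
    v_avg = v.mean()
    grid = np.linspace(0, 1, 10_001)
    for i in range(4):
        for j in range(2):
            c_row = counts.counts[i, j]
            if c_row.sum() == 0:
                assert eps[i, j] == 1.0
                continue
            err = (
                mdp.rewards[i, j]
                + 0.9 * (1 - grid[:, None]) * v[None, :]
                + 0.9 * grid[:, None] * v_avg
                - q.q[i, j]
            )
            sse = (c_row[None, :] * err**2).sum(axis=1)
            best = grid[np.argmin(sse)]
            assert eps[i, j] == pytest.approx(best, abs=1e-4)


def test_sse_matrix_assembly_matches_scalar_route(rng):
    mdp = random_mdp(rng, n_states=5, n_actions=2, gamma=0.85)
    ds = sample_dataset(mdp, "uniform_sa", 150, rng_seed=6)
    counts = count_transitions(ds, 5, 2)
    q = QTable(rng.normal(size=(5, 2)))
    pi = Policy(rng.integers(0, 2, size=5))
    eps_scalar = epsilon_star_sse(counts, q, pi, mdp.rewards, 0.85)
    mats = sse_matrices(counts, q, pi, mdp.rewards, 0.85)
    diag = mats.epsilon_diag.reshape(5, 2)
    mask = ~np.isnan(diag)
    clamped = np.clip(diag[mask], 0.0, 1.0)
    np.testing.assert_allclose(clamped, eps_scalar[mask], atol=1e-8)
    # C row sums are the per-pair counts
    np.testing.assert_array_equal(mats.count_matrix.sum(axis=1).reshape(5, 2), counts.n_sa)


# ---------------------------------------------------------------------------
# multinomial minimizer (Method 2)
# ---------------------------------------------------------------------------


def test_multinomial_epsilon_conventions():
    t = np.zeros((2, 1, 2))
    t[:, 0] = [[1.0, 0.0], [0.0, 1.0]]
    n = np.array([[5], [0]])
    # V(0) = V(1) = 3 -> deterministic rows, next value equals v_avg
    q = QTable(np.array([[3.0], [3.0]]))
    pi = Policy(np.array([0, 0]))
    eps = epsilon_star_multinomial(t, n, q, pi, np.zeros((2, 1)), 0.9)
    assert eps[0, 0] == 0.0  # zero variance, zero gap
    assert eps[1, 0] == 1.0  # no data


def test_multinomial_epsilon_matches_monte_carlo(rng):
    """MC oracle: empirical MSE of the regularized target over count draws."""
    row = np.array([0.6, 0.3, 0.1])
    n = 8
    v = np.array([1.0, 3.0, -2.0])  # next-state values under pi
    v_avg = v.mean()
    gamma = 0.9
    m = row @ v
    target_true = gamma * m
    draws = rng.multinomial(n, row, size=100_000) / n
    grid = np.linspace(0, 1, 201)
    emp_mse = [
        np.mean((gamma * (1 - e) * draws @ v + gamma * e * v_avg - target_true) ** 2)
        for e in grid
    ]
    best = grid[int(np.argmin(emp_mse))]
    t = row.reshape(1, 1, 3)
    eps = epsilon_star_multinomial(
        t, np.array([[n]]), QTable(v[:, None]), Policy(np.zeros(3, dtype=int)),
        np.zeros((1, 1)), gamma,
    )
    assert eps[0, 0] == pytest.approx(best, abs=0.02)


def test_multinomial_epsilon_in_unit_interval(rng):
    t = rng.dirichlet(np.ones(4), size=(4, 2))
    n = rng.integers(0, 10, size=(4, 2))
    q = QTable(rng.normal(size=(4, 2)))
    pi = Policy(rng.integers(0, 2, size=4))
    eps = epsilon_star_multinomial(t, n, q, pi, rng.normal(size=(4, 2)), 0.9)
    assert np.all((eps >= 0) & (eps <= 1))
    assert np.all(eps[n == 0] == 1.0)


# ---------------------------------------------------------------------------
# the model-free equivalence theorem
# ---------------------------------------------------------------------------


def test_theorem2_trivial_at_zero_like_epsilon(rng, small_mdp):
    ds = sample_dataset(small_mdp, "uniform_sa", 100, rng_seed=21)
    rep = verify_theorem2(ds, small_mdp.rewards, 0.9, 1e-12, n_iterations=20)
    assert rep.equivalent


def test_theorem2_on_river_swim_datasets():
    mdp = make_river_swim()
    for k in range(8):
        ds = sample_dataset(mdp, "uniform_sa", 60, rng_seed=31, replicate=k)
        for eps in (0.2, 0.6):
            rep = verify_theorem2(ds, mdp.rewards, mdp.gamma, eps, n_iterations=60)
            assert rep.equivalent, rep.disagreements
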