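# Methods

## The problem

In offline (batch) reinforcement learning the transition kernel of a Markov
decision process must be estimated from a fixed, often sparse, set of
observed transitions, and the policy computed from that estimate is then
deployed in the real environment.  Certainty-equivalence planning — treating
the maximum-likelihood kernel T̂ as the truth — overfits when counts are
small.  A ubiquitous remedy is *discount regularization*: planning with a
discount γp below the environment's true γ.  This package implements the
theory connecting discount regularization to explicit shrinkage estimators,
and the state-action-specific regularizers that theory motivates.

## Equivalences

**Model-based.**  For any row-stochastic "regularization row" v shared by
all state-action pairs and any ε ∈ (0, 1], planning with the unmodified
kernel at discount γ(1−ε) and planning with the shrunk kernel
(1−ε)T + εv at discount γ produce the same optimal policy.  The proof runs
through the Bellman optimality equation: the shared row contributes the
same constant to every backup, and constant reward offsets do not change
the argmax.  `verify_theorem1` machine-checks this on arbitrary instances,
accepting action swaps whose Q-gap is below a tolerance (1e-8 by default)
as numerical ties.

**Prior form.**  Shrinkage by ε toward a row v is exactly the posterior
mean of a Dirichlet prior with mean v and total magnitude
Σα = ε·n/(1−ε), where n is the pair's transition count.  Equating the
discount-implied ε = (γ−γp)/γ with the posterior-mean weight yields the
implied magnitude Σα = ((γ−γp)/γp)·n(s,a): discount regularization behaves
like a prior that is *stronger on pairs with more data* — backwards from
what a statistician would want.  `prior_magnitude_from_counts` constructs
this prior, and the sweep harness reproduces the exact loss-curve overlap
of the two methods on equal-count data.

**Model-free.**  The same argument applied to the Q-update shows that
fitted Q-iteration (FQI) at discount γ(1−ε) matches FQI at γ with the
weighted-average target
R + γ(1−ε)·max_a Q̂(s′,a) + γε·Q_reg, provided Q_reg is the same constant
for every pair (here: the mean over states of max_a Q̂, the uniform-row
instantiation).  `verify_theorem2` checks the two runs iteration by
iteration.  One genuine precondition: every pair must actually receive the
update.  A pair absent from the batch keeps its initialization in both
runs, which breaks the constant-offset structure for its state; the
verifier therefore excludes states with an unobserved action from the
strict comparison and reports them.

**λ-returns.**  Truncating the bootstrap values out of the λ-return leaves
exactly the discount-regularized return at γp = γλ; `lambda_return`
returns the (full, truncated, bias) decomposition and the tests confirm it
against the definitional k-step-return average.

## State-action-specific shrinkage

### Model-based (row MSE)

For a uniform shrinkage target, the mean squared error of the shrunk
empirical row decomposes as

    MSE(ε) = (1−ε)²·(1/n)·Σ_k T_k(1−T_k)   [variance]
           + ε²·Σ_k (1/Ns − T_k)²           [bias²]

with closed-form minimizer ε* = K/(K+n),
K = Σ T_k(1−T_k) / Σ(1/Ns − T_k)².  Conventions: deterministic row → K = 0
→ ε* = 0 (nothing to shrink); uniform row (vanishing bias denominator) and
unobserved pair (n = 0) → ε* = 1.  ε* is strictly decreasing in n on
nondegenerate rows.  Since T is unknown, `epsilon_star_from_data` offers
three estimators: the true-T oracle (diagnostic; uses the data's n),
the MLE plug-in, and posterior sampling — 50 rows drawn per pair from the
Dirichlet(1 + c) posterior, with ε minimizing the sample-averaged MSE
(1001-point grid plus bounded local refinement).  For a non-uniform target
row the bias term generalizes to Σ(v_k − T_k)² with the same variance
term; this extension beyond the uniform-target derivation is used only
when a custom row is supplied.

### Model-free (target SSE / MSE)

Two per-pair weights for the FQI target:

* *SSE route*: minimize the tuple-weighted sum of squared gaps between
  the regularized target and the current Q^π(s,a).  Per pair this is the
  scalar quadratic Σ_k c_{ijk}(a_k + ε b_k)² with minimizer −Σcab/Σcb²,
  clamped to [0,1]; degenerate quadratic (all next-state values equal to
  the mean value) → ε = 0; no data → ε = 1.  The value plugged in for a
  successor s_k is Q^π(s_k, π(s_k)) — the only reading consistent with a
  Bellman target.
* *Multinomial route*: treat the counts as multinomial and minimize
  bias² + variance of the target: bias γε(v̄ − ΣT_k w_k), variance
  γ²(1−ε)²·Var_T(w)/n, giving ε = (Var/n)/(Var/n + gap²) with the same
  clamping and conventions.  This closed form is validated against a
  Monte-Carlo oracle over simulated count draws.

Tabular FQI itself is implemented on the count tensor: with one-hot (s,a)
features, least-squares refitting is exactly the per-pair mean of targets,
which depends on the data only through c(s,a,s′).  ε initialization for
the adaptive modes is uniform on [0,1] from the run seed, refreshed every
iteration; an `oracle_Q` mode computes the SSE weights once from a
supplied true Q for no-estimation-error diagnostics.

### Continuous states (kernel error bars)

On a one-dimensional state space the transition model is the expected next
state by per-action Nadaraya–Watson regression, and regularized fitted
value iteration (FVI) applies the weighted-average backup at sampled
support states, with

    ε*(s,a) = se²(s,a) / ((T_reg_mean − T̂_NW(s,a))² + se²(s,a)),

se = σ̂·sqrt(ΣK_i²)/(ΣK_j) (effective-kernel ℓ2 norm; an alternative
reading with the unsquared kernel sum is available via `se_form`), and
σ̂² = (1/(2(n−1)))·Σ(s′_{d+1} − s′_d)² from first differences after
ordering by s.  ε* and the predicted next states are computed once before
iterating.  The regularization distribution defaults to uniform on [0,1]
(T_reg_mean = 0.5), so the backup's second term is the mean sampled value;
both are overridable.

**Bandwidth.**  The default bandwidth is chosen per action by
leave-one-out cross-validation over a geometric grid (data spacing up to
the sample range).  Density-style rules such as Silverman's were tested
and rejected: they scale with the covariate spread, not the regression
function, and on the continuous River Swim defaults they produce
bandwidths several times the per-step drift.  The resulting boundary bias
pulls the up-action map's fixed point below the rewarding region, so FVI
learns a degenerate value function for *every* method — the unregularized
baseline included.  Silverman's rule and fixed bandwidths remain available
through `bandwidth_rule`.

**Value model.**  A randomized-tree ensemble (ExtraTreesRegressor,
50 trees, seeded) behind a two-method `fit`/`predict` contract, so any
regressor can substitute.

## Environments

* **10-state random chain** (2 actions): per pair, 5 random successors
  with Uniform[0,1]-drawn normalized probabilities; rewards Uniform[0,1];
  a fresh MDP per replicate in sweeps.
* **River Swim** (6 states, 2 actions): swimming left is deterministic;
  swimming right succeeds 0.3, stays 0.6, slips 0.1, with blocked mass at
  the banks folded into staying; rewards 0.005 (left action, leftmost) and
  1 (right action, rightmost).  These numbers reconstruct the common
  construction — the source figure prints no values — and are all
  overridable.
* **GridWorld** (4×4, 4 actions): per-state intended-move probability
  p_s ~ Uniform[0,1], else a jump to a per-state fixed random successor;
  one random state rewards 1, the rest Uniform[−0.5, 0.5].
* **Continuous River Swim** (s ∈ [0,1], 2 actions): action 0 drifts
  +0.05 with uniform noise of width 0.2 ("against the current"), action 1
  drifts −0.05 with width 0.05; next states clipped to [0,1]; state reward
  0.1·max(0, 1−s/0.1) + 1·max(0, (s−0.9)/0.1).  The exact values used in
  the source experiments are not published; these defaults preserve the
  stated qualitative structure and are overridable.

True discount: γ = 0.99 everywhere by default (the only discount printed
in the source material); overridable per environment.

## Evaluation harness

Per replicate the harness (re)samples the environment where it is a
distribution over MDPs, draws one batch shared by all methods (pairing the
loss curves), fits and regularizes per method, and scores each policy by
the mean over states of V^{π*} − V^π, both evaluated exactly in the true
MDP at the true γ.  Everything derives from one master seed
(replicate-indexed substreams), so a config reruns to byte-identical CSVs.

Continuous policies are scored against a 201-bin uniform discretization of
the exact dynamics (the uniform noise is integrated over bins in closed
form), comparing with the discretized optimal policy.

**Matched strengths.**  The "uniform prior, fixed magnitude" curve is
plotted against the same ε axis as discount regularization by solving, per
dataset, mean over observed pairs of A/(n+A) = ε for the constant
magnitude A.  Because the per-pair weight is convex in the count, matching
at the mean count alone would silently over-regularize the prior curve;
the average-strength matching makes the two curves differ only in how
regularization is *allocated* across pairs, which is the comparison of
interest.

**Study sizes** (all overridable): tabular sweeps use 200 replicates with
uniform-random (s,a) batches of 20·Ns tuples — twenty transition
observations per state, the one data scale printed in the source — i.e.
200 tuples on the chain, 120 on River Swim.  The continuous comparison
uses 100 replicates of 200-tuple datasets, 200 support states and 60 FVI
iterations; at ~50 tuples per action the kernel map is frequently
non-monotone at the drift scale (spurious fixed points trap value
propagation for every method), so ~100 per action is the smallest scale at
which the comparison measures the regularizer rather than model failure.

## What the generators do and do not emulate

The synthetic environments exercise uneven data coverage, deterministic
versus stochastic rows, sparse counts, and continuous dynamics with
action-dependent noise — the features the regularizers respond to.  They
do not emulate high-dimensional or partially observed state, non-stationary
dynamics, unknown rewards, or behavior-policy confounding; passing tests
here say nothing about those settings.  Rewards attached to sampled tuples
are the known R(s,a) (reward estimation is out of scope).

## Numerical choices

Value iteration stops at sup-norm residual 1e-10 (cap 100 000 iterations,
explicit failure carrying the residual); policy evaluation is a direct
linear solve; greedy ties break to the lowest action index everywhere so
equivalent solvers return identical policies; equivalence checks
additionally tolerate Q-gaps below 1e-8.  ε values are clamped to [0,1]
after every closed-form solve.  MLE rows with no observations default to
uniform (the state-action-specific regularizers instead set ε = 1 there —
full shrinkage is the coherent n → 0 limit of the MSE minimizer).

## Known limitations

The model-based ε* minimizes transition-row MSE, which is a surrogate: a
low-MSE kernel does not guarantee a low-loss policy.  The model-free
weights minimize absolute per-pair target error, not relative values, and
underperform the model-based route in the sparse regimes tested (matching
the source's own finding).  The posterior-sampling estimator inherits the
flat Dirichlet(1+c) posterior, whose prior mass (Ns per pair) is heavy
relative to very small counts; with ~10 observations per pair this is
mild, but in extremely sparse data it over-disperses near-deterministic
rows.  The continuous machinery is one-dimensional by design.
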