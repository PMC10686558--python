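# Methods

`foragefit` implements a trial-based analysis of how past reward shapes
future choice in a dynamic two-port foraging task, and of how single
cortical neurons carry that reward history. Its scientific core is a
model comparison: is the influence of a past rewarded choice discounted
**exponentially** (a fixed fractional decay per trial, as produced by
fixed-learning-rate reinforcement learning) or **hyperbolically** (a fast
initial drop with a heavy tail), and can a heavy-tailed behavioral kernel
be assembled from a population of purely exponential neural integrators
with heterogeneous time constants?

## The task model

The simulated environment is a baited two-port bandit. On every trial
each port independently receives a bait with its current assignment
probability; a bait persists until its port is chosen, and choosing
consumes it. Assignment probabilities come in (high, low) pairs —
(60%, 10%) and (52.5%, 17.5%) — that invert every 60–80 trials (uniform
on that range) following the deterministic cycle
[60,10], [10,60], [52.5,17.5], [17.5,52.5], …, with the first block's
high side drawn at random. Bait persistence makes the leaner port's
value grow the longer it is ignored, so matching-like switching is the
optimal flavor of behavior. Both ports may hold a bait simultaneously;
a port left unchosen for `k` trials is baited with probability
`1−(1−p)^k` (verified against a Monte-Carlo oracle in the tests).

All behavioral models predict the probability of a *left* choice.
History enters through two signed per-trial signals,

- `RewC(t)` = +1 rewarded-left, −1 rewarded-right, 0 otherwise,
- `UnrC(t)` = +1 unrewarded-left, −1 unrewarded-right, 0 otherwise,

lagged over *valid* trials only (alarm/miss trials are spliced out before
lag construction), with lags reaching before the session start coded 0 so
that every valid trial keeps a design row.

## Behavioral models

**History GLM.** Logistic regression of choice on `RewC(t−i)` and
`UnrC(t−i)`, i = 1..10, plus a bias. Fit by unpenalized maximum
likelihood (L-BFGS-B on the cross-entropy with analytic gradients); a
1e−6 ridge on the weights guards against perfect separation and is far
below any interpretable prior.

**RL model.** A Rescorla-Wagner variant with separate learning rates for
rewarded (`α_rew`) and unrewarded (`α_unr`) trials, multiplicative
forgetting `δ` of the unchosen value, and a softmax
`P_L = σ(β_ΔQ (β_0 + Q_L − Q_R))`. Q values start at 0. The forward
recursion is driven by the observed choices and rewards; fitting is
bounded maximum likelihood (rates in [0,1], `β_ΔQ` in [0,20], `β_0` in
[−5,5]), best of 10 uniform random starts. The **RL index** — the
per-trial log-likelihood advantage of the fitted model over a bias-only
null (a single free logit scalar, whose MLE is the empirical left rate) —
gates "expert" sessions at 0.08. The inner recursion is jit-compiled
(numba) because it sits inside a multi-start optimizer evaluated on
10,000-trial sessions.

**Decay models.** The single-kernel choice models
`logit P_L = β · Σ_i RewC(t−i) w_i(τ) + β_0` with N = 15 lags and

- exponential kernel `w_i = e^{(1−i)/τ}`,
- hyperbolic kernel `w_i = 1/(1 + (i−1)/τ)`.

Both equal 1 at lag 1; the hyperbolic strictly dominates beyond lag 1 at
matched τ — the heavy tail is the entire scientific content of the
comparison. τ is optimized on a log scale inside (1e−2, 1e3), jointly
with (β, β_0) by L-BFGS-B with analytic gradients, best of 8 starts.
With τ fixed the model collapses to a one-regressor logistic regression
(used as an oracle check).

**Model comparison.** 10-fold cross-validation with contiguous folds
(respecting serial dependence; design rows are precomputed from the full
history so folds share history but not responses). Both families are fit
on the other nine folds and scored on the held-out fold; the statistic is
the mean held-out log-likelihood difference (hyp − exp) per test trial.
Positive ⇒ hyperbolic generalizes better. Per-fold fits are warm-started
from the full-session fit to keep the nonconvex τ search short; the
comparison is exactly antisymmetric and exactly zero when the same family
occupies both slots.

**Quasi-hyperbolic model.** `logit P_L = Σ_m β_m Σ_i RewC(t−i)
e^{(1−i)/τ_m} + β_0` with the M time constants held fixed and only the
weights (and bias) fit. Weights are unconstrained in sign: on a finite
15-lag window, free signs let a small mixture reproduce kernels whose
exact positive (Bernstein) representation needs time constants outside
the available pool — with the pool capped at τ = 10, a positive mixture
provably cannot match a hyperbolic kernel's far tail, while free signs
can. A `nonneg=True` option gives the positive-mixture estimator, which
has lower variance and is useful for short sessions. The **sweep** draws
M time constants at random from a pool (e.g., fitted neural time
constants), fits and scores each draw by the same 10-fold CV, and reports
the mean improvement over the session's best-fit single exponential,
alongside the full hyperbolic model's improvement as the reference
ceiling.

**Win-stay / lose-switch.** P(stay|win) normalized by the mean of
P(stay|win) and P(stay|lose), and symmetrically for switching after a
loss. Transitions are consecutive valid-trial pairs; pairs separated by
an invalid trial are skipped; conditionals with no defining events yield
NaN rather than an error.

**Inactivation variants.** Inactivation trials (~15% of trials, never
within three trials of the previous one) are compared with control trials
more than three trials after an inactivation. The split-condition history
GLM estimates separate 5-lag weight blocks for the two conditions in one
l1-penalized model (liblinear), fit on repeated matched subsamples: each
iteration trains on a random 90% of inactivation trials plus an
equal-count control subset, chooses the penalty from 10 log-spaced values
on [1e−3, 10] by held-out likelihood within the training subsample, and
evaluates on the remaining matched trials; reported weights are means
across iterations. The decay-model variant concatenates qualifying design
rows per condition, resamples matched counts with replacement (default 30
bootstraps), and reports the per-condition mean CV difference.

## Neural encoding models

Trial-mean (ready-period) activity, z-scored per cell, is modeled as a
linear function of kernel-weighted `RewC` history plus the upcoming
choice `C(t) ∈ {−1, +1}` (absorbing anticipatory movement signals) and an
offset. The lag-1 model tests modulation (two-sided t test on the
history coefficient, α = 0.05); the exponential and hyperbolic cell
models estimate a per-cell time constant with τ constrained to (0, 100].
Since the model is linear given τ, τ is profiled out: a 25-point
log-grid search refined by bounded scalar minimization of the profile
RSS, with the coefficient t test evaluated at the selected τ. Fits with
τ̂ ≥ 99.5 are flagged boundary-pinned and excluded from timescale
distributions (the exponential is unidentifiable from 15 lags there).
Per-cell model comparison uses held-out Gaussian log-likelihood with the
training-fold residual variance, same contiguous 10-fold scheme.

Controls and statistics:

- **Shuffle control**: each cell's activity is permuted independently
  across trials; the refit significant fraction estimates the false
  positive rate (calibrated to ~5%).
- **Split-half stability**: the exponential model is fit independently in
  the two halves of a session (history predictors rebuilt within each
  half, no cross-half constraints); a cell enters timescale analyses only
  if its history coefficient is significant in *both* halves. The
  full-session τ is used for distribution analyses.
- **Cross-area timescale test**: bootstrap of median differences against
  a reference area (default RSC), resampling an equal number of values
  per area, split evenly across that area's animals (default 100,000
  bootstraps); two-sided p-values with a +1 correction,
  Benjamini-Hochberg across areas.

## Synthetic data generator

Behavioral agents generate choices from their own stochastic histories
through the exact model equations: the RL agent via the value recursion,
kernel agents via exponential/hyperbolic/mixture kernels over their
realized `RewC` sequence. Synthetic neurons are noisy exponential
integrators: `A = β_RewC · (exp-kernel ⊛ RewC) + β_C C(t) + β_0 + ε`,
`ε ~ N(0, noise_sd²)`, z-scored per cell; populations draw τ log-uniform
(default [0.5, 10]). Reference conditions used throughout the tests:
kernel agents with β = 2, τ = 2 (behavioral effect sizes comparable to
expert mice, RL index ≈ 0.1–0.3); RL agents at (α_rew, α_unr, δ, β_ΔQ,
β_0) = (0.6, 0.3, 0.2, 3, 0); sessions of 1,000 trials for cohort
studies, 10,000 trials for single-session parameter recovery and for the
quasi-hyperbolic sweep (the length used for simulated-agent runs), 600
trials with 100 cells and unit noise for neural studies. The generator
emulates trial-level structure only: no within-trial dynamics, licking,
imaging noise correlations, slow drifts, or behavioral nonstationarity.
Passing tests therefore demonstrate correctness and calibration of the
estimators under the generative assumptions, not that real cortical data
must behave this way.

## Numerical choices

- Probabilities are clipped to [1e−10, 1−1e−10] inside logs; likelihoods
  are computed via `log_expit` for stability.
- Natural logarithms throughout; CV statistics are normalized per test
  trial.
- Ties at diff = 0 are reported as 0 (no family preferred).
- Weight-vs-lag curve fits (for mean GLM weights) use bounded least
  squares with three τ starts and Gaussian-residual AIC,
  `n ln(RSS/n) + 2k`, k = 2.
- All randomness flows through explicit integer seeds; fixed seeds give
  bitwise-identical sessions, activity matrices and fit results.

## Known limitations

- The quasi-hyperbolic sweep's mean improvement depends on the pool's
  range and size; small unrepresentative pools propagate into every draw.
- Unconstrained mixture weights overfit short (≤1,000-trial) sessions;
  use `nonneg=True` there.
- The τ profile search assumes a single history kernel per cell; cells
  mixing multiple timescales are summarized by an effective τ.
- Session-level statistics are exported for external hierarchical
  modeling; the package does not fit mixed-effects models itself.
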