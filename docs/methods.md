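# Methods

## Generative model and assumptions

The package targets trial-structured experiments with a limited response
window. A scalar latent state `x_k` ("inattention") follows a stationary
AR(1) process; each trial emits a log-normally distributed reaction time
and, optionally, a binary decision whose log-odds depend on both the state
and the realized reaction time. A trial whose reaction time exceeds its
window `T_k` is right-censored jointly: neither the time nor the decision is
recorded, only the fact of the timeout. Because `Pr(y_k > T_k | x_k)` is
increasing in the state (for `b1 > 0`), censoring is informative — it is
missingness *not at random* — and a censored trial enters the likelihood
through its survival probability rather than being discarded.

Assumptions: the state is Markov and scalar; the model parameters are known
and fixed (no parameter estimation — filtering only, no smoothing); decision
and reaction time are conditionally independent across trials given the
state; the observed-data likelihood is taken as the Gaussian density of
`log y` (the `1/y` Jacobian is state-free and cancels in every posterior
normalization, so all filters are unaffected by the convention).

## Parameters

`ModelParameters` holds nine scalars; the defaults are the reference study
conditions used throughout the tests and the acceptance script:

| parameter   | default | units                 | role |
|-------------|---------|-----------------------|------|
| `a0`        | 0.025   | state units           | state intercept |
| `a1`        | 0.95    | —                     | AR(1) coefficient (stationary iff abs < 1) |
| `sigma_eps` | 0.078   | state units           | process noise SD |
| `b0`        | −0.6    | log-seconds           | log-RT intercept (`exp(b0)` ≈ 0.55 s at state 0) |
| `b1`        | 1.0     | log-seconds per state | state→log-RT slope |
| `sigma_v`   | 0.141   | log-seconds           | observation noise SD |
| `c0`        | −3.5    | logit                 | decision intercept |
| `c1`        | 10.0    | logit per second      | RT→decision slope (slower ⇒ more correct) |
| `c2`        | −8.5    | logit per state       | state→decision slope (inattentive ⇒ more errors) |

These give a stationary state mean 0.5 and SD ≈ 0.25, so the state lives in
[0, 1] with high probability. The canonical session length is 100 trials,
and censoring thresholds of interest span 0.2–2 s, which sweeps the expected
censored fraction from ≈100% down to ≈0.3%.

## The four filters

All four share the AR(1) Chapman–Kolmogorov prediction; they differ only in
the per-trial likelihood applied at the update.

**Exact grid filter.** The belief is probability mass on a uniform state
grid (Riemann summation). Prediction is a dense transition-matrix product,
precomputed once per parameter/grid pair; the update multiplies by the trial
likelihood (computed in log space and re-centered before exponentiation) and
renormalizes. Default grid: stationary mean ± 8 stationary SDs, 1001 points,
which keeps off-grid stationary mass below 1e-14; mass truncated by the grid
is monitored and logged past 1e-6 per step. Posterior moments, skewness, and
numeric HPD regions are read off the grid. Doubling the resolution moves
posterior means by less than 1e-4 (tested), and on uncensored data the grid
filter agrees with the closed-form Kalman filter to 1e-4.

**Approximate Gaussian filter.** The posterior is summarized by mean and
variance; the update is the second-order Taylor (Laplace) step of the exact
log-posterior about the prediction mean. For an observed trial this is the
scalar Kalman update on `log y` (plus logistic score `c2 (z − q)` and
information `c2^2 q(1−q)` when a decision is present). For a censored trial
the score is `b1 U` and the information `b1^2 U (U − e/sigma_v^2)`, where
`e` is the standardized censoring residual and `U` the inverse Mills ratio
`phi(e)/L(e)` of the survival mass. The Mills inequality bounds the censored
information in `(0, 1/sigma_v^2)`, so censored trials always add positive,
bounded information and the posterior precision stays positive. Both
branches are verified against finite-difference derivatives of the exact
trial log-likelihood (1e-6). `U` is computed through the scaled
complementary error function (`erfcx`), which stays accurate arbitrarily
deep in the censoring tail; below standardized residuals of about −38 the
Gaussian density underflows double precision and the information term
degrades cleanly to zero.

**Data deletion.** Censored trials contribute likelihood one: the posterior
equals the one-step prediction on those trials. The filter stays calibrated
in width but ignores the evidence that censoring favors high states, which
biases the mean downward during censored runs.

**Multiple imputation.** `m` (default 10) independent chains; each chain
replaces every censored trial with a draw from its own conditional
predictive law — sample a state from the chain's one-step prediction, a
reaction time from the log-normal model given that state, accept once the
time exceeds the threshold, then a decision from the logistic model — and
filters the imputed record with the plain uncensored likelihood. Rejection
sampling is capped at 1000 attempts; past the cap an exact sampler draws
the state from the prediction reweighted by its survival probability and
the reaction time from the truncated log-normal by inverse CDF, which has
the same target law as the rejection loop without stalling when the
censoring probability is tiny (the two paths agree by a two-sample test).
Per trial the returned belief is the equal-weight density mixture of the m
chain posteriors; Rubin's-rules moment combination (mean of means,
within-chain variance plus `(1 + 1/m)` between-chain variance) is available
via `combine="rubin"`. The chains are run fully independently, each
conditioning its imputations on its own filtered history — a deliberate
reading of "average filter solution over imputations"; sharing a single
filtered history across chains would be the main alternative.

**Initial prior.** The generative start of a session is a stationary draw,
and the default prior for every filter is the (discretized) stationary
distribution; a delta, uniform, or arbitrary Gaussian prior can be supplied
instead.

## What the simulator emulates — and what it does not

The simulator reproduces the generative model exactly as specified above:
stationary state start, log-normal reaction times, logistic decisions drawn
only on observed trials, censoring at a fixed per-session threshold (the
API accepts per-trial thresholds; the experiments use constants). The
decision random stream is drawn for every trial whether or not it is
censored, so the same seed yields the *same underlying session* under any
threshold — the basis of the common-random-numbers design in the sweep.

It does not emulate features of real behavioral data: practice/fatigue
drifts beyond AR(1), trial-history covariates, non-log-normal reaction-time
families (e.g. Gamma), response anticipations or fast guesses, or parameter
uncertainty (the filters receive the true generative parameters). Passing
tests therefore demonstrate correctness of the estimators *under the model*,
not robustness to model misspecification.

## Evaluation

Two metrics, pooled over all trials of all realizations: RMSE between the
posterior mean and the true state, and empirical coverage of the 95% HPD
region (numeric on the grid; mean ± 1.96 sd for Gaussian beliefs). The
per-realization average RMSE is also reported, and a bootstrap over
realizations quantifies Monte-Carlo error. The no-censoring RMSE floor of
the reaction-time-only model is the scalar Riccati fixed point
`P = sigma_v^2 M / (b1^2 M + sigma_v^2)`, `M = a1^2 P + sigma_eps^2`
(`sqrt(P)` ≈ 0.0892 at the defaults); a normalized RMSE column divides by
this anchor. Under full censoring the filter carries no observation
information and the error approaches the stationary SD, 0.25. For the mixed
reaction-time + decision model the decision contributes extra information
and the no-censoring floor is lower (≈ 0.0815 empirically); no closed form
is used for it.

The threshold sweep runs all four methods on shared realizations
(realization `i` uses seed `base_seed + i`, identical across thresholds and
methods, so contrasts are paired) and is deterministic given `base_seed`.
Completed thresholds are flushed to CSV with a manifest, and a rerun with
identical settings resumes rather than recomputes.

## Problem sizes

The canonical experiment is 500 realizations × 100 trials per threshold.
The test suite and the acceptance script use desk-scale versions chosen to
keep Monte-Carlo error well inside the asserted tolerances: 100–300
realizations × 100 trials on the 1001-point grid for the single-threshold
studies, and 50 realizations on a 601-point grid for the three-threshold
method-comparison sweep (grid-convergence tests justify the coarser grid).
The full 500×100 sweep is available through `run_sweep` / `censorfilter
sweep` defaults.

## Numerical choices and degenerate inputs

- Censored probabilities go through the standard normal CDF/`erfc`; the
  error-function and CDF conventions coincide after the `sqrt(2)` rescaling.
- Log-likelihoods are re-centered by their maximum before exponentiation on
  the grid; a fully underflowed update raises an error naming the trial.
- HPD ties at the cutoff density are all included, so the attained mass is
  deterministically ≥ the level; the region may be a union of disjoint
  intervals for multimodal (e.g. post-censoring-run) posteriors.
- Non-stationary state parameters (|a1| ≥ 1) are rejected where the
  stationary distribution is required (steady-state moments, default grid,
  default priors); explicit grid bounds and priors make the filters usable
  regardless.
- Empty trial sequences return empty belief sequences; observed trials must
  have `0 < rt ≤ threshold`; censored trials carry no data fields and files
  encode censoring only via the explicit `status` column.

## Known limitations

- Interval (two-sided) censoring is provided as a likelihood evaluation
  (`interval_censored_log_likelihood`, the standard log-normal interval
  probability, of which the right-censored case is a special case) but is
  not wired into the filters.
- The Gaussian filter expands about the prediction mean, not the posterior
  mode; under very heavy censoring (≳80% of trials) its RMSE runs a few
  percent above the exact filter and its symmetric intervals cannot
  represent the right skew that accumulates over censored runs.
- At near-total censoring the imputation mixture's second moment is
  inflated by between-chain disagreement even though each chain is
  individually overconfident; its HPD coverage collapses regardless, which
  is the practically relevant failure.
- Fixed-interval smoothing and joint parameter estimation (EM or
  variational) are out of scope; the filters assume known parameters.
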