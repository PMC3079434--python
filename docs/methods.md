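# Methods

## The model

`sepnet` estimates how actor traits affect change in a directed friendship
network observed at discrete exam waves `t = 1..T`.  Let `Y_ijt` indicate a
nomination from actor `i` (ego) to actor `j` (alter) at exam `t`.  Rather
than modeling the joint network, the package conditions on the lagged state
of each directed tie and fits two *separable* models:

* **dissolution** — for pairs with `Y_ij,t-1 = 1`, the probability that the
  tie is gone at `t`;
* **formation** — for pairs with `Y_ij,t-1 = 0`, the probability that a tie
  appears at `t`.

Each side is a logistic regression on the logit scale

```
logit P(event) = alpha + delta_t + lambda * Y_ji,t-1
                 + beta' x_ij,t-1 + gamma' z_ij,t-1
                 + theta_i + eta_j
```

with exam fixed effects `delta_t` (first modeled exam as reference; exam-1
data only ever form predictors), a reciprocity term on the lagged inbound
tie `Y_ji,t-1`, trait predictors `x`, controls `z`, and crossed Gaussian
random effects: a sender effect `theta_i ~ N(0, sigma^2)` and a receiver
effect `eta_j ~ N(0, tau^2)`, each drawn once per actor.  Conditional on
the random effects and the lagged state, dyads are independent — a strong
but explicit assumption appropriate for very sparse networks, and one that
makes the model generative.  The process is Markov: states before `t-1`
carry no information given the state at `t-1`.

Inference targets the conditional (actor-level) parameters themselves, not
population-averaged effects.

### Dyadic predictors

For a continuous trait `X` the key predictors of a pair are the absolute
difference `|X_i - X_j|`, the direction `sgn(X_i - X_j)` (with
`sgn(0) = -1`; an `indicator` coding with "ego bigger" in {0,1} is
available as an option), their product (the signed difference itself), and
the dyad average `(X_i + X_j)/2`.  For a binary trait they are the one-hot
of (ego only, alter only, both), with "neither" as reference.  Controls
cover age (absolute difference and average), sex (both-male and both-female
indicators, mixed pairs as reference), education (difference and average of
an ordinal scale) and geographic separation (a precomputed pairwise
distance, lagged, optionally with its absolute change between the two most
recent exams).  All predictors are lagged so that trait change precedes tie
change.

Predictor columns are standardized to mean 0, SD 1 (sample SD, ddof = 1)
within each model dataset — never pooled across the dissolution and
formation sides — and the scaling constants are kept so coefficients can be
mapped back to trait units.  Binary indicator columns are standardized too
by default (a flag disables this), so that effect sizes are comparable
across predictors of both kinds.  Standardization statistics are computed
on the final analysis rows, after missing-predictor rows are dropped; this
keeps coefficients interpretable within the fitted sample.

### Missing data

An exam missed by either actor makes the tie status missing; such
dyad-exams contribute neither outcomes nor lags.  By default the lag is
strictly `t - 1` (transitions across gaps are counted descriptively but
excluded from risk sets); a `gap_lag` option uses the most recent observed
exam instead.  Rows with any missing required predictor are dropped and the
count is reported.  Height-like traits can be declared time-invariant;
"ever"-style recodes (an actor ever observed positive is positive
throughout) are provided at ingestion.

## Estimation

The crossed random-effects logistic model is fit by Laplace-approximate
maximum likelihood, the approach of the mixed-model software family this
model class is usually fit with.  For candidate `(log sigma, log tau)` the
inner loop finds the joint conditional mode of `(beta, theta, eta)` by
penalized iteratively reweighted least squares with full Newton steps and
step halving.  The crossed structure keeps this cheap: the sender-sender
and receiver-receiver Hessian blocks are diagonal, so the sender block is
eliminated diagonally and only one dense Cholesky factorization (of the
receiver Schur complement) is needed per step.  The Laplace log-likelihood
at the mode is

```
l(beta, u_hat) - (1/2) u_hat' Lambda^-1 u_hat
  - (1/2) log det Lambda - (1/2) log det H_uu
```

with `Lambda` the random-effect covariance and `H_uu` the random-effect
block of the penalized Hessian.  The outer loop maximizes this over the
log-SDs with Nelder-Mead (warm-starting the inner loop between
evaluations).  Numerical choices: inner tolerance 1e-9 on the penalized
log-likelihood; outer tolerances 2e-3 (parameters) and 1e-6 (objective);
SDs floored at 1e-6 during optimization and reported as exactly 0 below
1e-4 with a boundary flag (boundary estimates are a legitimate outcome, not
an error); fixed default start at SD 0.5 and beta at the plain-logistic
mode.  ML (not REML-style) criteria are used throughout — REML has no
settled definition for GLMMs.  Rows are brought into a canonical order
internally so results are exactly invariant to input row order.

Standard errors for the fixed effects come from the profiled observed
information (variance components held at their estimates); no SEs are
reported for the SDs.  Wald z-statistics and two-tailed normal p-values are
reported, with significance flagged at 0.05.  Either variance component can
be fixed (at 0 they are removed entirely; with both at 0 the fit reduces
exactly to plain logistic ML, which is tested against an independent
implementation).

### Quadrature oracle

For instances with at most 8 random effects in total, the exact marginal
likelihood is evaluated by Gauss-Hermite quadrature.  Crossed effects do
not factorize jointly, so the integral is taken over the full random-effect
vector: a tensor grid is laid over the smaller side's effects, conditional
on which the other side's units are independent and integrate one by one —
algebraically identical to the full tensor product but exponentially
cheaper.  This oracle verifies both the Laplace log-likelihood (agreement
within 0.5 per cent on test instances) and the location of the ML optimum
(within 0.05 per parameter), and is itself checked against dense-grid
integration on a 2-effect instance.

## Case-control sampling of never-connected dyads

The formation risk set over all orderable pairs is computationally and
statistically dominated by pairs that could never realistically form a
tie.  The sampler therefore augments the "case" dyads (ever non-null) with
`k` always-null "control" dyads per case: one endpoint of each case dyad is
chosen uniformly, and `k` partners are drawn without replacement from
actors who ever nominated somebody (so a nomination was at least possible),
excluding relatives and any pair that ever carried a tie.  Control dyads
colliding with cases or with already-drawn controls are re-drawn; the same
partner may serve in controls for different case dyads (only dyad-level
uniqueness is enforced).  Everything is deterministic given the seed and
the full draw is logged.  Under this design the formation intercept no
longer estimates the marginal formation rate (a warning is attached to the
fit); slope coefficients are unaffected, which is the standard case-control
argument.  No rare-events intercept correction is applied.

## The synthetic generator

The generator emulates the kind of panel the framework was built for — a
sparse tracking-sheet friendship network over seven waves — and doubles as
the package's validation harness, because its transition law *is* the
separable model evaluated by the same predictor code used in estimation.

* **Acquaintance pools.**  Each actor receives a fixed symmetric candidate
  pool (a random regular graph, default degree 10).  Ties can only exist
  inside pools.  Sparsity is achieved by pool size plus a calibrated
  formation intercept, not by a hard out-degree cap, which would violate
  dyadic independence; the one-nomination-per-wave convention of real
  tracking sheets is therefore only approximated (a small fraction of
  actors carries out-degree 2+, matching the data being emulated).
* **Calibration.**  With zero trait effects each in-pool ordered pair is a
  two-state Markov chain with formation probability `f(eta_f)` and
  dissolution probability `q(eta_d)`, so its stationary tie probability is
  `f/(f+q)`.  The default formation intercept (-5.88) solves
  `K * E[f/(f+q)] = 0.24` by Gauss-Hermite quadrature over the two receiver
  effects — the naive balance `K*Ef/(Ef+Eq)` overshoots because ties to
  low-dissolution receivers accumulate.  Defaults: dissolution intercept
  -1.65 (about a 16 per cent per-interval dissolution hazard), reciprocity
  effects -0.48 (dissolution) and -1.35 (formation), receiver SDs 0.583 and
  0.686, sender SDs 0 — the estimates reported for the motivating study —
  mean out-degree about 0.24 over 7 waves.
* **Traits.**  Continuous traits follow stationary AR(1) processes (default
  a BMI-like trait: mean 26, SD 4, autocorrelation 0.9); binary traits
  follow two-state Markov chains started at their stationary prevalence
  (default smoking-like: prevalence 0.3, persistence 0.9).  Ages advance 4
  years per wave, matching the roughly four-year exam spacing emulated.
  Default trait *effects* are zero — the generator's reference
  configuration is a null network — and experiments plant effects
  explicitly on named predictor columns.
* **Missingness** is applied per actor-exam after generation (default 5 per
  cent, chosen once as a plausible missed-exam rate for a cohort with
  near-zero attrition), so the underlying process is complete and the
  observed panel censors it, as in the real design.
* **What it does not emulate:** nomination budgets (the instrument's
  one-contact convention), trait contagion along ties (the reverse process
  is deliberately outside the estimation target), relatives, geography and
  education generators are off by default, and candidate pools are known to
  the experimenter — recovery experiments exploit that by fitting on the
  generative universe, which real analyses cannot do.  Passing recovery
  tests therefore demonstrates correctness of the estimation machinery
  under the model's own assumptions, not robustness to their violation.

## Validation experiments (what the test-suite runs)

Problem sizes are chosen to exercise the asymptotics while keeping the full
suite desk-sized: recovery uses 20 replicates at 500 and 1000 actors with
receiver SD 0.6, null sender SD, and raw-scale BMI effects of +0.08 / -0.04
(dissolution / formation) on the absolute difference; estimates are checked
for bias within 3 Monte-Carlo SEs per component at the 1000-actor size
(where the Laplace small-sample attenuation visible at 500 actors has
decayed), 95 per cent Wald coverage of at least 16/20 per component at both
sizes, and empirical-SE shrinkage consistent with sqrt(n) (median ratio
across components in [1.2, 1.7] when n doubles; individual 20-replicate
ratios are too noisy to test one by one).
Type-I error is checked over 40 fits of null panels (no trait effects):
the share of trait coefficients significant at 0.05 must lie within a
3-SE binomial band around 5 per cent.  Markov consistency is checked by
fitting the double-lag variant to single-lag data: all `t-2` key
coefficients must sit within 3 SEs of zero.

## Known limitations

* Laplace ML shares the small-cluster bias of the reference software
  family: variance components for receivers with one or two rows are
  shrunk; the quadrature oracle quantifies the (small) likelihood error on
  tiny instances.
* The sampler assumes enough eligible partners per case actor and raises
  otherwise rather than silently relaxing eligibility.
* Coefficient comparability across published tables depends on the
  standardization convention; both the standardized and unstandardized
  routes are supported because the convention used for any given published
  table is not always recoverable.  Published prose and tables occasionally
  disagree on signs; this package treats tables as authoritative and makes
  no attempt to reconcile prose.
* `transition_opportunities` and `count_candidate_null_dyads` implement the
  printed approximations of the motivating study's accounting (for example
  `n(n-1)/2 - n`), which are undefined for fewer than 3 dyads.
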