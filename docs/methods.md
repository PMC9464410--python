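# Methods

## The model

`survbma` performs Bayesian estimation, hypothesis testing, and
model-averaging for right-censored two-arm survival data under five
accelerated failure time (AFT) parametric families: exponential,
Weibull, log-normal, log-logistic, and gamma. All families share a
log-scale linear predictor

    eta_i = alpha + beta * x_i,        x_i in {0, 1},

where `alpha` is the log-days intercept of the comparator arm and
`beta = log(AF)` is the log acceleration factor of the treatment.
Writing `z = t * exp(-eta)`, each family is a unit-scale distribution
in `z` (shape or log-sd parameter `gamma_aux` where applicable), so the
acceleration identity `S(t | x=1) = S(t exp(-beta) | x=0)` holds exactly
for every family and `beta` has the same interpretation across all of
them. An AF above 1 means longer survival in the treated arm.

The likelihood of data `{t_i, c_i}` (event indicator `c_i = 1` for
observed events) is the usual censored-data product of hazard (events)
times survival (everyone), evaluated in log form as
`sum_events log f + sum_censored log S`.

### Ensembles and evidence

Two model ensembles are built from a prior table:

* **testing** — ten models: each family twice, once with `beta` fixed
  at 0 by a spike prior (null) and once with
  `beta ~ Normal(0.30, 0.15)` truncated to `[0, inf)` (alternative,
  an informed hypothesis of a clinically interesting positive effect);
  equal prior model probabilities of 1/10.
* **estimation** — five alternative models with
  `beta ~ Normal(0, 1)` (which places ~95% of the prior AF mass in
  roughly 0.14–7.1); probabilities of 1/5.

Per-family supporting priors (defaults in `default_prior_table()`)
are normal on `alpha` (means near 8.7 log-days, i.e. survival scales of
several thousand days, sds near 2) and log-normal on `gamma_aux`
(mean-log near 0, sd-log near 0.3). These were derived from historical
colon-cancer trials via meta-analytic predictive priors; the
`historical` module implements the same construction for new data.

Each model's marginal likelihood feeds posterior model probabilities
(softmax of log marginal likelihood plus log prior probability, via
log-sum-exp). Evidence for the treatment effect is the **inclusion
Bayes factor**: posterior over prior odds of the alternative-model
subset against the null subset. Family-level and single-model inclusion
Bayes factors use the same subset arithmetic. Estimation averages the
per-model `beta` posteriors into a mixture weighted by posterior model
probabilities; survival and hazard curves are averaged pointwise the
same way. Credible intervals are equal-tailed.

## Computation

### Posterior sampling

An adaptive random-walk Metropolis sampler runs 4 chains of 1000
warmup plus 2000 retained draws on an unconstrained scale: `alpha`
untransformed, `gamma_aux` log-transformed (its log-normal prior is
then simply normal), and `beta` untransformed. A lower-truncated
effect prior is handled by rejection at the bound rather than a log
transform: when the posterior piles against the bound, the log-beta
coordinate acquires a heavy left tail that both the sampler and the
bridge proposal cover poorly, while the natural-scale chain stays
well-behaved. Convergence is declared at split R-hat < 1.01 and bulk
ESS > 400 per parameter (arviz); non-converged samples are refused by
downstream consumers unless forced.

### Marginal likelihoods

Three estimators, cross-validated against each other and against the
exponential–gamma conjugate closed form in the test suite:

* **Bridge sampling** (reference): the iterative optimal-bridge
  estimator. A multivariate normal proposal is fitted to half of the
  pooled posterior draws; the bridge identity is iterated on the other
  half against an equal number of proposal draws until the log estimate
  moves by less than 1e-10 (at most 1000 iterations). The Monte Carlo
  error is the approximate relative root-MSE with the posterior half's
  autocorrelation absorbed through an effective sample size.
* **Laplace** (design-analysis default): posterior-mode expansion on
  the unconstrained scale. For truncated effect priors the expansion
  uses the untruncated normal prior and multiplies by the Gaussian
  posterior mass on the allowed side over the prior truncation mass —
  accurate even when the mode sits below the bound, where a
  log-transformed expansion fails. Against bridge sampling on a
  full-size (n = 2070) synthetic trial the per-model discrepancy is
  below 0.1 in log (typically below 0.05), and against brute-force 3-D
  quadrature below 0.005.
* **Quadrature** (deterministic oracle, <= 2 free parameters):
  adaptive tensor Gauss-Legendre on a box centered at the posterior
  mode with half-width 12 posterior sds (clipped at hard support
  bounds; truncated effects are integrated on the natural beta scale),
  with node counts doubling until the log integral is stable to 1e-8.

Mode finding uses damped Newton iterations whose gradient/Hessian
stencils are evaluated in a single vectorized likelihood call; the
likelihood collapses tied censoring times (administrative censoring
makes most rows identical), so one full-ensemble fit of a 2070-person
trial takes ~30 ms. Sequential analyses warm-start each look from the
previous look's mode.

## Design analysis (BFDA)

Trials are simulated from the prior predictive distribution of the
testing ensemble: a generating model is chosen (equal split across the
five families within a scenario), `(alpha, gamma_aux)` are drawn from
their priors, `beta` from its prior under the alternative scenario or
fixed at 0 under the null, and survival times are drawn per arm with
administrative censoring at the horizon. Defaults mirror the planned
trial: 2070 participants in equal arms, all entering at time 0, a
5-year (1825-day) horizon, monthly (30-day) looks in the sequential
design. Sequential Bayes factor trajectories are frozen once they
leave 1/15–15 (the decision bounds of interest lie inside that range;
freezing saves most of the computation). Per-replicate seeds derive
from the master seed and are recorded in the result tables.

Misleading-evidence rates at a symmetric bound are exceedance
fractions (fixed-n) or any-look crossing fractions (sequential);
calibration inverts the empirical quantiles (fixed-n) or per-trajectory
extremes (sequential) to find bounds matching target error rates.
`DesignSpec` defaults to 500 replicates per scenario; the reproduction
script uses 1000 for the fixed-n analysis (matching the scale of the
original study) and 200 trajectories per scenario for the sequential
analysis — enough that binomial Monte Carlo error is small against the
published operating characteristics while a full analysis completes on
a single CPU in minutes.

The exact binomial example (ten patients, null recovery rate 0.5,
point alternatives 0.6 and 0.7) is computed by enumeration over the 11
outcomes. Enumeration attributes the 5.5% misleading-evidence rate at
BF >= 5 to the theta = 0.7 comparison (56/1024) and <0.1% to
theta = 0.6 (1/1024); the narrative pairing of these two numbers is
sometimes reversed in secondary accounts, so the implementation reports
the enumerated assignment.

## Synthetic data

The `simulate` module's default preset emulates a colon-cancer
disease-free-survival trial: log-normal event times with `alpha = 8.7`,
`gamma_aux = 1.9`, 1035 participants per arm, administrative censoring
at 1825 days — yielding roughly 20–30% observed events, the regime of
the motivating trial. Optional independent exponential censoring and a
uniform accrual window exist for sensitivity work. What the generator
does **not** emulate: covariate-dependent censoring fitted to real
trial data, staggered calendar-time entry in the monitor (participants
are treated as time-on-study aligned), competing risks, or covariates
beyond the single treatment indicator. Passing tests therefore
demonstrate correctness of the machinery and realistic operating
characteristics under these stylized conditions, not performance on
any particular real dataset.

## Historical borrowing

`historical.predictive_prior` implements a normal–normal hierarchical
meta-analysis of per-study maximum-likelihood estimates: study
parameters are `N(mu, tau^2)` with a flat prior on `mu` and a
half-normal prior (default scale 0.5 on the log-days scale) on `tau`,
evaluated on a 2-D grid; the predictive distribution for a new study
is moment-matched to a normal with variance `Var(mu) + E(tau^2)`. This
is a deliberate simplification of a full MCMC hierarchical model: it
keeps the defining property (heterogeneity inflates the predictive
scale, discounting dissimilar history) while remaining deterministic
and fast. Studies with fewer than 20 events are rejected as too
uninformative for a stable curvature-based standard error.

## Numerical choices and edge cases

* All probability arithmetic in log space; inclusion Bayes factors
  with a zero-probability complement return +inf explicitly.
* Spike-held parameters are never treated as densities; a fully spiked
  model's marginal likelihood is its likelihood at the spike point.
* Empty datasets have log-likelihood 0, so prior-only sampling is the
  empty-data special case of the same code path.
* Administrative censoring at a look replaces `(t > tau)` rows with
  `(tau, censored)`; the operation is idempotent and event counts are
  non-decreasing across looks.
* Fixed-n BFDA replicates whose ensemble fit fails are dropped and
  counted (`n_failed`); monitoring flags a failed look and continues.
* MLE fits for AIC/BIC use Nelder-Mead on `(alpha, beta, log gamma)`
  with observed-information standard errors; k = 2 parameters for the
  exponential family, 3 otherwise.

## Known limitations

* Laplace marginal likelihoods are a surrogate; although validated
  against bridge sampling at full trial size, extremely small or
  nearly-eventless datasets push posteriors away from Gaussianity.
  Replicates in that regime contribute Monte Carlo noise rather than
  bias in rate estimates (cross-checked against bridge on the worst
  cases in the suite).
* The sequential freeze at 1/15–15 carries the last Bayes factor
  forward; a trajectory that would have re-entered the range is not
  resumed.
* The meta-analytic prior builder is the simplified normal–normal
  construction described above, not a full hierarchical MCMC.
* Proportional-hazards parameterizations, covariates beyond one binary
  arm, frailties, and interval censoring are out of scope.
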