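# survbma

Informed Bayesian model-averaged parametric survival analysis for
two-arm clinical trials: estimation, hypothesis testing, design
analysis, and sequential evidence monitoring, built for
biostatisticians planning or re-analyzing time-to-event studies who
want Bayes factors and model-averaging without committing to a single
parametric family.

## The model

Survival times follow one of five accelerated failure time (AFT)
families — exponential, Weibull, log-normal, log-logistic, gamma —
sharing the log-scale linear predictor

    eta_i = alpha_d + beta * x_i,    beta = log(AF),

where `x_i` codes the treatment arm and the acceleration factor AF is
the multiplicative survival-time ratio between arms (AF > 1 means
longer survival). Right censoring enters the likelihood as

    p(data | theta_d, M_d) = prod_i h_d(t_i | x_i)^{I(c_i = 1)} S_d(t_i | x_i).

Each family `d`, with its priors, is a model `M_d`; its marginal
likelihood `p(data | M_d)` (estimated by bridge sampling, a validated
Laplace surrogate, or quadrature) measures prior predictive
performance. Testing pits five null models (spike `beta = 0`) against
five informed alternatives (`beta ~ N(0.30, 0.15)` truncated to
positive values) and reports the **inclusion Bayes factor**

    BF_10 = [post. odds of alternative models] / [prior odds],

which is robust to misspecification of any single family because every
family appears on both sides. Estimation averages `beta` posteriors
across families weighted by posterior model probabilities. Bayes
Factor Design Analysis (BFDA) simulates trials from the prior
predictive distribution under both scenarios to estimate
misleading-evidence rates and calibrate decision boundaries, for both
fixed-n analyses and monthly sequential monitoring. See
`docs/methods.md` for details.

## Worked example

Simulate a colon-cancer-like trial (2070 participants, 5-year horizon,
true log(AF) = 0.2) and test for a treatment effect:

```python
import survbma as sb

ds = sb.generate_trial(sb.colon_like(log_af=0.2), seed=11)
res = sb.EnsembleModel(ds, ensemble="testing").fit(method="laplace", seed=1)
print(res.summary()[["prior_prob", "post_prob", "log_marglik", "incl_bf"]].round(3))
print(f"inclusion BF10 = {res.inclusion_bf_effect:.2f}")
```

```
                          prior_prob  post_prob  log_marglik  incl_bf
model
exponential[null]                0.1      0.000    -5153.111    0.000
weibull[null]                    0.1      0.000    -5154.263    0.000
lognormal[null]                  0.1      0.187    -5141.473    2.066
loglogistic[null]                0.1      0.000    -5150.592    0.000
gamma[null]                      0.1      0.000    -5154.912    0.000
exponential[alternative]         0.1      0.000    -5151.845    0.000
weibull[alternative]             0.1      0.000    -5152.945    0.000
lognormal[alternative]           0.1      0.813    -5140.002   39.175
loglogistic[alternative]         0.1      0.000    -5149.083    0.001
gamma[alternative]               0.1      0.000    -5153.619    0.000
inclusion BF10 = 4.36
```

The data were generated from a log-normal family, and the ensemble
correctly concentrates its posterior mass there (0.187 + 0.813 = 1.00
on the two log-normal models); the inclusion Bayes factor of 4.36
says the data are about four times more likely under the models
assuming a positive effect. Estimating the effect size with the
model-averaged estimation ensemble:

```python
est = sb.EnsembleModel(ds, ensemble="estimation").fit(
    method="laplace", seed=2, sample_all=True
)
mix = est.beta_mixture()
lo, hi = mix.credible_interval()
print(f"log(AF) = {mix.mean:.3f}, 95% CI [{lo:.3f}, {hi:.3f}]")
```

```
log(AF) = 0.212, 95% CI [0.016, 0.411]
```

— the posterior mean acceleration factor is exp(0.212) ≈ 1.24, and the
interval covers the generating value 0.2.

The same analyses run from the shell (`survbma test`, `survbma fit`,
`survbma bfda`, `survbma monitor`, `survbma simulate`, `survbma
priors`); every run writes a manifest with its settings and seed.

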