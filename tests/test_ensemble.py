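"""Model-averaging arithmetic, mixtures, curves, AIC/BIC, and the model object."""

import numpy as np
import pytest

import survbma as sb
from survbma.ensemble import (
    EnsembleModel,
    MixturePosterior,
    aic_bic_select,
    averaged_curve,
    averaged_posterior_beta,
    bayes_factor,
    inclusion_bf,
    posterior_model_probs,
)
from survbma.mcmc import PosteriorSamples, SamplerSettings


def test_posterior_probs_identity_under_equal_marginals():
    prior = np.array([0.2, 0.3, 0.5])
    np.testing.assert_allclose(posterior_model_probs([-5.0, -5.0, -5.0], prior), prior)


def test_posterior_probs_analytic_two_models():
    post = posterior_model_probs([np.log(3.0), 0.0], [0.5, 0.5])
    np.testing.assert_allclose(post, [0.75, 0.25], atol=1e-12)


def test_posterior_probs_brute_force_oracle(rng):
    log_mls = rng.uniform(-3, 0, 10)
    prior = rng.dirichlet(np.ones(10))
    raw = np.exp(log_mls) * prior
    np.testing.assert_allclose(
        posterior_model_probs(log_mls, prior), raw / raw.sum(), atol=1e-12
    )


def test_posterior_probs_input_validation():
    with pytest.raises(ValueError):
        posterior_model_probs([0.0, 1.0], [0.5])
    with pytest.raises(ValueError):
        posterior_model_probs([np.nan, 0.0], [0.5, 0.5])


@pytest.mark.parametrize("delta, expected", [(0.0, 1.0), (np.log(10.0), 10.0)])
def test_bayes_factor_values(delta, expected):
    assert bayes_factor(-100.0 + delta, -100.0) == pytest.approx(expected)


def test_bayes_factor_equals_odds_ratio(rng):
    """BF = posterior odds / prior odds for arbitrary prior probabilities."""
    for _ in range(20):
        lm = rng.uniform(-5, 0, 2)
        p1 = rng.uniform(0.05, 0.95)
        prior = np.array([p1, 1 - p1])
        post = posterior_model_probs(lm, prior)
        via_odds = (post[0] / post[1]) / (prior[0] / prior[1])
        assert bayes_factor(lm[0], lm[1]) == pytest.approx(via_odds, rel=1e-12)


def test_inclusion_bf_identity_and_analytic():
    prior = np.array([0.1] + [0.9 / 9] * 9)
    assert inclusion_bf(prior, prior, [0]) == pytest.approx(1.0)
    assert inclusion_bf([0.1, 0.9], [0.5, 0.5], [0]) == pytest.approx(9.0)


def test_inclusion_bf_marginal_likelihood_oracle(rng):
    """Inclusion BF equals the prior-weighted marginal-likelihood ratio."""
    log_mls = rng.uniform(-4, 0, 10)
    prior = rng.dirichlet(np.ones(10))
    post = posterior_model_probs(log_mls, prior)
    subset = [0, 3, 7]
    comp = [i for i in range(10) if i not in subset]
    ml = np.exp(log_mls)
    direct = (ml[subset] @ prior[subset] / prior[subset].sum()) / (
        ml[comp] @ prior[comp] / prior[comp].sum()
    )
    assert inclusion_bf(prior, post, subset) == pytest.approx(direct, rel=1e-10)


def test_inclusion_bf_rejects_improper_subsets():
    prior = np.array([0.5, 0.5])
    with pytest.raises(ValueError):
        inclusion_bf(prior, prior, [])
    with pytest.raises(ValueError):
        inclusion_bf(prior, prior, [0, 1])


def test_inclusion_bf_round_trips(null_trial):
    """Family and single-model inclusion BFs invert back to posterior probs."""
    res = EnsembleModel(null_trial).fit(seed=1)
    prior = res.prior_probs
    # effect inclusion: BF x prior odds = posterior odds
    alt = [i for i, m in enumerate(res.specs) if not m.is_null]
    bf = res.inclusion_bf_effect
    prior_odds = prior[alt].sum() / (1 - prior[alt].sum())
    post_odds = res.posterior_probs[alt].sum() / (1 - res.posterior_probs[alt].sum())
    assert bf * prior_odds == pytest.approx(post_odds, rel=1e-10)
    # single-model inclusion BFs invert to posterior probabilities
    for i, bf_m in enumerate(res.model_inclusion_bfs()):
        odds = bf_m * prior[i] / (1 - prior[i])
        assert odds / (1 + odds) == pytest.approx(res.posterior_probs[i], rel=1e-10)
    # family inclusion BFs invert to family posterior probabilities
    fam_probs = res.family_posterior_probs()
    for fam_name, bf_f in res.family_inclusion_bfs().items():
        prior_f = sum(p for p, m in zip(prior, res.specs) if m.family.value == fam_name)
        odds = bf_f * prior_f / (1 - prior_f)
        assert odds / (1 + odds) == pytest.approx(fam_probs[fam_name], rel=1e-10)


def _fake_samples(draws):
    draws = np.asarray(draws, dtype=float)
    return PosteriorSamples(
        names=["beta"],
        unconstrained=draws.reshape(1, -1, 1),
        constrained={"beta": draws},
        rhat={"beta": 1.0},
        ess={"beta": float(len(draws))},
    )


def test_mixture_single_component_identity():
    draws = np.random.default_rng(3).normal(0.2, 0.1, 4000)
    mix = averaged_posterior_beta([_fake_samples(draws)], [1.0])
    assert mix.mean == pytest.approx(draws.mean())
    lo, hi = mix.credible_interval()
    # agreement up to the order-statistic resolution of 4000 draws
    assert lo == pytest.approx(np.quantile(draws, 0.025), abs=2e-3)
    assert hi == pytest.approx(np.quantile(draws, 0.975), abs=2e-3)


def test_mixture_mean_linearity(rng):
    a = rng.normal(-1, 0.1, 3000)
    b = rng.normal(1, 0.1, 3000)
    w = np.array([0.3, 0.7])
    mix = averaged_posterior_beta([_fake_samples(a), _fake_samples(b)], w)
    assert mix.mean == pytest.approx(w[0] * a.mean() + w[1] * b.mean(), abs=1e-10)


def test_bimodal_mixture_interval_covers_both_modes(rng):
    a = rng.normal(-1, 0.1, 5000)
    b = rng.normal(1, 0.1, 5000)
    mix = averaged_posterior_beta([_fake_samples(a), _fake_samples(b)], [0.5, 0.5])
    lo, hi = mix.credible_interval()
    assert lo < -0.8 and hi > 0.8
    # pooled-sample quantile oracle
    pooled = np.concatenate([a, b])
    assert lo == pytest.approx(np.quantile(pooled, 0.025), abs=0.02)
    assert hi == pytest.approx(np.quantile(pooled, 0.975), abs=0.02)


def test_all_null_mixture_is_an_error():
    with pytest.raises(ValueError):
        averaged_posterior_beta([], [])


def test_averaged_curve_properties(small_trial):
    res = EnsembleModel(small_trial, ensemble="estimation").fit(
        seed=3, sample_all=True,
        sampler_settings=SamplerSettings(chains=2, warmup=300, draws=400, seed=3),
    )
    grid = np.linspace(0.0, 1825.0, 40)
    curve = res.averaged_curve(grid, arm=0)
    assert curve.estimate[0] == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(curve.estimate) <= 1e-9)
    assert np.all(curve.lower <= curve.estimate + 1e-12)
    assert np.all(curve.estimate <= curve.upper + 1e-12)


def test_averaged_curve_degenerate_weight_returns_component(small_trial):
    res = EnsembleModel(small_trial, ensemble="estimation").fit(
        seed=4, sample_all=True,
        sampler_settings=SamplerSettings(chains=2, warmup=300, draws=400, seed=4),
    )
    grid = np.linspace(0.0, 1000.0, 10)
    alt = [i for i, m in enumerate(res.specs) if not m.is_null]
    w = np.zeros(len(alt))
    w[0] = 1.0
    one = averaged_curve(
        [res.specs[i] for i in alt], [res.samples[i] for i in alt], w, grid, seed=1
    )
    only = averaged_curve(
        [res.specs[alt[0]]], [res.samples[alt[0]]], [1.0], grid, seed=1
    )
    np.testing.assert_allclose(one.estimate, only.estimate, rtol=1e-10)


def test_aic_bic_structure_and_nesting(small_trial):
    table = aic_bic_select(small_trial)
    assert table.loc["exponential", "k"] == 2
    for family in ("weibull", "lognormal", "loglogistic", "gamma"):
        assert table.loc[family, "k"] == 3
    # Weibull nests the exponential, so its max likelihood cannot be lower
    assert table.loc["weibull", "loglik"] >= table.loc["exponential", "loglik"] - 1e-6
    assert table["selected_aic"].sum() == 1
    assert table["selected_bic"].sum() == 1


def test_bic_consistency_on_exponential_data():
    """BIC picks the true (exponential) family in most replicates."""
    hits = 0
    reps = 30
    for rep in range(reps):
        ds = sb.generate_trial(
            sb.colon_like(n_per_arm=500, family=sb.FamilyId.EXPONENTIAL,
                          alpha=7.8, gamma_aux=None, log_af=0.0),
            seed=500 + rep,
        )
        table = aic_bic_select(ds)
        if table["selected_bic"].idxmax() == "exponential":
            hits += 1
    assert hits / reps >= 0.8


def test_null_data_median_inclusion_bf_below_one():
    bfs = []
    for rep in range(20):
        ds = sb.generate_trial(sb.colon_like(n_per_arm=500, log_af=0.0), seed=700 + rep)
        bfs.append(EnsembleModel(ds).fit(seed=rep).inclusion_bf_effect)
    assert np.median(bfs) < 1.0


def test_results_summary_and_serialization(null_trial, tmp_path):
    res = EnsembleModel(null_trial).fit(seed=9)
    table = res.summary()
    assert len(table) == 10
    assert table["post_prob"].sum() == pytest.approx(1.0, abs=1e-12)
    assert (table["incl_bf"] > 0).all()
    payload = res.to_dict()
    assert payload["inclusion_bf_effect"] == pytest.approx(res.inclusion_bf_effect)
    res.to_json(tmp_path / "out.json")
    assert (tmp_path / "out.json").exists()
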