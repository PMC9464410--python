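"""AFT family definitions: closed forms, nesting, and the acceleration identity."""

import numpy as np
import pytest
from scipy import integrate, stats

from survbma.families import (
    FAMILIES,
    FamilyId,
    FamilyParams,
    linear_predictor,
    log_density,
    log_hazard,
    log_survival,
    mean_survival,
    quantile,
    random_times,
    survival,
)

DEFAULT_PARAMS = {
    FamilyId.EXPONENTIAL: FamilyParams(8.7, 0.3),
    FamilyId.WEIBULL: FamilyParams(8.8, 0.3, 0.93),
    FamilyId.LOGNORMAL: FamilyParams(8.7, 0.3, 1.86),
    FamilyId.LOGLOGISTIC: FamilyParams(8.54, 0.3, 1.02),
    FamilyId.GAMMA: FamilyParams(8.88, 0.3, 0.9),
}


@pytest.mark.parametrize(
    "alpha, beta, x, expected",
    [(8.7, 0.3, 0, 8.7), (8.7, 0.3, 1, 9.0), (0.0, -0.2, 1, -0.2)],
)
def test_linear_predictor(alpha, beta, x, expected):
    assert linear_predictor(alpha, beta, x) == pytest.approx(expected)


def test_linear_predictor_rejects_nonbinary_arm():
    with pytest.raises(ValueError):
        linear_predictor(8.7, 0.3, 2)


def test_survival_closed_form_anchors():
    # exponential at its scale: S(e^eta) = e^-1
    p = FamilyParams(5.0, 0.0)
    assert survival(FamilyId.EXPONENTIAL, np.exp(5.0), p) == pytest.approx(
        np.exp(-1), abs=1e-12
    )
    # log-normal median at t = e^eta for any sd
    for g in (0.5, 1.9):
        p = FamilyParams(6.0, 0.0, g)
        assert survival(FamilyId.LOGNORMAL, np.exp(6.0), p) == pytest.approx(0.5, abs=1e-12)


def test_weibull_shape_one_is_exponential():
    pw = FamilyParams(7.0, 0.2, 1.0)
    pe = FamilyParams(7.0, 0.2)
    t = np.array([1.0, 100.0, 2000.0])
    for x in (0, 1):
        np.testing.assert_allclose(
            survival(FamilyId.WEIBULL, t, pw, x), survival(FamilyId.EXPONENTIAL, t, pe, x)
        )


@pytest.mark.parametrize("family", FAMILIES)
def test_survival_monotone_and_bounded(family):
    p = DEFAULT_PARAMS[family]
    t = np.linspace(0, 50000, 400)
    s = survival(family, t, p, 0)
    assert s[0] == pytest.approx(1.0)
    assert np.all(np.diff(s) <= 1e-15)
    assert np.all((0 <= s) & (s <= 1))


@pytest.mark.parametrize("family", FAMILIES)
def test_density_integrates_to_one(family):
    p = DEFAULT_PARAMS[family]
    # integrate in log-time to resolve the mass around e^alpha
    val, err = integrate.quad(
        lambda u: np.exp(log_density(family, np.exp(u), p, 0) + u),
        p.alpha - 30.0,
        p.alpha + 30.0,
        limit=200,
    )
    assert val == pytest.approx(1.0, abs=1e-6)


def test_lognormal_log_density_at_median():
    g = 1.86
    p = FamilyParams(8.7, 0.0, g)
    t = np.exp(8.7)
    expected = np.log(1.0 / (t * g * np.sqrt(2 * np.pi)))
    assert log_density(FamilyId.LOGNORMAL, t, p, 0) == pytest.approx(expected, abs=1e-12)


def test_exponential_hazard_is_constant():
    p = FamilyParams(6.5, 0.0)
    for t in (1.0, 50.0, 5000.0):
        assert log_hazard(FamilyId.EXPONENTIAL, t, p, 0) == pytest.approx(-6.5, abs=1e-12)


def test_hazard_equals_density_over_survival(rng):
    """h = f/S across random (family, t, params) triples."""
    for _ in range(100):
        family = FAMILIES[rng.integers(len(FAMILIES))]
        p = FamilyParams(
            rng.normal(8, 1),
            rng.normal(0, 0.3),
            None if family is FamilyId.EXPONENTIAL else float(rng.uniform(0.5, 2.5)),
        )
        t = float(np.exp(p.alpha) * rng.uniform(0.05, 3.0))
        lh = log_hazard(family, t, p, 0)
        direct = log_density(family, t, p, 0) - log_survival(family, t, p, 0)
        assert lh == pytest.approx(direct, rel=1e-8)


@pytest.mark.parametrize("family", FAMILIES)
def test_aft_identity(family):
    """S(t | x=1) = S(t e^{-beta} | x=0): the defining acceleration property."""
    p = DEFAULT_PARAMS[family]
    t = np.exp(p.alpha) * np.array([0.01, 0.3, 1.0, 2.5, 10.0])
    s1 = survival(family, t, p, 1)
    s0 = survival(family, t * np.exp(-p.beta), p, 0)
    np.testing.assert_allclose(s1, s0, atol=1e-12)


@pytest.mark.parametrize("family", FAMILIES)
def test_positive_effect_lengthens_survival(family):
    p = DEFAULT_PARAMS[family]  # beta = 0.3 > 0
    t = np.exp(p.alpha) * np.array([0.1, 1.0, 3.0])
    assert np.all(survival(family, t, p, 1) > survival(family, t, p, 0))


@pytest.mark.parametrize(
    "family, params, expected",
    [
        (FamilyId.EXPONENTIAL, FamilyParams(np.log(100.0), 0.0), 100.0),
        (FamilyId.WEIBULL, FamilyParams(6.0, 0.0, 1.0), np.exp(6.0)),
        (FamilyId.GAMMA, FamilyParams(5.0, 0.0, 2.0), 2.0 * np.exp(5.0)),
    ],
)
def test_mean_survival_closed_forms(family, params, expected):
    assert mean_survival(family, params, 0) == pytest.approx(expected)


def test_loglogistic_mean_requires_shape_above_one():
    with pytest.raises(ValueError):
        mean_survival(FamilyId.LOGLOGISTIC, FamilyParams(8.0, 0.0, 0.9), 0)


@pytest.mark.parametrize("family", FAMILIES)
def test_monte_carlo_mean_matches_closed_form(family):
    p = DEFAULT_PARAMS[family]
    if family is FamilyId.LOGLOGISTIC:
        p = FamilyParams(p.alpha, p.beta, 1.6)  # mean needs shape > 1
    draws = random_times(family, p, 0, n=100_000, seed=7)
    se = draws.std(ddof=1) / np.sqrt(draws.size)
    assert abs(draws.mean() - mean_survival(family, p, 0)) < 3 * se


@pytest.mark.parametrize("family", FAMILIES)
def test_random_times_deterministic_and_distributed(family):
    p = DEFAULT_PARAMS[family]
    a = random_times(family, p, 1, n=10_000, seed=11)
    b = random_times(family, p, 1, n=10_000, seed=11)
    np.testing.assert_array_equal(a, b)
    # KS against the analytic CDF
    d = stats.kstest(a, lambda t: 1.0 - survival(family, t, p, 1)).statistic
    assert d < 1.63 / np.sqrt(a.size)  # 1% critical value


def test_weibull_draws_nest_exponential_under_shared_stream():
    pe = FamilyParams(7.5, 0.1)
    pw = FamilyParams(7.5, 0.1, 1.0)
    a = random_times(FamilyId.EXPONENTIAL, pe, 1, n=500, seed=3)
    b = random_times(FamilyId.WEIBULL, pw, 1, n=500, seed=3)
    np.testing.assert_allclose(a, b, rtol=1e-12)


def test_quantile_inverts_cdf():
    p = DEFAULT_PARAMS[FamilyId.GAMMA]
    q = np.array([0.1, 0.5, 0.9])
    t = quantile(FamilyId.GAMMA, q, p, 0)
    np.testing.assert_allclose(1.0 - survival(FamilyId.GAMMA, t, p, 0), q, atol=1e-10)


def test_domain_errors():
    p = DEFAULT_PARAMS[FamilyId.WEIBULL]
    with pytest.raises(ValueError):
        survival(FamilyId.WEIBULL, -1.0, p, 0)
    with pytest.raises(ValueError):
        log_density(FamilyId.WEIBULL, 0.0, p, 0)
    with pytest.raises(ValueError):
        FamilyParams(8.0, 0.0, -1.0)
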