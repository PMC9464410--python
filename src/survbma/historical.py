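"""Meta-analytic predictive (MAP) priors from historical datasets.

Historical participant-level trials are each reduced to a maximum-
likelihood estimate (with standard error) of the intercept or
log-auxiliary parameter under the pooled null model, then combined in a
normal-normal hierarchical model: study-level parameters are
N(mu, tau^2) around an overall mean with between-study heterogeneity
tau, which gets a half-normal prior. The predictive distribution for a
new study integrates N(mu, tau^2) over the joint posterior of (mu, tau)
and is summarized by a moment-matched normal — wider than the posterior
of mu itself because heterogeneity is passed on, which is exactly how a
MAP prior discounts dissimilar historical data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .data import SurvivalDataset
from .families import FamilyId, FamilyParams, has_aux
from .likelihood import _num_hessian, log_likelihood
from .priors import PriorSpec, normal

__all__ = ["StudyEstimate", "PredictivePrior", "fit_study", "predictive_prior"]

MIN_EVENTS = 20


@dataclass(frozen=True)
class StudyEstimate:
    study_id: str
    family: FamilyId
    parameter: str  # "alpha" or "log_gamma"
    estimate: float
    se: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if self.parameter not in ("alpha", "log_gamma"):
            raise ValueError("parameter must be 'alpha' or 'log_gamma'")


@dataclass(frozen=True)
class PredictivePrior:
    parameter: str
    location: float
    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def as_prior(self) -> PriorSpec:
        return normal(self.location, self.scale)


def fit_study(
    dataset: SurvivalDataset, family: FamilyId, study_id: str = "study"
) -> tuple[StudyEstimate, StudyEstimate | None]:
    """Pooled null-model MLE of (alpha, log gamma) with observed-information SEs.

    Arms are pooled (no treatment effect in the historical fit). Studies
    with fewer than 20 events are rejected — too little information for
    a stable curvature estimate.
    """
    family = FamilyId(family)
    if dataset.n_events < MIN_EVENTS:
        raise ValueError(
            f"historical study needs >= {MIN_EVENTS} events, got {dataset.n_events}"
        )
    pooled = SurvivalDataset(dataset.times, dataset.events, np.zeros(len(dataset), int),
                             dataset.horizon)
    k = 2 if has_aux(family) else 1

    def loglik(u):
        g = math.exp(u[1]) if k == 2 else None
        try:
            return log_likelihood(pooled, family, FamilyParams(u[0], 0.0, g))
        except (ValueError, FloatingPointError):
            return -1e12

    x0 = np.array([math.log(pooled.times.sum() / max(pooled.n_events, 1)), 0.0][:k])
    res = optimize.minimize(lambda u: -loglik(u), x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    if not res.success:
        raise RuntimeError(f"MLE optimization failed for {family}: {res.message}")
    info = -_num_hessian(loglik, res.x)
    cov = np.linalg.inv(info)
    ses = np.sqrt(np.diag(cov))
    alpha_est = StudyEstimate(study_id, family, "alpha", float(res.x[0]), float(ses[0]))
    gamma_est = (
        StudyEstimate(study_id, family, "log_gamma", float(res.x[1]), float(ses[1]))
        if k == 2
        else None
    )
    return alpha_est, gamma_est


def predictive_prior(
    estimates: list[StudyEstimate],
    heterogeneity_prior_scale: float = 0.5,
    grid_size: int = 200,
) -> PredictivePrior:
    """MAP prior from k >= 2 study estimates of the same parameter.

    Normal-normal hierarchy with a flat prior on the overall mean mu and
    a half-normal(heterogeneity_prior_scale) prior on tau, evaluated on
    a 2-d grid. The predictive N(mu, tau^2) for a new study is averaged
    over the (mu, tau) posterior and moment-matched to a normal:
    location = E[mu], scale^2 = Var[mu] + E[tau^2].
    """
    if len(estimates) < 2:
        raise ValueError(
            "need at least 2 historical studies; with fewer, specify the prior directly"
        )
    params = {e.parameter for e in estimates}
    if len(params) > 1:
        raise ValueError(f"mixed parameters in meta-analysis: {params}")
    y = np.array([e.estimate for e in estimates])
    v = np.array([e.se**2 for e in estimates])

    span = 6.0 * math.sqrt(v.max() + heterogeneity_prior_scale**2 + np.var(y))
    mus = np.linspace(y.mean() - span, y.mean() + span, grid_size)
    taus = np.linspace(1e-6, 4.0 * heterogeneity_prior_scale + 2.0 * y.std(ddof=0), grid_size)
    mu_g, tau_g = np.meshgrid(mus, taus, indexing="ij")
    # marginal likelihood of (mu, tau): y_k ~ N(mu, v_k + tau^2)
    log_post = np.zeros_like(mu_g)
    for yk, vk in zip(y, v):
        var = vk + tau_g**2
        log_post += -0.5 * np.log(2 * math.pi * var) - 0.5 * (yk - mu_g) ** 2 / var
    log_post += -0.5 * (tau_g / heterogeneity_prior_scale) ** 2  # half-normal tau prior
    w = np.exp(log_post - log_post.max())
    w /= w.sum()
    e_mu = float(np.sum(w * mu_g))
    var_mu = float(np.sum(w * (mu_g - e_mu) ** 2))
    e_tau2 = float(np.sum(w * tau_g**2))
    return PredictivePrior(
        parameter=estimates[0].parameter,
        location=e_mu,
        scale=math.sqrt(var_mu + e_tau2),
    )
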