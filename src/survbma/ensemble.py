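"""Bayesian model-averaging over AFT survival models.

The central objects follow the model/results convention of statistical
modelling packages: :class:`EnsembleModel` is built from a dataset and a
prior table and its :meth:`~EnsembleModel.fit` returns
:class:`EnsembleResults` carrying per-model marginal likelihoods,
posterior model probabilities, inclusion Bayes factors, the mixture
posterior of the treatment effect, and model-averaged survival/hazard
curves.

Model-level arithmetic: posterior model probabilities are the softmax of
log marginal likelihood plus log prior probability; a Bayes factor is a
ratio of marginal likelihoods; an inclusion Bayes factor compares a
model subset to its complement through posterior over prior inclusion
odds. All of it runs in log space.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from . import families as fam
from .data import SurvivalDataset
from .likelihood import log_likelihood
from .marglik import (
    MarginalLikelihoodResult,
    log_marginal_bridge,
    log_marginal_laplace,
)
from .mcmc import PosteriorSamples, SamplerSettings, sample_posterior
from .models import ModelSpec, estimation_ensemble, testing_ensemble
from .priors import PriorTable, default_prior_table

__all__ = [
    "posterior_model_probs",
    "bayes_factor",
    "inclusion_bf",
    "MixturePosterior",
    "averaged_posterior_beta",
    "AveragedCurve",
    "averaged_curve",
    "aic_bic_select",
    "EnsembleModel",
    "EnsembleResults",
]


# ---------------------------------------------------------------- arithmetic


def posterior_model_probs(log_mls, prior_probs) -> np.ndarray:
    """Posterior model probabilities: softmax of log_ml + log prior prob."""
    log_mls = np.asarray(log_mls, dtype=float)
    prior_probs = np.asarray(prior_probs, dtype=float)
    if log_mls.shape != prior_probs.shape:
        raise ValueError("log_mls and prior_probs must have equal length")
    if not np.all(np.isfinite(log_mls)):
        raise ValueError("non-finite log marginal likelihood")
    if abs(prior_probs.sum() - 1.0) > 1e-8:
        raise ValueError("prior probabilities must sum to 1")
    w = log_mls + np.log(prior_probs)
    return np.exp(w - logsumexp(w))


def bayes_factor(log_ml_1: float, log_ml_0: float) -> float:
    """BF_10 = exp(log_ml_1 - log_ml_0)."""
    if not (np.isfinite(log_ml_1) and np.isfinite(log_ml_0)):
        raise ValueError("non-finite log marginal likelihoods")
    return math.exp(log_ml_1 - log_ml_0)


def inclusion_bf(prior_probs, posterior_probs, subset) -> float:
    """Inclusion Bayes factor of a model subset against its complement.

    (posterior odds of subset vs complement) / (prior odds of subset vs
    complement). A zero-posterior complement yields +inf.
    """
    prior_probs = np.asarray(prior_probs, dtype=float)
    posterior_probs = np.asarray(posterior_probs, dtype=float)
    idx = np.zeros(prior_probs.size, dtype=bool)
    idx[list(subset)] = True
    if not idx.any() or idx.all():
        raise ValueError("subset must be a non-empty proper subset")
    post_in, post_out = posterior_probs[idx].sum(), posterior_probs[~idx].sum()
    prior_in, prior_out = prior_probs[idx].sum(), prior_probs[~idx].sum()
    if post_out == 0.0:
        return math.inf
    return (post_in / post_out) / (prior_in / prior_out)


# ------------------------------------------------------------------ mixtures


@dataclass
class MixturePosterior:
    """Posterior of the effect as a mixture over alternative models."""

    component_draws: list[np.ndarray]
    weights: np.ndarray
    labels: list[str]
    draws: np.ndarray = field(init=False)
    resample_seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("mixture weights must sum to 1")
        self.weights = w
        # stratified resampling proportional to the weights, fixed seed
        rng = np.random.default_rng(self.resample_seed)
        size = max(len(d) for d in self.component_draws)
        counts = np.floor(w * size).astype(int)
        rem = size - counts.sum()
        if rem > 0:
            frac = w * size - np.floor(w * size)
            counts[np.argsort(-frac)[:rem]] += 1
        parts = [
            rng.choice(d, size=c, replace=True)
            for d, c in zip(self.component_draws, counts)
            if c > 0
        ]
        self.draws = rng.permutation(np.concatenate(parts)) if parts else np.empty(0)

    @property
    def mean(self) -> float:
        return float(sum(w * d.mean() for w, d in zip(self.weights, self.component_draws)))

    def credible_interval(self, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        lo, hi = _mixture_quantiles(self.component_draws, self.weights, [a, 1.0 - a])
        return float(lo), float(hi)


def _mixture_quantiles(component_draws, weights, qs) -> np.ndarray:
    """Exact weighted-pooled quantiles of a mixture of empirical samples."""
    vals = np.concatenate(component_draws)
    wts = np.concatenate(
        [np.full(len(d), w / len(d)) for d, w in zip(component_draws, weights)]
    )
    order = np.argsort(vals)
    vals, wts = vals[order], wts[order]
    cdf = np.cumsum(wts)
    cdf /= cdf[-1]
    return np.interp(qs, cdf, vals)


def averaged_posterior_beta(
    samples: list[PosteriorSamples],
    posterior_probs,
    labels: list[str] | None = None,
    resample_seed: int = 0,
) -> MixturePosterior:
    """Model-averaged posterior of log(AF) across alternative models.

    Weights are the posterior model probabilities renormalized over the
    supplied (alternative) models.
    """
    w = np.asarray(posterior_probs, dtype=float)
    if len(samples) == 0:
        raise ValueError("no alternative models to average over")
    if w.sum() <= 0:
        raise ValueError("all-null ensemble: no posterior mass on alternative models")
    w = w / w.sum()
    draws = [s.constrained["beta"] for s in samples]
    labels = labels or [f"component{i}" for i in range(len(samples))]
    return MixturePosterior(draws, w, labels, resample_seed=resample_seed)


# -------------------------------------------------------------------- curves


@dataclass(frozen=True)
class AveragedCurve:
    """Pointwise mixture estimate and credible band of S or h on a grid."""

    grid: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    arm: int
    kind: str


def averaged_curve(
    models: list[ModelSpec],
    samples: list[PosteriorSamples],
    posterior_probs,
    grid,
    arm: int = 0,
    kind: str = "survival",
    max_draws_per_model: int = 500,
    seed: int = 0,
) -> AveragedCurve:
    """Model-averaged survival or hazard curve with 95% pointwise band.

    Pools posterior draws of the curve across models in proportion to
    the posterior model probabilities and reports the pointwise mixture
    mean and 2.5/97.5% quantiles.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("time grid must be nonnegative")
    if kind not in ("survival", "hazard"):
        raise ValueError("kind must be 'survival' or 'hazard'")
    w = np.asarray(posterior_probs, dtype=float)
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    curves, weights = [], []
    for model, s, wi in zip(models, samples, w):
        if wi <= 0:
            continue
        n = len(s.constrained["alpha"])
        take = rng.choice(n, size=min(n, max_draws_per_model), replace=False)
        for i in take:
            params = fam.FamilyParams(
                alpha=float(s.constrained["alpha"][i]),
                beta=float(s.constrained.get("beta", np.zeros(n))[i]),
                gamma_aux=(
                    float(s.constrained["gamma_aux"][i]) if "gamma_aux" in s.constrained else None
                ),
            )
            if kind == "survival":
                y = fam.survival(model.family, grid, params, arm)
            else:
                pos = np.maximum(grid, 1e-12)
                y = np.exp(fam.log_hazard(model.family, pos, params, arm))
            curves.append(y)
            weights.append(wi / take.size)
    curves = np.asarray(curves)
    weights = np.asarray(weights)
    weights = weights / weights.sum()
    est = weights @ curves
    lower = np.empty_like(est)
    upper = np.empty_like(est)
    order = np.argsort(curves, axis=0)
    for j in range(grid.size):
        c = curves[order[:, j], j]
        ww = np.cumsum(weights[order[:, j]])
        ww /= ww[-1]
        lower[j], upper[j] = np.interp([0.025, 0.975], ww, c)
    return AveragedCurve(grid, est, lower, upper, arm=arm, kind=kind)


# --------------------------------------------------------- AIC/BIC selection


def aic_bic_select(dataset: SurvivalDataset, families=None) -> pd.DataFrame:
    """Maximum-likelihood fit per family with AIC/BIC model selection.

    Returns one row per family (mle parameters, max log-likelihood, AIC
    = 2k - 2 logL, BIC = k log n - 2 logL) sorted as given; families
    whose optimizer fails are dropped with a warning column. k counts
    (alpha, beta) plus the auxiliary parameter where present.
    """
    families = list(families) if families is not None else list(fam.FamilyId)
    n = len(dataset)
    rows = []
    for family in families:
        family = fam.FamilyId(family)
        k = fam.n_params(family, with_beta=True)
        if n < k:
            raise ValueError("need at least as many observations as parameters")

        def nll(u, family=family):
            alpha, beta = u[0], u[1]
            g = math.exp(u[2]) if fam.has_aux(family) else None
            try:
                return -log_likelihood(
                    dataset, family, fam.FamilyParams(alpha, beta, g)
                )
            except (ValueError, FloatingPointError):
                return 1e12

        ev = max(dataset.n_events, 1)
        x0 = [math.log(dataset.times.sum() / ev), 0.0]
        if fam.has_aux(family):
            x0.append(0.0)
        res = optimize.minimize(nll, np.asarray(x0), method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if not res.success or not np.isfinite(res.fun):
            import warnings

            warnings.warn(f"MLE failed for {family}; dropped from selection")
            continue
        logl = -float(res.fun)
        from .likelihood import _num_hessian

        info = _num_hessian(nll, res.x)  # observed information (nll curvature)
        try:
            beta_se = float(np.sqrt(np.linalg.inv(info)[1, 1]))
        except (np.linalg.LinAlgError, ValueError):
            beta_se = np.nan
        rows.append(
            {
                "family": family.value,
                "alpha": float(res.x[0]),
                "beta": float(res.x[1]),
                "beta_se": beta_se,
                "gamma_aux": float(math.exp(res.x[2])) if fam.has_aux(family) else np.nan,
                "k": k,
                "loglik": logl,
                "aic": 2 * k - 2 * logl,
                "bic": k * math.log(n) - 2 * logl,
            }
        )
    df = pd.DataFrame(rows).set_index("family")
    df["selected_aic"] = df["aic"] == df["aic"].min()
    df["selected_bic"] = df["bic"] == df["bic"].min()
    return df


# ------------------------------------------------------------ model/results


class EnsembleModel:
    """Bayesian model-averaged AFT survival model.

    Parameters
    ----------
    dataset : SurvivalDataset
        Right-censored two-arm data.
    prior_table : PriorTable, optional
        Priors per family and for the effect; defaults to the informed
        colon-cancer table.
    ensemble : {"testing", "estimation"}
        ``testing`` pits five null against five alternative models and
        yields the inclusion Bayes factor for the effect; ``estimation``
        averages five alternative models under a weakly informative
        effect prior.
    """

    def __init__(
        self,
        dataset: SurvivalDataset,
        prior_table: PriorTable | None = None,
        ensemble: str = "testing",
    ):
        if ensemble not in ("testing", "estimation"):
            raise ValueError("ensemble must be 'testing' or 'estimation'")
        self.dataset = dataset
        self.prior_table = prior_table or default_prior_table()
        self.ensemble = ensemble
        builder = testing_ensemble if ensemble == "testing" else estimation_ensemble
        self.model_specs: list[ModelSpec] = builder(self.prior_table)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time: str = "time",
        status: str = "status",
        arm: str = "arm",
        horizon: float | None = None,
        **kwargs,
    ) -> "EnsembleModel":
        return cls(SurvivalDataset.from_dataframe(df, time, status, arm, horizon), **kwargs)

    def fit(
        self,
        method: str = "laplace",
        seed: int | None = None,
        sampler_settings: SamplerSettings | None = None,
        sample_all: bool = False,
        force: bool = False,
    ) -> "EnsembleResults":
        """Fit every model and assemble the averaged results.

        ``method='laplace'`` fits each model by posterior-mode
        optimization (fast; the design-analysis default);
        ``method='bridge'`` runs MCMC plus bridge sampling per model.
        ``sample_all=True`` additionally draws posterior samples for all
        models when using Laplace (needed for mixture summaries and
        curves; the testing decision itself needs none).
        """
        if method not in ("laplace", "bridge"):
            raise ValueError("method must be 'laplace' or 'bridge'")
        mls: list[MarginalLikelihoodResult] = []
        samples: list[PosteriorSamples | None] = []
        rng = np.random.default_rng(seed)
        for spec in self.model_specs:
            sub_seed = int(rng.integers(2**31 - 1))
            if method == "bridge" or sample_all:
                settings = sampler_settings or SamplerSettings(seed=sub_seed)
                if settings.seed is None:
                    settings = SamplerSettings(
                        settings.chains, settings.warmup, settings.draws, sub_seed
                    )
                smp = sample_posterior(self.dataset, spec, settings)
                samples.append(smp)
            else:
                samples.append(None)
            if method == "bridge":
                mls.append(
                    log_marginal_bridge(
                        self.dataset, spec, samples=samples[-1], seed=sub_seed, force=force
                    )
                )
            else:
                mls.append(log_marginal_laplace(self.dataset, spec))
        return EnsembleResults(self, mls, samples, method=method, seed=seed)


class EnsembleResults:
    """Fitted ensemble: probabilities, Bayes factors, mixtures, curves."""

    def __init__(self, model: EnsembleModel, mls, samples, method: str, seed=None):
        self.model = model
        self.ml_results = list(mls)
        self.samples = list(samples)
        self.method = method
        self.seed = seed
        self.log_mls = np.array([r.log_ml for r in mls])
        self.prior_probs = np.array([m.prior_prob for m in model.model_specs])
        self.posterior_probs = posterior_model_probs(self.log_mls, self.prior_probs)

    # ---- membership helpers
    @property
    def specs(self) -> list[ModelSpec]:
        return self.model.model_specs

    def _alt_idx(self):
        return [i for i, m in enumerate(self.specs) if not m.is_null]

    # ---- Bayes factors
    @property
    def inclusion_bf_effect(self) -> float:
        """Inclusion BF for the presence of the treatment effect (BF_10)."""
        alt = self._alt_idx()
        if not alt or len(alt) == len(self.specs):
            raise ValueError("inclusion BF for the effect needs both null and alternative models")
        return inclusion_bf(self.prior_probs, self.posterior_probs, alt)

    def family_inclusion_bfs(self) -> dict[str, float]:
        """Inclusion BF of each parametric family against the other families."""
        out = {}
        for family in fam.FamilyId:
            idx = [i for i, m in enumerate(self.specs) if m.family is family]
            out[family.value] = inclusion_bf(self.prior_probs, self.posterior_probs, idx)
        return out

    def model_inclusion_bfs(self) -> np.ndarray:
        """Inclusion BF of each single model against the rest of the ensemble."""
        return np.array(
            [
                inclusion_bf(self.prior_probs, self.posterior_probs, [i])
                for i in range(len(self.specs))
            ]
        )

    def family_posterior_probs(self) -> dict[str, float]:
        return {
            family.value: float(
                sum(
                    p
                    for p, m in zip(self.posterior_probs, self.specs)
                    if m.family is family
                )
            )
            for family in fam.FamilyId
        }

    # ---- mixture posterior of the effect
    def _require_samples(self):
        alt = self._alt_idx()
        missing = [i for i in alt if self.samples[i] is None]
        if missing:
            raise RuntimeError(
                "posterior draws unavailable; refit with method='bridge' or sample_all=True"
            )
        return alt

    def beta_mixture(self, resample_seed: int = 0) -> MixturePosterior:
        alt = self._require_samples()
        return averaged_posterior_beta(
            [self.samples[i] for i in alt],
            self.posterior_probs[alt],
            labels=[self.specs[i].name for i in alt],
            resample_seed=resample_seed,
        )

    def averaged_curve(self, grid, arm=0, kind="survival", seed=0) -> AveragedCurve:
        alt = self._require_samples()
        return averaged_curve(
            [self.specs[i] for i in alt],
            [self.samples[i] for i in alt],
            self.posterior_probs[alt],
            grid,
            arm=arm,
            kind=kind,
            seed=seed,
        )

    # ---- reporting
    def summary(self) -> pd.DataFrame:
        """Per-model table: priors, probabilities, log marglik, inclusion BF."""
        rows = []
        incl = self.model_inclusion_bfs()
        for m, lm, pp, qp, ib in zip(
            self.specs, self.log_mls, self.prior_probs, self.posterior_probs, incl
        ):
            rows.append(
                {
                    "model": m.name,
                    "family": m.family.value,
                    "prior_beta": str(m.beta_prior),
                    "prior_alpha": str(m.alpha_prior),
                    "prior_gamma": str(m.gamma_prior) if m.gamma_prior else "",
                    "prior_prob": pp,
                    "post_prob": qp,
                    "log_marglik": lm,
                    "incl_bf": ib,
                }
            )
        return pd.DataFrame(rows).set_index("model")

    def to_dict(self) -> dict:
        out = {
            "ensemble": self.model.ensemble,
            "method": self.method,
            "seed": self.seed,
            "models": [m.name for m in self.specs],
            "log_mls": self.log_mls.tolist(),
            "prior_probs": self.prior_probs.tolist(),
            "posterior_probs": self.posterior_probs.tolist(),
            "family_posterior_probs": self.family_posterior_probs(),
            "family_inclusion_bfs": self.family_inclusion_bfs(),
        }
        alt = self._alt_idx()
        if alt and len(alt) < len(self.specs):
            bf10 = self.inclusion_bf_effect
            out["inclusion_bf_effect"] = bf10
            out["log_inclusion_bf_effect"] = math.log(bf10) if bf10 > 0 else -math.inf
        if all(self.samples[i] is not None for i in alt):
            mix = self.beta_mixture()
            lo, hi = mix.credible_interval()
            out["beta"] = {"mean": mix.mean, "ci95": [lo, hi]}
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def plot_survival(self, grid=None, ax=None, seed: int = 0):
        """Model-averaged survival curves with 95% bands, both arms."""
        import matplotlib.pyplot as plt

        if grid is None:
            horizon = self.model.dataset.horizon or float(self.model.dataset.times.max())
            grid = np.linspace(0.0, horizon, 101)
        if ax is None:
            _, ax = plt.subplots()
        for arm, color in ((0, "tab:green"), (1, "tab:purple")):
            curve = self.averaged_curve(grid, arm=arm, seed=seed)
            ax.plot(curve.grid, curve.estimate, color=color, label=f"arm {arm}")
            ax.fill_between(curve.grid, curve.lower, curve.upper, color=color, alpha=0.2)
        ax.set_xlabel("time (days)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1)
        ax.legend()
        return ax
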