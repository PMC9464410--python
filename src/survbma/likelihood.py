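"""Censored log-likelihood and the unconstrained posterior target.

The likelihood of right-censored data factorizes as a product of the
hazard (for observed events) times survival over all participants, so in
log form

    log L = sum_events log f(t_i | x_i) + sum_censored log S(t_i | x_i).

Posterior computations run on an unconstrained parameter vector: the
intercept alpha is untransformed, the auxiliary parameter enters as
log(gamma_aux), and the effect beta is untransformed under a normal
prior or log-transformed under a lower-truncated normal prior (with the
corresponding Jacobian terms added to the prior density).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from . import families as fam
from .data import SurvivalDataset
from .models import ModelSpec
from .priors import PriorSpec, log_prior_density

__all__ = ["log_likelihood", "AFTTarget", "map_fit", "MapFit"]


def log_likelihood(dataset: SurvivalDataset, model: ModelSpec | fam.FamilyId, params) -> float:
    """Censored log-likelihood of ``params`` for the dataset.

    ``model`` may be a ModelSpec or a bare family id; ``params`` is a
    FamilyParams. Empty datasets have log-likelihood 0.
    """
    family = model.family if isinstance(model, ModelSpec) else fam.FamilyId(model)
    if len(dataset) == 0:
        return 0.0
    if not np.isfinite(params.alpha) or not np.isfinite(params.beta):
        raise ValueError("non-finite parameters")
    total = 0.0
    for x in (0, 1):
        in_arm = dataset.arms == x
        ev = in_arm & (dataset.events == 1)
        cens = in_arm & (dataset.events == 0)
        if ev.any():
            total += float(np.sum(fam.log_density(family, dataset.times[ev], params, x)))
        if cens.any():
            total += float(np.sum(fam.log_survival(family, dataset.times[cens], params, x)))
    return total


class _Dim:
    """One free coordinate of the unconstrained target."""

    __slots__ = ("name", "prior", "transform")

    def __init__(self, name: str, prior: PriorSpec, transform: str):
        self.name = name
        self.prior = prior
        self.transform = transform  # "identity" or "log"

    def constrain(self, u):
        return np.exp(u) if self.transform == "log" else u

    def log_prior(self, u: float) -> float:
        """Prior log density on the unconstrained scale (incl. Jacobian)."""
        if self.transform == "identity":
            return self.prior.fast_logpdf(u)
        if self.prior.kind == "lognormal":
            # log-normal on the constrained scale is normal on the log scale
            p = self.prior
            z = (u - p.location) / p.scale
            return -0.5 * z * z - np.log(p.scale) - 0.9189385332046727
        return self.prior.fast_logpdf(np.exp(u)) + u

    def log_prior_vec(self, u: np.ndarray) -> np.ndarray:
        """Vectorized version of :meth:`log_prior`."""
        u = np.asarray(u, dtype=float)
        p = self.prior
        half_log_2pi = 0.9189385332046727
        if self.transform == "log" and p.kind == "lognormal":
            z = (u - p.location) / p.scale
            return -0.5 * z * z - np.log(p.scale) - half_log_2pi
        value = np.exp(u) if self.transform == "log" else u
        if p.kind == "normal":
            z = (value - p.location) / p.scale
            out = -0.5 * z * z - np.log(p.scale) - half_log_2pi
        elif p.kind == "truncated_normal":
            z = (value - p.location) / p.scale
            log_z = float(special.log_ndtr((p.location - p.lower_bound) / p.scale))
            out = np.where(
                value >= p.lower_bound,
                -0.5 * z * z - np.log(p.scale) - half_log_2pi - log_z,
                -np.inf,
            )
        elif p.kind == "lognormal":
            lv = np.log(value)
            z = (lv - p.location) / p.scale
            out = -0.5 * z * z - np.log(p.scale) - half_log_2pi - lv
        else:  # pragma: no cover
            raise ValueError(p.kind)
        if self.transform == "log":
            out = out + u
        return out

    def unconstrained_guess(self) -> float:
        p = self.prior
        if self.transform == "log":
            if p.kind == "lognormal":
                return p.location
            # truncated normal on the positive half line
            return float(np.log(max(p.location, p.scale / 2)))
        return p.location


def _batch_log_density(family, t, eta, g):
    """log f(t) broadcast over (m, 1) params x (1, n) times."""
    logt = np.log(t)
    logz = logt - eta
    if family is fam.FamilyId.EXPONENTIAL:
        return -eta - np.exp(logz)
    if family is fam.FamilyId.WEIBULL:
        return np.log(g) - eta + (g - 1.0) * logz - np.exp(g * logz)
    if family is fam.FamilyId.LOGNORMAL:
        w = logz / g
        return -0.5 * w * w - 0.9189385332046727 - np.log(g) - logt
    if family is fam.FamilyId.LOGLOGISTIC:
        return np.log(g) - eta + (g - 1.0) * logz - 2.0 * np.logaddexp(0.0, g * logz)
    if family is fam.FamilyId.GAMMA:
        return -eta + (g - 1.0) * logz - np.exp(logz) - special.gammaln(g)
    raise ValueError(family)  # pragma: no cover


def _batch_log_survival(family, t, eta, g):
    """log S(t) broadcast over (m, 1) params x (1, n) times."""
    logz = np.log(t) - eta
    if family is fam.FamilyId.EXPONENTIAL:
        return -np.exp(logz)
    if family is fam.FamilyId.WEIBULL:
        return -np.exp(g * logz)
    if family is fam.FamilyId.LOGNORMAL:
        return special.log_ndtr(-logz / g)
    if family is fam.FamilyId.LOGLOGISTIC:
        return -np.logaddexp(0.0, g * logz)
    if family is fam.FamilyId.GAMMA:
        with np.errstate(divide="ignore"):
            return np.log(special.gammaincc(g, np.exp(logz)))
    raise ValueError(family)  # pragma: no cover


class AFTTarget:
    """Unconstrained log-posterior kernel for one (dataset, model) pair.

    Free coordinates, in order: alpha; beta (if its prior is proper);
    log(gamma_aux) (if the family has one). Spiked parameters are held
    fixed. ``logpdf`` accepts a vector or an (m, dim) batch; batches are
    evaluated vectorized, which is what makes mode finding cheap.
    """

    def __init__(self, dataset: SurvivalDataset, model: ModelSpec, log_beta: bool = True):
        self.dataset = dataset
        self.model = model
        self.log_beta = log_beta
        dims: list[_Dim] = []
        if not model.alpha_prior.is_spike:
            dims.append(_Dim("alpha", model.alpha_prior, "identity"))
        if not model.beta_prior.is_spike:
            truncated = model.beta_prior.kind == "truncated_normal"
            tr = "log" if (truncated and log_beta) else "identity"
            dims.append(_Dim("beta", model.beta_prior, tr))
        if model.gamma_prior is not None:
            dims.append(_Dim("gamma_aux", model.gamma_prior, "log"))
        self.dims = dims
        self.names = [d.name for d in dims]
        self._prepare()

    @property
    def dim(self) -> int:
        return len(self.dims)

    def _prepare(self) -> None:
        # group by (arm, event) once; arms enter the likelihood only via eta
        ds = self.dataset
        self._groups = []
        for x in (0, 1):
            for event in (1, 0):
                m = (ds.arms == x) & (ds.events == event)
                if m.any():
                    t = ds.times[m]
                    # censored times are often ties (administrative censoring)
                    tt, counts = np.unique(t, return_counts=True)
                    self._groups.append((x, event, tt, counts.astype(float)))

    def params(self, u: np.ndarray) -> fam.FamilyParams:
        """Map an unconstrained vector to constrained FamilyParams."""
        u = np.asarray(u, dtype=float)
        vals = {d.name: d.constrain(ui) for d, ui in zip(self.dims, u)}
        beta = vals.get(
            "beta", self.model.beta_prior.location if self.model.beta_prior.is_spike else 0.0
        )
        alpha = vals.get("alpha", self.model.alpha_prior.location)
        return fam.FamilyParams(
            alpha=float(alpha), beta=float(beta), gamma_aux=vals.get("gamma_aux")
        )

    def log_likelihood(self, u: np.ndarray) -> float:
        params = self.params(u)
        family = self.model.family
        total = 0.0
        for x, event, t, counts in self._groups:
            f = fam.log_density if event else fam.log_survival
            total += float(counts @ f(family, t, params, x))
        return total

    def log_prior(self, u: np.ndarray) -> float:
        u = np.asarray(u, dtype=float)
        return float(sum(d.log_prior(ui) for d, ui in zip(self.dims, u)))

    def logpdf_batch(self, U: np.ndarray) -> np.ndarray:
        """Vectorized kernel over an (m, dim) batch of unconstrained points."""
        U = np.atleast_2d(np.asarray(U, dtype=float))
        m = U.shape[0]
        out = np.zeros(m)
        for j, d in enumerate(self.dims):
            out += d.log_prior_vec(U[:, j])
        if len(self.dataset):
            idx = {name: j for j, name in enumerate(self.names)}
            if "alpha" in idx:
                alpha = U[:, idx["alpha"]][:, None]
            else:
                alpha = self.model.alpha_prior.location
            if "beta" in idx:
                beta = U[:, idx["beta"]]
                if self.dims[idx["beta"]].transform == "log":
                    beta = np.exp(beta)
                beta = beta[:, None]
            else:
                beta = (
                    self.model.beta_prior.location if self.model.beta_prior.is_spike else 0.0
                )
            g = np.exp(U[:, idx["gamma_aux"]])[:, None] if "gamma_aux" in idx else None
            family = self.model.family
            with np.errstate(over="ignore", invalid="ignore"):
                for x, event, t, counts in self._groups:
                    eta = alpha + beta * x
                    f = _batch_log_density if event else _batch_log_survival
                    vals = f(family, t[None, :], eta, g)
                    out += vals @ counts
        out[~np.isfinite(out)] = -np.inf
        return out

    def logpdf(self, u: np.ndarray) -> float | np.ndarray:
        u = np.asarray(u, dtype=float)
        if u.ndim == 2:
            return self.logpdf_batch(u)
        try:
            ll = self.log_likelihood(u) if len(self.dataset) else 0.0
        except (ValueError, FloatingPointError):
            return -np.inf
        lp = self.log_prior(u)
        out = ll + lp
        return out if np.isfinite(out) else -np.inf

    def initial_point(self) -> np.ndarray:
        """Data-informed starting point for optimization and sampling."""
        u0 = np.array([d.unconstrained_guess() for d in self.dims])
        ds = self.dataset
        if len(ds) and ds.n_events > 0:
            # exponential-rate style guess for the log-days intercept
            u0[0] = float(np.log(ds.times.sum() / ds.n_events))
        return u0


@dataclass(frozen=True)
class MapFit:
    """Posterior mode with the negative Hessian on the unconstrained scale."""

    u: np.ndarray
    log_post: float
    hessian: np.ndarray
    converged: bool

    @property
    def cov(self) -> np.ndarray:
        return np.linalg.inv(self.hessian)


def _num_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar f at x."""
    p = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _stencil(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Central-difference stencil points for gradient + Hessian at x."""
    p = x.size
    points = [x]
    for i in range(p):
        e = np.zeros(p)
        e[i] = h[i]
        points.append(x + e)
        points.append(x - e)
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p)
            ei[i] = h[i]
            ej = np.zeros(p)
            ej[j] = h[j]
            points.extend([x + ei + ej, x + ei - ej, x - ei + ej, x - ei - ej])
    return np.asarray(points)


def _grad_hess_from_stencil(values: np.ndarray, h: np.ndarray, p: int):
    f0 = values[0]
    g = np.empty(p)
    H = np.empty((p, p))
    for i in range(p):
        fp, fm = values[1 + 2 * i], values[2 + 2 * i]
        g[i] = (fp - fm) / (2.0 * h[i])
        H[i, i] = (fp - 2.0 * f0 + fm) / h[i] ** 2
    k = 1 + 2 * p
    for i in range(p):
        for j in range(i + 1, p):
            fpp, fpm, fmp, fmm = values[k : k + 4]
            k += 4
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return f0, g, H


def _newton_map(target, x0: np.ndarray, max_iter: int = 60) -> MapFit | None:
    """Damped Newton ascent with batched stencil evaluations."""
    x = np.asarray(x0, dtype=float)
    fx = float(target.logpdf(x))
    if not np.isfinite(fx):
        return None
    p = x.size
    for _ in range(max_iter):
        h = 1e-4 * np.maximum(1.0, np.abs(x))
        values = np.asarray(target.logpdf_batch(_stencil(x, h)))
        if not np.all(np.isfinite(values)):
            return None
        f0, g, H = _grad_hess_from_stencil(values, h, p)
        npH = -0.5 * (H + H.T)
        eigs = np.linalg.eigvalsh(npH)
        if eigs[0] <= 0:
            npH = npH + (1e-6 - eigs[0]) * np.eye(p)
        grad_small = float(np.max(np.abs(g))) < 1e-6 * max(1.0, abs(f0))
        step = np.linalg.solve(npH, g)
        if grad_small and float(np.max(np.abs(step))) < 1e-6:
            if eigs[0] <= 0:
                return None
            return MapFit(u=x, log_post=f0, hessian=npH, converged=True)
        lam = 1.0
        improved = False
        for _ in range(12):
            x_new = x + lam * step
            f_new = float(target.logpdf(x_new))
            if np.isfinite(f_new) and f_new > fx:
                improved = True
                break
            lam *= 0.5
        if not improved:
            if grad_small and eigs[0] > 0:
                return MapFit(u=x, log_post=f0, hessian=npH, converged=True)
            return None
        x, fx = x_new, f_new
    return None


def map_fit(target, x0: np.ndarray | None = None, warm: bool = False) -> MapFit:
    """Posterior mode and curvature of an unconstrained target.

    ``target`` needs ``logpdf`` and ``dim`` (and ``initial_point`` if x0
    is omitted). Targets exposing ``logpdf_batch`` are optimized by
    damped Newton with whole finite-difference stencils evaluated in one
    vectorized call; others fall back to BFGS with a Nelder-Mead polish.
    ``warm`` marks x0 as a nearby previous mode (same path, fewer
    iterations needed in practice).
    """
    if x0 is None:
        x0 = target.initial_point()
    x0 = np.asarray(x0, dtype=float)

    if hasattr(target, "logpdf_batch"):
        out = _newton_map(target, x0)
        if out is not None:
            return out

    def neg(u):
        v = target.logpdf(u)
        return -v if np.isfinite(v) else 1e12

    res = optimize.minimize(neg, x0, method="BFGS", options={"gtol": 1e-6, "maxiter": 500})
    best = res
    if not res.success:
        res2 = optimize.minimize(neg, res.x, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if res2.fun < best.fun:
            best = res2
    H = -_num_hessian(target.logpdf, best.x)
    # symmetrize and guard against tiny negative curvature from noise
    H = 0.5 * (H + H.T)
    converged = bool(np.all(np.linalg.eigvalsh(H) > 0))
    if not converged:
        H = H + (1e-6 - min(0.0, float(np.linalg.eigvalsh(H).min()))) * np.eye(H.shape[0])
        converged = bool(np.all(np.linalg.eigvalsh(H) > 0))
    return MapFit(u=best.x, log_post=-best.fun, hessian=H, converged=converged)
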