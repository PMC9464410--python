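"""Accelerated failure time (AFT) parametric families.

Five families share a log-scale linear predictor eta = alpha + beta * x,
where x in {0, 1} codes the treatment arm and beta = log(AF) is the log
acceleration factor. Writing z = t * exp(-eta) for the rescaled time, each
family is a unit-scale distribution in z:

    exponential   S(t) = exp(-z)
    weibull       S(t) = exp(-z**gamma)
    lognormal     S(t) = 1 - Phi((log t - eta) / gamma)
    loglogistic   S(t) = 1 / (1 + z**gamma)
    gamma         S(t) = Q(gamma, z)        (upper regularized inc. gamma)

The auxiliary parameter ``gamma_aux`` is the shape (Weibull, log-logistic,
gamma) or the log-scale standard deviation (log-normal); the exponential
has none. The defining AFT property holds for all of them:
S(t | x=1) = S(t * exp(-beta) | x=0).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "FamilyId",
    "FamilyParams",
    "FAMILIES",
    "n_params",
    "has_aux",
    "linear_predictor",
    "survival",
    "log_density",
    "log_survival",
    "log_hazard",
    "mean_survival",
    "random_times",
    "quantile",
]


class FamilyId(str, enum.Enum):
    """The five AFT parametric families."""

    EXPONENTIAL = "exponential"
    WEIBULL = "weibull"
    LOGNORMAL = "lognormal"
    LOGLOGISTIC = "loglogistic"
    GAMMA = "gamma"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


FAMILIES: tuple[FamilyId, ...] = tuple(FamilyId)

_NO_AUX = {FamilyId.EXPONENTIAL}


def has_aux(family: FamilyId) -> bool:
    """Whether the family carries an auxiliary (shape/sd) parameter."""
    return FamilyId(family) not in _NO_AUX


def n_params(family: FamilyId, with_beta: bool = True) -> int:
    """Number of free parameters (alpha [, beta] [, gamma_aux])."""
    k = 1 + (1 if with_beta else 0)
    return k + (1 if has_aux(family) else 0)


@dataclass(frozen=True)
class FamilyParams:
    """Parameters of one AFT model: intercept, log(AF), auxiliary shape/sd."""

    alpha: float
    beta: float = 0.0
    gamma_aux: float | None = None

    def __post_init__(self) -> None:
        if self.gamma_aux is not None and not self.gamma_aux > 0:
            raise ValueError(f"gamma_aux must be positive, got {self.gamma_aux}")


def linear_predictor(alpha: float, beta: float, x) -> float:
    """Log-days location eta = alpha + beta * x for arm indicator x in {0, 1}."""
    x = np.asarray(x)
    if not np.all((x == 0) | (x == 1)):
        raise ValueError("arm indicator x must be 0 or 1")
    return alpha + beta * x


def _aux(family: FamilyId, params: FamilyParams) -> float:
    if not has_aux(family):
        return 1.0
    if params.gamma_aux is None:
        raise ValueError(f"{family} requires gamma_aux")
    return params.gamma_aux


def _check_time(t, allow_zero: bool) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if allow_zero:
        if np.any(t < 0):
            raise ValueError("negative survival time")
    elif np.any(t <= 0):
        raise ValueError("survival time must be positive")
    return t


def log_survival(family: FamilyId, t, params: FamilyParams, x=0):
    """log S(t | x) for the given family; t >= 0."""
    family = FamilyId(family)
    t = _check_time(t, allow_zero=True)
    eta = linear_predictor(params.alpha, params.beta, x)
    g = _aux(family, params)
    with np.errstate(divide="ignore", over="ignore"):
        logz = np.log(t) - eta
        if family is FamilyId.EXPONENTIAL:
            out = -np.exp(logz)
        elif family is FamilyId.WEIBULL:
            out = -np.exp(g * logz)
        elif family is FamilyId.LOGNORMAL:
            out = special.log_ndtr(-logz / g)
        elif family is FamilyId.LOGLOGISTIC:
            out = -np.logaddexp(0.0, g * logz)
        elif family is FamilyId.GAMMA:
            out = np.log(special.gammaincc(g, np.exp(logz)))
        else:  # pragma: no cover
            raise ValueError(family)
    return out


def survival(family: FamilyId, t, params: FamilyParams, x=0):
    """Survival probability S(t | x) in [0, 1]."""
    return np.exp(log_survival(family, t, params, x))


def log_density(family: FamilyId, t, params: FamilyParams, x=0):
    """log f(t | x); t > 0.

    In terms of z = t * exp(-eta): f(t) = exp(-eta) * f_z(z) with f_z the
    unit-scale density of the family.
    """
    family = FamilyId(family)
    t = _check_time(t, allow_zero=False)
    eta = linear_predictor(params.alpha, params.beta, x)
    g = _aux(family, params)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        logz = np.log(t) - eta
        z = np.exp(logz)
        if family is FamilyId.EXPONENTIAL:
            return -eta - z
        if family is FamilyId.WEIBULL:
            return math.log(g) - eta + (g - 1.0) * logz - np.exp(g * logz)
        if family is FamilyId.LOGNORMAL:
            # density of log t ~ N(eta, g) divided by t
            w = logz / g
            return -0.5 * w * w - 0.9189385332046727 - math.log(g) - np.log(t)
        if family is FamilyId.LOGLOGISTIC:
            return (
                math.log(g) - eta + (g - 1.0) * logz - 2.0 * np.logaddexp(0.0, g * logz)
            )
        if family is FamilyId.GAMMA:
            return -eta + (g - 1.0) * logz - z - special.gammaln(g)
    raise ValueError(family)  # pragma: no cover


def log_hazard(family: FamilyId, t, params: FamilyParams, x=0):
    """log h(t | x) = log f - log S; t > 0."""
    return log_density(family, t, params, x) - log_survival(family, t, params, x)


def mean_survival(family: FamilyId, params: FamilyParams, x=0) -> float:
    """Expected survival time in days.

    Closed forms: exponential e^eta; Weibull e^eta * Gamma(1 + 1/g);
    log-normal exp(eta + g^2/2); log-logistic e^eta * (pi/g)/sin(pi/g)
    (requires g > 1); gamma g * e^eta.
    """
    family = FamilyId(family)
    eta = float(linear_predictor(params.alpha, params.beta, x))
    g = _aux(family, params)
    if family is FamilyId.EXPONENTIAL:
        return math.exp(eta)
    if family is FamilyId.WEIBULL:
        return math.exp(eta) * math.gamma(1.0 + 1.0 / g)
    if family is FamilyId.LOGNORMAL:
        return math.exp(eta + 0.5 * g * g)
    if family is FamilyId.LOGLOGISTIC:
        if g <= 1.0:
            raise ValueError("log-logistic mean undefined for gamma_aux <= 1")
        return math.exp(eta) * (math.pi / g) / math.sin(math.pi / g)
    if family is FamilyId.GAMMA:
        return g * math.exp(eta)
    raise ValueError(family)  # pragma: no cover


def quantile(family: FamilyId, q, params: FamilyParams, x=0):
    """Inverse CDF: time t with P(T <= t | x) = q."""
    family = FamilyId(family)
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("quantile level must lie in [0, 1]")
    eta = linear_predictor(params.alpha, params.beta, x)
    g = _aux(family, params)
    scale = np.exp(eta)
    if family is FamilyId.EXPONENTIAL:
        z = -np.log1p(-q)
    elif family is FamilyId.WEIBULL:
        z = (-np.log1p(-q)) ** (1.0 / g)
    elif family is FamilyId.LOGNORMAL:
        z = np.exp(g * stats.norm.ppf(q))
    elif family is FamilyId.LOGLOGISTIC:
        z = (q / (1.0 - q)) ** (1.0 / g)
    elif family is FamilyId.GAMMA:
        z = special.gammaincinv(g, q)
    else:  # pragma: no cover
        raise ValueError(family)
    return scale * z


def random_times(
    family: FamilyId,
    params: FamilyParams,
    x=0,
    n: int = 1,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw n i.i.d. survival times via inverse-CDF on a shared uniform stream.

    Inverse-CDF sampling makes nested families (e.g. Weibull with shape 1 and
    exponential) coincide draw-for-draw under the same seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.random(n)
    return np.asarray(quantile(family, u, params, x), dtype=float)
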