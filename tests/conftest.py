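import numpy as np
import pytest

import survbma as sb


@pytest.fixture(scope="session")
def prior_table():
    return sb.default_prior_table()


@pytest.fixture(scope="session")
def small_trial():
    """A 200-participant trial with a moderate positive effect."""
    return sb.generate_trial(sb.colon_like(n_per_arm=100, log_af=0.2), seed=5)


@pytest.fixture(scope="session")
def null_trial():
    """A full-size (2070) colon-cancer-like trial with no effect."""
    return sb.generate_trial(sb.colon_like(log_af=0.0), seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


class ConjugateExponentialTarget:
    """Exponential likelihood with Gamma(a, b) prior on the rate.

    Unconstrained coordinate u = log(rate); the closed-form log marginal
    likelihood is lgamma(a + d) - lgamma(a) + a log b - (a + d) log(b + sum t)
    with d the number of events — the independent oracle for the
    marginal-likelihood estimators.
    """

    names = ["lograte"]
    dim = 1

    def __init__(self, times, events, a, b):
        self.t = np.asarray(times, dtype=float)
        self.c = np.asarray(events, dtype=float)
        self.a, self.b = a, b

    def logpdf(self, u):
        u = np.atleast_1d(np.asarray(u, dtype=float))
        if u.ndim == 2:
            return np.array([self.logpdf(row) for row in u])
        lam = np.exp(u[0])
        loglik = self.c.sum() * u[0] - lam * self.t.sum()
        # Gamma(a, b) prior on lam plus the log-transform Jacobian
        logprior = (
            self.a * np.log(self.b)
            - float(__import__("math").lgamma(self.a))
            + self.a * u[0]
            - self.b * lam
        )
        return float(loglik + logprior)

    def initial_point(self):
        return np.array([np.log(max(self.c.sum(), 1.0) / self.t.sum())])

    def closed_form_log_ml(self):
        import math

        d = self.c.sum()
        return (
            math.lgamma(self.a + d)
            - math.lgamma(self.a)
            + self.a * math.log(self.b)
            - (self.a + d) * math.log(self.b + self.t.sum())
        )
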