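"""Bayes Factor Design Analysis (BFDA) for fixed-n and sequential trials.

BFDA simulates trials from the prior predictive distribution of the
model ensemble under two scenarios — the null models are true (effect
absent) or the alternative models are true (effect drawn from its prior)
— then computes the distribution of inclusion Bayes factors the planned
analysis would produce. From those distributions one reads off
misleading-evidence rates at a decision boundary and, inversely,
calibrates boundaries to target error rates.

A self-contained exact binomial example illustrates the logic: with
point hypotheses the Bayes factor for k successes in n trials is a
likelihood ratio, and the misleading-evidence probability is an exact
enumeration over the n + 1 outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import SurvivalDataset
from .ensemble import inclusion_bf, posterior_model_probs
from .families import FamilyParams, random_times
from .marglik import ensemble_laplace_log_mls
from .models import ModelSpec, testing_ensemble
from .monitor import censor_at
from .priors import PriorTable, default_prior_table, sample_prior

__all__ = [
    "binomial_point_bf",
    "binomial_misleading_rate",
    "DesignSpec",
    "DesignAnalysisResult",
    "simulate_trial",
    "fixed_n_bfda",
    "misleading_rates",
    "calibrate_fixed",
    "sequential_bfda",
    "calibrate_sequential",
]


# ------------------------------------------------------- binomial example


def binomial_point_bf(k: int, n: int, theta_alt: float, theta0: float) -> float:
    """Bayes factor of two point hypotheses for k successes in n trials.

    The binomial coefficients cancel, leaving the likelihood ratio
    theta_alt^k (1-theta_alt)^(n-k) / theta0^k (1-theta0)^(n-k).
    """
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    for th in (theta_alt, theta0):
        if not 0 < th < 1:
            raise ValueError("success probabilities must lie in (0, 1)")
    log_bf = k * (math.log(theta_alt) - math.log(theta0)) + (n - k) * (
        math.log1p(-theta_alt) - math.log1p(-theta0)
    )
    return math.exp(log_bf)


def binomial_misleading_rate(
    theta_alt: float, theta0: float, n: int, bf_threshold: float
) -> float:
    """Exact P(BF >= threshold | null true) by enumeration over outcomes."""
    if bf_threshold <= 0:
        raise ValueError("bf_threshold must be positive")
    ks = np.arange(n + 1)
    bfs = np.array([binomial_point_bf(int(k), n, theta_alt, theta0) for k in ks])
    pmf = stats.binom.pmf(ks, n, theta0)
    return float(pmf[bfs >= bf_threshold].sum())


# ------------------------------------------------------------ trial design


@dataclass(frozen=True)
class DesignSpec:
    """Design of the simulated trial and of the analysis plan.

    Defaults mirror the planned colon-cancer trial: 2070 participants in
    equal arms, all entering at time 0, analyzed after a 5-year (1825
    day) horizon; sequential looks every 30 days with the Bayes factor
    trajectory frozen once it leaves ``compute_stop_range`` (a compute
    shortcut: the decision bounds of interest lie inside the range).
    """

    prior_table: PriorTable = field(default_factory=default_prior_table)
    n_total: int = 2070
    allocation: float = 0.5
    horizon: float = 1825.0
    reps: int = 500
    seed: int | None = None
    interval: float = 30.0
    compute_stop_range: tuple[float, float] = (1.0 / 15.0, 15.0)

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0 < self.allocation < 1:
            raise ValueError("allocation must lie in (0, 1)")
        if self.interval <= 0 or self.interval > self.horizon:
            raise ValueError("interval must lie in (0, horizon]")
        lo, hi = self.compute_stop_range
        if not lo < 1 < hi:
            raise ValueError("compute_stop_range must bracket 1")

    def arms(self) -> np.ndarray:
        n_exp = int(round(self.n_total * self.allocation))
        arms = np.zeros(self.n_total, dtype=int)
        arms[:n_exp] = 1
        return arms


@dataclass
class DesignAnalysisResult:
    """BF samples (fixed-n) or trajectories (sequential) per scenario."""

    design: DesignSpec
    kind: str  # "fixed" or "sequential"
    h0_bfs: np.ndarray
    h1_bfs: np.ndarray
    h0_trajectories: list[np.ndarray] | None = None
    h1_trajectories: list[np.ndarray] | None = None
    look_times: np.ndarray | None = None
    h0_meta: pd.DataFrame | None = None
    h1_meta: pd.DataFrame | None = None
    n_failed: int = 0

    def scenario_bfs(self, scenario: str) -> np.ndarray:
        return self.h0_bfs if scenario == "h0" else self.h1_bfs

    def trajectory_extremes(self, scenario: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-trajectory (max BF10, min BF10) over all looks."""
        trajs = self.h0_trajectories if scenario == "h0" else self.h1_trajectories
        if trajs is None:
            raise ValueError("no trajectories stored; run sequential_bfda")
        maxima = np.array([np.nanmax(t) for t in trajs])
        minima = np.array([np.nanmin(t) for t in trajs])
        return maxima, minima


def simulate_trial(
    model: ModelSpec, spec: DesignSpec, rep_seed: int | np.random.Generator
) -> SurvivalDataset:
    """One prior-predictive trial under a generating model.

    Draws the intercept and auxiliary parameter from their priors, the
    effect from its prior (zero under a null model), then survival times
    per arm, administratively censored at the horizon.
    """
    rng = rep_seed if isinstance(rep_seed, np.random.Generator) else np.random.default_rng(rep_seed)
    alpha = float(sample_prior(model.alpha_prior, 1, rng)[0])
    gamma = (
        float(sample_prior(model.gamma_prior, 1, rng)[0]) if model.gamma_prior is not None else None
    )
    beta = float(sample_prior(model.beta_prior, 1, rng)[0])
    params = FamilyParams(alpha=alpha, beta=beta, gamma_aux=gamma)
    arms = spec.arms()
    times = np.empty(arms.size)
    for x in (0, 1):
        m = arms == x
        times[m] = random_times(model.family, params, x, int(m.sum()), rng)
    events = (times <= spec.horizon).astype(int)
    times = np.minimum(times, spec.horizon)
    return SurvivalDataset(times, events, arms, horizon=spec.horizon)


def _generating_models(spec: DesignSpec, scenario: str) -> list[ModelSpec]:
    specs = testing_ensemble(spec.prior_table)
    want_null = scenario == "h0"
    return [m for m in specs if m.is_null == want_null]


def _ensemble_bf10(dataset: SurvivalDataset, specs, prior_probs, alt, warm=None):
    log_mls, warm = ensemble_laplace_log_mls(dataset, specs, warm)
    post = posterior_model_probs(log_mls, prior_probs)
    return inclusion_bf(prior_probs, post, alt), warm


def _rep_plan(spec: DesignSpec, scenario: str):
    """Per-rep (generating model, seed) pairs, equal split across families."""
    gens = _generating_models(spec, scenario)
    if spec.reps % len(gens):
        raise ValueError(f"reps must be divisible by {len(gens)} generating models")
    master = np.random.default_rng(
        None if spec.seed is None else (spec.seed, 0 if scenario == "h0" else 1)
    )
    seeds = master.integers(2**31 - 1, size=spec.reps)
    plan = []
    per = spec.reps // len(gens)
    for gi, gen in enumerate(gens):
        for r in range(per):
            plan.append((gen, int(seeds[gi * per + r])))
    return plan


def fixed_n_bfda(spec: DesignSpec, progress: bool = False) -> DesignAnalysisResult:
    """Fixed-n BFDA: the inclusion-BF distribution under both scenarios.

    Per replicate: simulate a full trial from one generating model, fit
    all ten testing models, record the inclusion Bayes factor for the
    effect. Replicates are split equally across the five families within
    each scenario. Failed fits are excluded and counted.
    """
    analysis = testing_ensemble(spec.prior_table)
    prior_probs = np.array([m.prior_prob for m in analysis])
    alt = [i for i, m in enumerate(analysis) if not m.is_null]
    out = {}
    meta = {}
    n_failed = 0
    for scenario in ("h0", "h1"):
        bfs, rows = [], []
        for gen, rep_seed in _rep_plan(spec, scenario):
            dataset = simulate_trial(gen, spec, rep_seed)
            try:
                bf10, _ = _ensemble_bf10(dataset, analysis, prior_probs, alt)
            except Exception:
                n_failed += 1
                continue
            bfs.append(bf10)
            rows.append(
                {
                    "generating_model": gen.name,
                    "rep_seed": rep_seed,
                    "events": dataset.n_events,
                    "bf10": bf10,
                }
            )
        out[scenario] = np.array(bfs)
        meta[scenario] = pd.DataFrame(rows)
    return DesignAnalysisResult(
        design=spec,
        kind="fixed",
        h0_bfs=out["h0"],
        h1_bfs=out["h1"],
        h0_meta=meta["h0"],
        h1_meta=meta["h1"],
        n_failed=n_failed,
    )


def misleading_rates(
    result: DesignAnalysisResult, bf10_bound: float = 10.0, bf01_bound: float = 10.0
) -> dict[str, float]:
    """False-positive / false-negative / undecided rates at given bounds.

    Fixed-n: a false positive is an H0-scenario BF10 at or above the
    acceptance bound; a false negative is an H1-scenario BF10 at or
    below 1/bf01_bound. Sequential: crossing at any look counts.
    """
    if bf10_bound < 1 or bf01_bound < 1:
        raise ValueError("decision bounds must be >= 1 on their own scales")
    if result.kind == "sequential":
        h0_max, _ = result.trajectory_extremes("h0")
        _, h1_min = result.trajectory_extremes("h1")
        fp = float(np.mean(h0_max >= bf10_bound))
        fn = float(np.mean(h1_min <= 1.0 / bf01_bound))
        h0_min = result.trajectory_extremes("h0")[1]
        h1_max = result.trajectory_extremes("h1")[0]
        undecided_h0 = float(np.mean((h0_max < bf10_bound) & (h0_min > 1.0 / bf01_bound)))
        undecided_h1 = float(np.mean((h1_max < bf10_bound) & (h1_min > 1.0 / bf01_bound)))
    else:
        fp = float(np.mean(result.h0_bfs >= bf10_bound))
        fn = float(np.mean(result.h1_bfs <= 1.0 / bf01_bound))
        undecided_h0 = float(np.mean((result.h0_bfs < bf10_bound) & (result.h0_bfs > 1.0 / bf01_bound)))
        undecided_h1 = float(np.mean((result.h1_bfs < bf10_bound) & (result.h1_bfs > 1.0 / bf01_bound)))
    return {
        "false_positive": fp,
        "false_negative": fn,
        "undecided_h0": undecided_h0,
        "undecided_h1": undecided_h1,
    }


def calibrate_fixed(
    result: DesignAnalysisResult, alpha: float = 0.05, beta: float = 0.10
) -> dict[str, float]:
    """Boundaries matching target error rates in the fixed-n design.

    bf10_bound is the (1 - alpha) quantile of BF10 under the null
    scenario; bf01_bound is the reciprocal of the beta quantile of BF10
    under the alternative scenario.
    """
    if result.h0_bfs.size == 0 or result.h1_bfs.size == 0:
        raise ValueError("both scenario BF samples are required")
    bf10_bound = float(np.quantile(result.h0_bfs, 1.0 - alpha))
    bf01_bound = float(1.0 / np.quantile(result.h1_bfs, beta))
    return {"bf10_bound": bf10_bound, "bf01_bound": bf01_bound}


def sequential_bfda(spec: DesignSpec, progress: bool = False) -> DesignAnalysisResult:
    """Sequential BFDA: inclusion-BF trajectories under monthly looks.

    One dataset per replicate; at each look the data are censored at the
    analysis time and the ensemble refitted (warm-started from the
    previous look). Once the BF leaves ``compute_stop_range`` the last
    value is carried forward to the remaining looks.
    """
    analysis = testing_ensemble(spec.prior_table)
    prior_probs = np.array([m.prior_prob for m in analysis])
    alt = [i for i, m in enumerate(analysis) if not m.is_null]
    looks = np.arange(spec.interval, spec.horizon + 1e-9, spec.interval)
    lo, hi = spec.compute_stop_range
    trajs = {}
    bfs_final = {}
    meta = {}
    n_failed = 0
    for scenario in ("h0", "h1"):
        scenario_trajs, rows = [], []
        for gen, rep_seed in _rep_plan(spec, scenario):
            dataset = simulate_trial(gen, spec, rep_seed)
            bf_path = np.full(looks.size, np.nan)
            warm = None
            frozen = None
            failed = False
            for j, tau in enumerate(looks):
                if frozen is not None:
                    bf_path[j] = frozen
                    continue
                snap = censor_at(dataset, float(tau))
                try:
                    bf10, warm = _ensemble_bf10(snap, analysis, prior_probs, alt, warm)
                except Exception:
                    failed = True
                    break
                bf_path[j] = bf10
                if not lo < bf10 < hi:
                    frozen = bf10
            if failed:
                n_failed += 1
                continue
            scenario_trajs.append(bf_path)
            rows.append(
                {
                    "generating_model": gen.name,
                    "rep_seed": rep_seed,
                    "events": dataset.n_events,
                    "final_bf10": bf_path[-1],
                }
            )
        trajs[scenario] = scenario_trajs
        bfs_final[scenario] = np.array([t[-1] for t in scenario_trajs])
        meta[scenario] = pd.DataFrame(rows)
    return DesignAnalysisResult(
        design=spec,
        kind="sequential",
        h0_bfs=bfs_final["h0"],
        h1_bfs=bfs_final["h1"],
        h0_trajectories=trajs["h0"],
        h1_trajectories=trajs["h1"],
        look_times=looks,
        h0_meta=meta["h0"],
        h1_meta=meta["h1"],
        n_failed=n_failed,
    )


def calibrate_sequential(
    result: DesignAnalysisResult, alpha: float = 0.05, beta: float = 0.10
) -> dict[str, float]:
    """Boundaries whose any-look crossing rates stay within the targets.

    The smallest upper bound crossed by at most ``alpha`` of the null
    trajectories and the largest null-acceptance bound (on the BF01
    scale) crossed by at most ``beta`` of the alternative trajectories,
    found from the empirical distribution of per-trajectory extremes.
    """
    h0_max, _ = result.trajectory_extremes("h0")
    _, h1_min = result.trajectory_extremes("h1")
    bf10_bound = float(np.quantile(h0_max, 1.0 - alpha, method="higher"))
    bf01_bound = float(1.0 / np.quantile(h1_min, beta, method="lower"))
    return {"bf10_bound": max(bf10_bound, 1.0), "bf01_bound": max(bf01_bound, 1.0)}
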