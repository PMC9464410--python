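"""Sequential evidence monitoring of a two-arm trial.

At each scheduled look the data are administratively censored at the
analysis time, the ten-model testing ensemble is refitted, and the
inclusion Bayes factor for the treatment effect plus the posterior
probability of each parametric family are recorded. Crossings of
decision bounds are reported at the first look at or after which the
bound is met — evidence is only observed at looks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SurvivalDataset
from .ensemble import inclusion_bf, posterior_model_probs
from .families import FamilyId
from .marglik import ensemble_laplace_log_mls
from .models import ModelSpec, testing_ensemble
from .priors import PriorTable

__all__ = ["censor_at", "MonitoringSchedule", "EvidenceTrajectory", "run_monitor"]


def censor_at(dataset: SurvivalDataset, analysis_time: float) -> SurvivalDataset:
    """Administratively censor everything beyond ``analysis_time``.

    Rows with time > analysis_time become censored at the analysis time;
    other rows are unchanged. Idempotent.
    """
    if analysis_time <= 0:
        raise ValueError("analysis_time must be positive")
    beyond = dataset.times > analysis_time
    times = np.where(beyond, analysis_time, dataset.times)
    events = np.where(beyond, 0, dataset.events)
    return SurvivalDataset(times, events, dataset.arms, dataset.horizon)


@dataclass(frozen=True)
class MonitoringSchedule:
    """Strictly increasing analysis times in days."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("analysis times must be positive and strictly increasing")
        object.__setattr__(self, "times", t)

    @classmethod
    def monthly(cls, horizon: float, interval: float = 30.0) -> "MonitoringSchedule":
        """Every ``interval`` days up to and including the horizon."""
        times = np.arange(interval, horizon + 1e-9, interval)
        if times.size == 0 or times[-1] < horizon - 1e-9:
            times = np.append(times, horizon)
        return cls(times)


@dataclass
class EvidenceTrajectory:
    """Evidence per analysis time plus first bound crossings."""

    times: np.ndarray
    bf10: np.ndarray
    family_probs: pd.DataFrame
    events: np.ndarray
    failed: np.ndarray
    first_crossings: dict[str, float | None] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, "bf10": self.bf10, "events": self.events})
        return pd.concat([df, self.family_probs.reset_index(drop=True)], axis=1)

    def plot(self, bounds: tuple[float, float] = (10.0, 10.0), ax=None):
        """The Bayes factor trajectory on a log scale with decision bounds."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times / 30.0, self.bf10, color="black")
        ax.axhline(bounds[0], linestyle="--", color="tab:purple")
        ax.axhline(1.0 / bounds[1], linestyle="--", color="tab:green")
        ax.set_yscale("log")
        ax.set_xlabel("months since start")
        ax.set_ylabel("inclusion BF10")
        return ax


def run_monitor(
    dataset: SurvivalDataset,
    prior_table: PriorTable | None = None,
    schedule: MonitoringSchedule | None = None,
    bounds: tuple[float, float] = (10.0, 10.0),
) -> EvidenceTrajectory:
    """Monitor the inclusion BF over a schedule of administrative censorings.

    ``bounds`` is (bf10_bound, bf01_bound): the first look with
    BF10 >= bf10_bound or BF10 <= 1/bf01_bound is reported in
    ``first_crossings``. A failed fit at one look is flagged and the
    trajectory continues.
    """
    horizon = dataset.horizon or float(dataset.times.max())
    schedule = schedule or MonitoringSchedule.monthly(horizon)
    specs: list[ModelSpec] = testing_ensemble(prior_table)
    prior_probs = np.array([m.prior_prob for m in specs])
    alt = [i for i, m in enumerate(specs) if not m.is_null]

    bf10 = np.full(schedule.times.size, np.nan)
    events = np.zeros(schedule.times.size, dtype=int)
    failed = np.zeros(schedule.times.size, dtype=bool)
    fam_rows = []
    warm = None
    for j, tau in enumerate(schedule.times):
        snap = censor_at(dataset, float(tau))
        events[j] = snap.n_events
        try:
            log_mls, warm = ensemble_laplace_log_mls(snap, specs, warm)
            post = posterior_model_probs(log_mls, prior_probs)
            bf10[j] = inclusion_bf(prior_probs, post, alt)
            fam_rows.append(
                {
                    f.value: float(
                        sum(p for p, m in zip(post, specs) if m.family is f)
                    )
                    for f in FamilyId
                }
            )
        except Exception:
            failed[j] = True
            fam_rows.append({f.value: np.nan for f in FamilyId})

    family_probs = pd.DataFrame(fam_rows)
    up, low = bounds
    first = {"bf10": None, "bf01": None}
    for t, b in zip(schedule.times, bf10):
        if first["bf10"] is None and np.isfinite(b) and b >= up:
            first["bf10"] = float(t)
        if first["bf01"] is None and np.isfinite(b) and b <= 1.0 / low:
            first["bf01"] = float(t)
    return EvidenceTrajectory(
        times=schedule.times,
        bf10=bf10,
        family_probs=family_probs,
        events=events,
        failed=failed,
        first_crossings=first,
    )
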