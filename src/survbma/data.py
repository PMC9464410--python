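"""Right-censored two-arm survival data container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset"]


@dataclass(frozen=True)
class SurvivalDataset:
    """Per-participant (time, event, arm) records with an optional horizon.

    ``times`` are positive days; ``events`` is 1 for an observed event and
    0 for right censoring; ``arms`` is 0 for the comparator and 1 for the
    experimental arm; ``horizon`` (days) bounds all recorded times when set.
    """

    times: np.ndarray
    events: np.ndarray
    arms: np.ndarray
    horizon: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=np.int64)
        arms = np.asarray(self.arms, dtype=np.int64)
        if not (times.shape == events.shape == arms.shape) or times.ndim != 1:
            raise ValueError("times, events and arms must be equal-length 1-d arrays")
        if times.size and np.any(times <= 0):
            raise ValueError("all survival times must be positive")
        if not np.all(np.isin(events, (0, 1))):
            raise ValueError("event indicators must be 0 or 1")
        if not np.all(np.isin(arms, (0, 1))):
            raise ValueError("arm indicators must be 0 or 1")
        if self.horizon is not None:
            if self.horizon <= 0:
                raise ValueError("horizon must be positive")
            if times.size and np.any(times > self.horizon + 1e-9):
                raise ValueError("times exceed the stated horizon")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "arms", arms)

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def event_fraction(self) -> float:
        return self.n_events / len(self) if len(self) else float("nan")

    def subset(self, mask) -> "SurvivalDataset":
        return SurvivalDataset(self.times[mask], self.events[mask], self.arms[mask], self.horizon)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time: str = "time",
        status: str = "status",
        arm: str = "arm",
        horizon: float | None = None,
    ) -> "SurvivalDataset":
        return cls(
            df[time].to_numpy(float),
            df[status].to_numpy(int),
            df[arm].to_numpy(int),
            horizon=horizon,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "status": self.events, "arm": self.arms})
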