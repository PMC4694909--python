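"""Kaplan-Meier estimation, median survival, and the two-group log-rank test.

Used to compare progression-free and overall survival between SUMSCAN
favorable and unfavorable tumors.  Estimation is delegated to lifelines;
this module fixes the conventions: events are processed before censorings
tied at the same time, and the median is the first time at which the
survival probability reaches 0.5 or below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .target_scoring import SumscanClass

__all__ = [
    "SurvivalObservation",
    "SurvivalCurve",
    "km_estimate",
    "logrank_test",
    "median_survival",
]


@dataclass(frozen=True)
class SurvivalObservation:
    """One follow-up interval: time in months, whether the event (progression
    or death) was observed, and optionally the SUMSCAN stratum."""

    time: float
    event: bool
    group: SumscanClass | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"survival time must be >= 0, got {self.time}")


@dataclass(frozen=True)
class SurvivalCurve:
    """A product-limit step function.

    ``times`` are the distinct observation times in increasing order;
    ``survival`` the estimate just after each time; ``at_risk`` the number
    of subjects at risk just before it; ``events``/``censored`` the counts
    occurring at it.  S = 1 before the first time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray

    def probability_at(self, t: float) -> float:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(observations: Sequence[SurvivalObservation]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate for one group.

    Censored observations reduce the risk set without producing a step;
    an event and a censoring tied at the same time are resolved event-first
    (the censored subject is still at risk for the tied event).
    """
    if not observations:
        raise ValueError("cannot estimate survival from zero observations")
    times = np.array([o.time for o in observations], dtype=float)
    events = np.array([o.event for o in observations], dtype=bool)

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    # lifelines inserts a t=0 anchor row; keep only actual observation times.
    table = kmf.event_table[kmf.event_table.index.isin(np.unique(times))]
    step_times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[step_times, "KM_estimate"].to_numpy()
    return SurvivalCurve(
        times=step_times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
        censored=table["censored"].to_numpy(dtype=int),
    )


def median_survival(curve: SurvivalCurve) -> float | None:
    """Smallest time with S(t) <= 0.5, or None if the curve never gets there."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    return float(curve.times[below[0]]) if below.size else None


def logrank_test(
    group_a: Sequence[SurvivalObservation],
    group_b: Sequence[SurvivalObservation],
) -> tuple[float, float]:
    """Two-group log-rank test (1 df); returns (chi-square statistic, p).

    A group with zero observed events still yields a statistic, with a
    warning that the comparison is driven entirely by the other group.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    for name, group in (("first", group_a), ("second", group_b)):
        if not any(o.event for o in group):
            warnings.warn(
                f"{name} group has zero observed events; "
                "log-rank comparison is one-sided in information",
                stacklevel=2,
            )
    res = _lifelines_logrank(
        np.array([o.time for o in group_a], dtype=float),
        np.array([o.time for o in group_b], dtype=float),
        event_observed_A=np.array([o.event for o in group_a], dtype=bool),
        event_observed_B=np.array([o.event for o in group_b], dtype=bool),
    )
    return float(res.test_statistic), float(res.p_value)
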