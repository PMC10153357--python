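"""Sampling-time grids and exhaustive enumeration of imaging schedules.

Three schedule families are swept in the simulation study:

* STP: every hour from 1 to 240 h post-injection (240 times).
* 2TP: every unordered pair from the 4-hourly grid 4, 8, ..., 240 h
  (60 times, 1770 pairs).
* 3TP: triples restricted to realistic clinic hours -- with injection at the
  start of day 0, scans can only happen at the beginning (24k h), middle
  (24k + 4 h) and end (24k + 8 h) of each day (30 valid times up to 240 h), and
  no two scans may fall on the same day (pairwise gap > 12 h).  This yields
  3294 admissible triples.

Clinical 4-scan data is grouped into four nominal time periods (days 0, 1-2,
3-5 and 6-8) and reduced-time-point fits use every 2- or 3-subset of the four
scans (6 and 4 combinations).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SamplingSchedule",
    "TimePeriod",
    "DEFAULT_TIME_PERIODS",
    "stp_grid",
    "two_tp_grid",
    "enumerate_2tp",
    "three_tp_times",
    "enumerate_3tp",
    "clinical_combinations",
    "assign_time_period",
]


@dataclass(frozen=True)
class SamplingSchedule:
    """An ordered set of 1-3 imaging times (hours post-injection)."""

    times: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        object.__setattr__(self, "times", times)
        if not 1 <= len(times) <= 3:
            raise ValueError("schedule must hold 1-3 times")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("schedule times must be strictly increasing")


@dataclass(frozen=True)
class TimePeriod:
    """A nominal imaging window, e.g. t_D3_5 = 71-126 h (days 3-5)."""

    label: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("window must have low < high")

    def contains(self, t: float) -> bool:
        return self.low <= t <= self.high


DEFAULT_TIME_PERIODS = (
    TimePeriod("t_D0", 3.0, 5.0),
    TimePeriod("t_D1_2", 21.0, 52.0),
    TimePeriod("t_D3_5", 71.0, 126.0),
    TimePeriod("t_D6_8", 144.0, 194.0),
)


def stp_grid() -> list[int]:
    """Hourly single-time-point grid: 1, 2, ..., 240 h."""
    return list(range(1, 241))


def two_tp_grid() -> list[int]:
    """4-hourly grid for two-point schedules: 4, 8, ..., 240 h (60 times)."""
    return list(range(4, 241, 4))


def enumerate_2tp() -> list[SamplingSchedule]:
    """All increasing pairs from the 4-hourly grid (1770 schedules)."""
    return [SamplingSchedule(p) for p in itertools.combinations(two_tp_grid(), 2)]


def three_tp_times() -> list[int]:
    """Admissible 3TP scan times: the three daily slots of days 0-10 (30 times).

    Day 0 offers only the middle (4 h) and end (8 h) slots; day 10 only the
    beginning (240 h).
    """
    times = {4, 8, 240}
    for k in range(1, 10):
        times.update((24 * k, 24 * k + 4, 24 * k + 8))
    return sorted(times)


def enumerate_3tp() -> list[SamplingSchedule]:
    """All increasing triples of admissible times with pairwise gap > 12 h.

    The gap rule forbids two scans on the same day; across days every gap is at
    least 16 h, so the rule is equivalent to one-scan-per-day (3294 schedules).
    """
    out = []
    for trip in itertools.combinations(three_tp_times(), 3):
        if all(t2 - t1 > 12 for t1, t2 in itertools.combinations(trip, 2)):
            out.append(SamplingSchedule(trip))
    return out


def clinical_combinations(n_scans: int = 4, r: int = 2) -> list[tuple[int, ...]]:
    """All r-subsets of a patient's scan indices (r strictly below n_scans)."""
    if not 2 <= r < n_scans:
        raise ValueError(
            f"r must satisfy 2 <= r < n_scans (got r={r}, n_scans={n_scans}); "
            "r = n_scans is the reference fit itself"
        )
    return list(itertools.combinations(range(n_scans), r))


def assign_time_period(t: float, periods=DEFAULT_TIME_PERIODS) -> str:
    """Map a scan time to its nominal period label.

    Times inside a window map directly; times between windows (clinical
    scheduling is imperfect) map to the period with the nearest boundary, with
    a warning recorded.
    """
    if not t > 0:
        raise ValueError("time must be positive")
    for p in periods:
        if p.contains(t):
            return p.label
    dists = [(min(abs(t - p.low), abs(t - p.high)), i) for i, p in enumerate(periods)]
    _, idx = min(dists)
    best = periods[idx]
    warnings.warn(
        f"scan time {t} h outside all nominal windows; assigned to nearest "
        f"period {best.label} ({best.low}-{best.high} h)"
    )
    return best.label
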