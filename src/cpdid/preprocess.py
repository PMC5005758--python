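"""Epidemiologic preprocessing: event records to quarterly count series.

Raw input is one row per injury event (timestamp, age, group label). The
inclusion rules select school-age pedestrians (5-19 years) injured during
school-travel hours -- weekdays 7-9 AM or 2-4 PM, September through June --
and the retained events are aggregated into dense quarterly count series per
group, with population offsets linearly interpolated between the 2000 and
2010 census anchors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SCHOOL_AGE_MIN = 5
SCHOOL_AGE_MAX = 19
#: months with school in session (September through June)
SCHOOL_MONTHS = frozenset({1, 2, 3, 4, 5, 6, 9, 10, 11, 12})
#: school-travel hour bands, half-open: [7, 9) and [14, 16) local time
TRAVEL_HOURS = frozenset({7, 8, 14, 15})

#: quarters between the 2000 census anchor (2000 Q1) and the 2010 anchor
QUARTERS_PER_DECADE = 40
CENSUS_ANCHOR_YEAR = 2000


@dataclass(frozen=True)
class CrashRecord:
    """A single injury event: when it happened, to whom, and where (by group).

    ``group`` is a free-text stratum label (e.g. ``"SRTS"`` vs
    ``"non-SRTS"``); census-tract assignment from coordinates is upstream of
    this package and arrives as this label.
    """

    timestamp: datetime
    age: int
    group: str

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be nonnegative, got {self.age}")


@dataclass
class QuarterlySeries:
    """Aligned quarterly counts and population offsets for one group.

    ``t`` is the 1-based quarter index (t=1 is ``start_year`` Q1), ``y`` the
    event count, and ``O`` the positive population offset entering the
    log-linear mean as ``log O_t``.
    """

    t: np.ndarray
    year: np.ndarray
    quarter: np.ndarray
    y: np.ndarray
    O: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=int)
        self.year = np.asarray(self.year, dtype=int)
        self.quarter = np.asarray(self.quarter, dtype=int)
        self.y = np.asarray(self.y, dtype=int)
        self.O = np.asarray(self.O, dtype=float)
        n = len(self.t)
        if not (len(self.year) == len(self.quarter) == len(self.y) == len(self.O) == n):
            raise ValueError("all series columns must have equal length")
        if n and not np.array_equal(self.t, np.arange(self.t[0], self.t[0] + n)):
            raise ValueError("quarter index t must increase by exactly 1")
        if np.any(self.y < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(self.O <= 0):
            raise ValueError("population offsets must be strictly positive")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "year": self.year,
                "quarter": self.quarter,
                "count": self.y,
                "population": self.O,
                "group": self.group,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group: str | None = None) -> "QuarterlySeries":
        if group is not None:
            df = df[df["group"] == group]
        elif "group" in df.columns and df["group"].nunique() > 1:
            raise ValueError("frame holds multiple groups; pass group=")
        df = df.sort_values("t")
        label = group if group is not None else (
            str(df["group"].iloc[0]) if "group" in df.columns and len(df) else ""
        )
        return cls(
            t=df["t"].to_numpy(),
            year=df["year"].to_numpy(),
            quarter=df["quarter"].to_numpy(),
            y=df["count"].to_numpy(),
            O=df["population"].to_numpy(),
            group=label,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, group: str | None = None) -> "QuarterlySeries":
        return cls.from_frame(pd.read_csv(path), group=group)


def is_school_travel(timestamp: datetime) -> bool:
    """True iff the event falls in the school-travel exposure window.

    The window is Monday-Friday, September through June, during the hour
    bands [7, 9) or [14, 16) local time. Half-open bands mean an event at
    exactly 9:00 or 16:00 is excluded. The decision depends only on weekday,
    month and hour, never on the year.
    """
    return (
        timestamp.weekday() < 5
        and timestamp.month in SCHOOL_MONTHS
        and timestamp.hour in TRAVEL_HOURS
    )


def is_school_age(age: int) -> bool:
    """True iff ``age`` lies in the school-age range 5-19, both ends inclusive."""
    if age < 0:
        raise ValueError(f"age must be nonnegative, got {age}")
    return SCHOOL_AGE_MIN <= age <= SCHOOL_AGE_MAX


def interpolate_population(p2000: float, p2010: float, quarters_since_2000: float) -> float:
    """Population at a quarter, linear between the two decennial census anchors.

    The anchors are quarter 1 of 2000 (``quarters_since_2000 = 0``) and
    quarter 1 of 2010 (``quarters_since_2000 = 40``); the line extends
    beyond the anchors for quarters outside the decade.
    """
    if p2000 <= 0 or p2010 <= 0:
        raise ValueError("census anchor populations must be positive")
    return p2000 + (p2010 - p2000) * quarters_since_2000 / QUARTERS_PER_DECADE


def quarter_offsets(
    p2000: float, p2010: float, start_year: int, n_quarters: int
) -> np.ndarray:
    """Interpolated population for quarters t=1..n_quarters from ``start_year`` Q1."""
    shift = 4 * (start_year - CENSUS_ANCHOR_YEAR)
    t = np.arange(1, n_quarters + 1)
    return np.array(
        [interpolate_population(p2000, p2010, shift + (ti - 1)) for ti in t]
    )


def rate_per_10k(count: float, population: float) -> float:
    """Event rate per 10,000 population."""
    if population <= 0:
        raise ValueError("population must be positive")
    return count / population * 10_000


def percent_change(old: float, new: float) -> float:
    """Relative change (new - old) / old, as a proportion."""
    if old == 0:
        raise ValueError("baseline value must be nonzero")
    return (new - old) / old


def circular_buffer_area(radius_ft: float) -> float:
    """Area in square feet of a circular geographic buffer of ``radius_ft`` feet."""
    if radius_ft <= 0:
        raise ValueError("radius must be positive")
    return math.pi * radius_ft**2


def _quarter_index(ts: datetime, start_year: int) -> int:
    return 4 * (ts.year - start_year) + (ts.month - 1) // 3 + 1


def aggregate_quarterly(
    records: Iterable[CrashRecord] | pd.DataFrame,
    start_year: int,
    n_quarters: int,
    populations: Mapping[str, tuple[float, float]],
    pre_filtered: bool = False,
) -> dict[str, QuarterlySeries]:
    """Aggregate event records into dense per-group quarterly count series.

    Unless ``pre_filtered``, both inclusion rules (:func:`is_school_travel`
    and :func:`is_school_age`) are applied first. Quarters with no retained
    events appear with a zero count, so every series has exactly
    ``n_quarters`` rows and the counts sum to the number of retained
    records. ``populations`` maps each group label to its
    ``(census-2000, census-2010)`` anchor counts, from which the offsets are
    interpolated.

    Raises ``ValueError`` if any retained record falls outside
    ``[start_year Q1, start_year Q1 + n_quarters)``, reporting how many do.
    """
    if isinstance(records, pd.DataFrame):
        it = (
            CrashRecord(ts.to_pydatetime() if hasattr(ts, "to_pydatetime") else ts,
                        int(a), str(g))
            for ts, a, g in zip(
                pd.to_datetime(records["timestamp"]), records["age"], records["group"]
            )
        )
        records = it

    kept: list[CrashRecord] = []
    for rec in records:
        if pre_filtered or (is_school_travel(rec.timestamp) and is_school_age(rec.age)):
            kept.append(rec)

    out_of_range = sum(
        1 for r in kept if not 1 <= _quarter_index(r.timestamp, start_year) <= n_quarters
    )
    if out_of_range:
        raise ValueError(
            f"{out_of_range} retained record(s) fall outside the "
            f"{n_quarters}-quarter window starting {start_year} Q1"
        )

    groups = sorted(populations)
    counts = {g: np.zeros(n_quarters, dtype=int) for g in groups}
    for r in kept:
        if r.group not in counts:
            raise KeyError(f"no census populations supplied for group {r.group!r}")
        counts[r.group][_quarter_index(r.timestamp, start_year) - 1] += 1

    t = np.arange(1, n_quarters + 1)
    years = start_year + (t - 1) // 4
    quarters = (t - 1) % 4 + 1
    out = {}
    for g in groups:
        p2000, p2010 = populations[g]
        out[g] = QuarterlySeries(
            t=t,
            year=years,
            quarter=quarters,
            y=counts[g],
            O=quarter_offsets(p2000, p2010, start_year, n_quarters),
            group=g,
        )
    return out


def records_to_frame(records: Iterable[CrashRecord]) -> pd.DataFrame:
    """Event records as a tidy frame (ISO-8601 timestamp, integer age, group)."""
    recs = list(records)
    return pd.DataFrame(
        {
            "timestamp": [r.timestamp.isoformat() for r in recs],
            "age": [r.age for r in recs],
            "group": [r.group for r in recs],
        }
    )
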