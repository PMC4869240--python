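"""Event calendars for single-day awareness campaigns.

The campaign event modelled here is an annual awareness day held on the third
Thursday of November (the Great American Smokeout convention); the baseline
comparison event is New Year's Day, the day conventionally assumed to see the
largest spike in cessation-related activity.  Both are treated as single
calendar days, timezone-free: every stream is assumed to be aggregated to
calendar days upstream.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

CAMPAIGN = "campaign"
BASELINE = "baseline"
EVENT_KINDS = (CAMPAIGN, BASELINE)

_FIRST_CAMPAIGN_YEAR = 1976

_THURSDAY = 3  # datetime.weekday() convention, Monday == 0


def _check_year(year: object, minimum: int = dt.MINYEAR) -> int:
    if isinstance(year, bool) or not isinstance(year, int):
        raise ValueError(f"year must be an integer, got {year!r}")
    if not (minimum <= year <= dt.MAXYEAR):
        raise ValueError(f"year {year} outside valid range [{minimum}, {dt.MAXYEAR}]")
    return year


def campaign_date(year: int) -> dt.date:
    """Third Thursday of November of ``year``.

    Raises ``ValueError`` for non-integer years or years before the first
    campaign era (1976).
    """
    year = _check_year(year, minimum=_FIRST_CAMPAIGN_YEAR)
    first = dt.date(year, 11, 1)
    offset = (_THURSDAY - first.weekday()) % 7
    return first + dt.timedelta(days=offset + 14)


def baseline_date(year: int) -> dt.date:
    """January 1 of ``year``."""
    return dt.date(_check_year(year), 1, 1)


def event_date(year: int, kind: str) -> dt.date:
    if kind == CAMPAIGN:
        return campaign_date(year)
    if kind == BASELINE:
        return baseline_date(year)
    raise ValueError(f"unknown event kind {kind!r}; expected one of {EVENT_KINDS}")


@dataclass(frozen=True)
class EventCalendar:
    """Dated single-day events of named kinds over a span of years.

    Invariants (checked on construction): every event lies inside ``span``, at
    most one event of a given kind per calendar year, and campaign dates are
    third Thursdays of November.
    """

    events: tuple[tuple[dt.date, str], ...]
    span: tuple[dt.date, dt.date] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        events = tuple(sorted((pd.Timestamp(d).date(), k) for d, k in self.events))
        object.__setattr__(self, "events", events)
        if self.span is None:
            if not events:
                raise ValueError("empty calendar requires an explicit span")
            object.__setattr__(self, "span", (events[0][0], events[-1][0]))
        else:
            lo, hi = (pd.Timestamp(x).date() for x in self.span)
            object.__setattr__(self, "span", (lo, hi))
        lo, hi = self.span
        seen: set[tuple[int, str]] = set()
        for d, k in events:
            if k not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {k!r}")
            if not (lo <= d <= hi):
                raise ValueError(f"event {d} ({k}) outside calendar span {lo}..{hi}")
            if (d.year, k) in seen:
                raise ValueError(f"more than one {k} event in {d.year}")
            seen.add((d.year, k))
            if k == CAMPAIGN and (d.weekday() != _THURSDAY or not 15 <= d.day <= 21
                                  or d.month != 11):
                raise ValueError(f"campaign date {d} is not a third Thursday of November")

    @classmethod
    def from_years(cls, years: Iterable[int], kinds: Sequence[str] = EVENT_KINDS,
                   span: tuple[dt.date, dt.date] | None = None) -> "EventCalendar":
        events = [(event_date(y, k), k) for y in years for k in kinds]
        return cls(tuple(events), span)

    def dates(self, kind: str) -> list[dt.date]:
        if kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {kind!r}")
        return [d for d, k in self.events if k == kind]

    def years(self, kind: str) -> list[int]:
        return [d.year for d in self.dates(kind)]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.events, columns=["date", "kind"])
        df["date"] = df["date"].map(lambda d: d.isoformat())
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path,
                 span: tuple[dt.date, dt.date] | None = None) -> "EventCalendar":
        df = pd.read_csv(path)
        missing = {"date", "kind"} - set(df.columns)
        if missing:
            raise ValueError(f"calendar file missing column(s) {sorted(missing)}")
        events = [(dt.date.fromisoformat(str(r.date)), str(r.kind))
                  for r in df.itertuples()]
        return cls(tuple(events), span)


def build_event_indicator(dates: pd.DatetimeIndex, calendar: EventCalendar,
                          kind: str):
    """Binary daily indicator: 1 exactly on event days of ``kind`` inside ``dates``.

    ``dates`` must be a contiguous, strictly increasing daily range.
    """
    import numpy as np

    dates = pd.DatetimeIndex(dates)
    if len(dates) == 0:
        raise ValueError("empty date range")
    expected = pd.date_range(dates[0], dates[-1], freq="D")
    if len(dates) != len(expected) or not (dates == expected).all():
        raise ValueError("date range must be contiguous daily and strictly increasing")
    event_days = {pd.Timestamp(d) for d in calendar.dates(kind)}
    return np.fromiter((1 if d in event_days else 0 for d in dates),
                       dtype=float, count=len(dates))
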