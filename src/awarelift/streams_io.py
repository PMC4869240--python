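"""Daily stream containers, normalization, and long-CSV panel I/O.

Each infoveillance stream arrives as daily counts plus (depending on the
source) a denominator, and is normalized once, before any modelling:

* ``proportion`` — counts divided by an all-items denominator (news stories
  mentioning cessation relative to all news stories);
* ``per_million`` — counts per million denominator items (Wikipedia page
  views per million English-language page views);
* ``rsv`` — relative search volume: the daily search proportion rescaled so
  the highest day in the window equals 100;
* ``raw_count`` — used unchanged when no suitable denominator exists
  (quitline calls, tweet counts); trend and seasonality are handled later by
  the estimation model instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, PanelFormatError, StreamDataError

NORMALIZATION_KINDS = ("proportion", "per_million", "rsv", "raw_count")

#: Google Trends reports integer RSV; the float dialect keeps full precision.
RSV_MAX = 100.0
_RSV_TOL = 0.5  # rounding tolerance on the maximum of an rsv series


@dataclass(frozen=True)
class DailySeries:
    """A contiguous daily sequence of non-negative values for one stream."""

    dates: pd.DatetimeIndex
    values: np.ndarray
    kind: str
    label: str = ""

    def __post_init__(self):
        dates = pd.DatetimeIndex(self.dates)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "values", values)
        problem = _invariant_violation(self)
        if problem is not None:
            raise StreamDataError(f"{self.label or 'series'}: {problem}")

    def __len__(self) -> int:
        return len(self.values)

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.dates, name=self.label)

    def value_on(self, day) -> float:
        ts = pd.Timestamp(day)
        loc = self.dates.get_indexer([ts])[0]
        if loc < 0:
            raise ValueError(f"{ts.date()} not in series span")
        return float(self.values[loc])


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    message: str = "pass"


def _invariant_violation(series: DailySeries) -> str | None:
    """First violated invariant of a DailySeries, or None."""
    if series.kind not in NORMALIZATION_KINDS:
        return f"unknown normalization kind {series.kind!r}"
    if len(series.dates) != len(series.values):
        return "dates and values have different lengths"
    if len(series.dates) == 0:
        return None
    expected = pd.date_range(series.dates[0], series.dates[-1], freq="D")
    if len(series.dates) != len(expected) or not (series.dates == expected).all():
        missing = expected.difference(series.dates)
        first = missing[0].date() if len(missing) else series.dates[0].date()
        return f"dates not contiguous daily (first missing: {first})"
    if not np.all(np.isfinite(series.values)):
        return "non-finite value present"
    if np.any(series.values < 0):
        day = series.dates[int(np.argmin(series.values >= 0))].date()
        return f"negative value on {day}"
    if series.kind == "proportion" and np.any(series.values > 1):
        return "proportion out of [0,1]"
    if series.kind == "rsv" and abs(series.values.max(initial=0.0) - RSV_MAX) > _RSV_TOL:
        return f"rsv maximum {series.values.max(initial=0.0):g} != 100"
    return None


def validate_series(series: DailySeries) -> ValidationReport:
    """Check all DailySeries invariants; violations are reported, not raised."""
    problem = _invariant_violation(series)
    return ValidationReport(True) if problem is None else ValidationReport(False, problem)


def normalize_series(numerator, denominator=None, kind: str = "raw_count", *,
                     dates=None, label: str = "", round_rsv: bool = False) -> DailySeries:
    """Normalize daily counts into a :class:`DailySeries` of the given kind.

    Parameters
    ----------
    numerator : array-like
        Daily counts (for ``rsv``, the daily proportion before rescaling may
        also be passed directly with ``denominator=None``).
    denominator : array-like, optional
        Required (strictly positive) for ``proportion`` and ``per_million``;
        optional for ``rsv``; forbidden for ``raw_count``.
    round_rsv : bool
        Reproduce the public Google Trends dialect by rounding RSV to
        integers.  Off by default: rounding loses information that recovery
        tests rely on.
    """
    num = np.asarray(numerator, dtype=float)
    if dates is None:
        dates = pd.date_range("2000-01-01", periods=len(num), freq="D")
    dates = pd.DatetimeIndex(dates)
    if np.any(num < 0):
        day = dates[int(np.argmax(num < 0))].date()
        raise StreamDataError(f"negative numerator on {day}")

    if kind == "raw_count":
        if denominator is not None:
            raise ValueError("raw_count takes no denominator")
        return DailySeries(dates, num, kind, label)

    if kind in ("proportion", "per_million"):
        if denominator is None:
            raise ValueError(f"{kind} requires a denominator")
        den = np.asarray(denominator, dtype=float)
        bad = den <= 0
        if np.any(bad):
            day = dates[int(np.argmax(bad))].date()
            raise StreamDataError(f"non-positive denominator on {day}")
        ratio = num / den
        if kind == "per_million":
            ratio = ratio * 1_000_000.0
        return DailySeries(dates, ratio, kind, label)

    if kind == "rsv":
        if denominator is not None:
            den = np.asarray(denominator, dtype=float)
            bad = den <= 0
            if np.any(bad):
                day = dates[int(np.argmax(bad))].date()
                raise StreamDataError(f"non-positive denominator on {day}")
            prop = num / den
        else:
            prop = num
        top = prop.max(initial=0.0)
        if top <= 0:
            raise DegenerateInputError("all-zero series: rsv maximum undefined")
        out = prop / top * RSV_MAX
        if round_rsv:
            out = np.round(out)
        return DailySeries(dates, out, kind, label)

    raise ValueError(f"unknown normalization kind {kind!r}")


def read_panel(path: str | Path) -> dict[str, DailySeries]:
    """Read a long-format panel CSV (``date,stream,kind,value``) into series.

    Gaps in a stream's dates are a data error, not silently filled: the
    estimation model assumes contiguous daily series and no imputation rule
    is defined for these sources.
    """
    df = pd.read_csv(path)
    required = {"date", "stream", "kind", "value"}
    missing = required - set(df.columns)
    if missing:
        raise PanelFormatError(f"panel missing column(s) {sorted(missing)}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise PanelFormatError(f"unparseable date in panel: {exc}") from exc
    dup = df.duplicated(subset=["date", "stream"])
    if dup.any():
        row = df[dup].iloc[0]
        raise StreamDataError(
            f"duplicate (date, stream) entry: ({row['date'].date()}, {row['stream']})")

    out: dict[str, DailySeries] = {}
    for label, grp in df.groupby("stream", sort=True):
        grp = grp.sort_values("date")
        kinds = grp["kind"].unique()
        if len(kinds) != 1:
            raise StreamDataError(f"{label}: mixed normalization kinds {sorted(kinds)}")
        dates = pd.DatetimeIndex(grp["date"])
        expected = pd.date_range(dates[0], dates[-1], freq="D")
        if len(dates) != len(expected):
            first_gap = expected.difference(dates)[0].date()
            raise StreamDataError(f"{label}: gap in dates (first missing: {first_gap})")
        out[str(label)] = DailySeries(dates, grp["value"].to_numpy(dtype=float),
                                      str(kinds[0]), str(label))
    return out


def write_panel(panel: Mapping[str, DailySeries], path: str | Path) -> None:
    """Write series to a long-format CSV, full float precision (round-trip safe)."""
    frames = []
    for label in sorted(panel):
        s = panel[label]
        frames.append(pd.DataFrame({
            "date": s.dates.strftime("%Y-%m-%d"),
            "stream": s.label or label,
            "kind": s.kind,
            "value": np.array([repr(float(v)) for v in s.values]),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
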