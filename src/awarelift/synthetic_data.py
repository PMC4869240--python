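"""Synthetic multi-stream daily panels with known injected event lifts.

The generator emulates exactly the structures the estimation model adjusts
for — linear trend, circaseptan (day-of-week) periodicity, annual
seasonality — plus stream-appropriate noise, and injects multiplicative
single-day lifts on event days.  The injected lift delta is the ground truth
that every recovery test scores against: a value is scaled by (1 + delta) on
the event day, commensurable with the estimator's ratio effect
(observed − counterfactual) / counterfactual.

The expected value on day t is

    (baseline + trend * t) * weekly[dow(t)] * (1 + A * cos(2*pi*doy(t)/365.25))
        * (1 + delta  if t is an event day)

with Poisson or multiplicative Gaussian-AR(1) noise applied on top.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import calendar_events as cal
from .streams_io import DailySeries, normalize_series
from .tweet_filter import ShortText, RELEVANT, IRRELEVANT


@dataclass(frozen=True)
class GaussianAR1:
    """Multiplicative Gaussian AR(1) noise: value = mean * (1 + e_t), where
    e_t = phi * e_{t-1} + innovation and sd(e_t) = sigma (stationary)."""
    sigma: float
    phi: float = 0.0

    def __post_init__(self):
        if not 0 <= self.phi < 1:
            raise ValueError("phi must be in [0, 1)")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def cosine_weekly(amplitude: float) -> np.ndarray:
    """A 7-day multiplier profile 1 + amplitude*cos(2*pi*i/7); mean exactly 1."""
    i = np.arange(7)
    return 1.0 + amplitude * np.cos(2 * np.pi * i / 7)


@dataclass(frozen=True)
class StreamConfig:
    """Generative settings for one stream.

    ``noise`` is ``None`` (deterministic), ``"poisson"``, or a
    :class:`GaussianAR1`.  ``lifts`` maps (event kind, year) -> delta and
    overrides the panel-level lifts for this stream.
    """
    baseline: float
    kind: str = "raw_count"
    trend: float = 0.0                      # stream units per day
    weekly: Optional[Sequence[float]] = None  # 7 positive multipliers, mean 1
    annual_amplitude: float = 0.0           # fraction of level
    noise: object = None
    lifts: Optional[Mapping[tuple[str, int], float]] = None

    def __post_init__(self):
        if self.weekly is not None:
            w = np.asarray(self.weekly, dtype=float)
            if w.shape != (7,) or np.any(w <= 0) or abs(w.mean() - 1) > 1e-8:
                raise ValueError("weekly profile needs 7 positive multipliers with mean 1")
            object.__setattr__(self, "weekly", tuple(w))
        if self.noise not in (None, "poisson") and not isinstance(self.noise, GaussianAR1):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass(frozen=True)
class SyntheticPanelConfig:
    span: tuple[dt.date, dt.date]
    streams: Mapping[str, StreamConfig]
    event_lifts: Mapping[tuple[str, int], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        lo, hi = (pd.Timestamp(x).date() for x in self.span)
        object.__setattr__(self, "span", (lo, hi))
        object.__setattr__(self, "streams", dict(self.streams))
        object.__setattr__(self, "event_lifts", dict(self.event_lifts))
        for (kind, year), delta in self._all_lifts():
            if delta <= -1:
                raise ValueError(f"lift for ({kind}, {year}) must exceed -1")
            d = cal.event_date(year, kind)
            if not (lo <= d <= hi):
                raise ValueError(f"event ({kind}, {year}) on {d} outside span {lo}..{hi}")

    def _all_lifts(self):
        seen = list(self.event_lifts.items())
        for sc in self.streams.values():
            if sc.lifts:
                seen.extend(sc.lifts.items())
        return seen

    def lifts_for(self, stream: str) -> dict[tuple[str, int], float]:
        sc = self.streams[stream]
        merged = dict(self.event_lifts)
        if sc.lifts:
            merged.update(sc.lifts)
        return merged


def _noise_to_obj(noise) -> object:
    if noise is None:
        return "none"
    if noise == "poisson":
        return "poisson"
    return {"gaussian_ar1": {"sigma": noise.sigma, "phi": noise.phi}}


def _noise_from_obj(obj) -> object:
    if obj in (None, "none"):
        return None
    if obj == "poisson":
        return "poisson"
    if isinstance(obj, dict) and "gaussian_ar1" in obj:
        return GaussianAR1(**obj["gaussian_ar1"])
    raise ValueError(f"unknown noise spec {obj!r}")


def config_to_dict(config: SyntheticPanelConfig) -> dict:
    """Plain-dict form of a panel config (YAML/JSON safe)."""
    def lifts_out(lifts):
        return {f"{kind}:{year}": delta for (kind, year), delta in sorted(lifts.items())}

    streams = {}
    for name, sc in sorted(config.streams.items()):
        entry = {"baseline": sc.baseline, "kind": sc.kind, "trend": sc.trend,
                 "annual_amplitude": sc.annual_amplitude,
                 "noise": _noise_to_obj(sc.noise)}
        if sc.weekly is not None:
            entry["weekly"] = [float(w) for w in sc.weekly]
        if sc.lifts:
            entry["lifts"] = lifts_out(sc.lifts)
        streams[name] = entry
    return {"span": [config.span[0].isoformat(), config.span[1].isoformat()],
            "seed": config.seed, "event_lifts": lifts_out(config.event_lifts),
            "streams": streams}


def config_from_dict(raw: dict) -> SyntheticPanelConfig:
    def lifts_in(obj):
        out = {}
        for key, delta in (obj or {}).items():
            kind, year = key.split(":")
            out[(kind, int(year))] = float(delta)
        return out

    streams = {}
    for name, entry in raw["streams"].items():
        streams[name] = StreamConfig(
            baseline=float(entry["baseline"]), kind=entry.get("kind", "raw_count"),
            trend=float(entry.get("trend", 0.0)),
            weekly=entry.get("weekly"),
            annual_amplitude=float(entry.get("annual_amplitude", 0.0)),
            noise=_noise_from_obj(entry.get("noise")),
            lifts=lifts_in(entry.get("lifts")) or None)
    lo, hi = (dt.date.fromisoformat(s) for s in raw["span"])
    return SyntheticPanelConfig(span=(lo, hi), streams=streams,
                                event_lifts=lifts_in(raw.get("event_lifts")),
                                seed=int(raw.get("seed", 0)))


def config_to_yaml(config: SyntheticPanelConfig, path) -> None:
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def config_from_yaml(path) -> SyntheticPanelConfig:
    import yaml
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def _expected_curve(config: SyntheticPanelConfig, stream: str,
                    with_lifts: bool = True) -> tuple[pd.DatetimeIndex, np.ndarray]:
    sc = config.streams[stream]
    dates = pd.date_range(config.span[0], config.span[1], freq="D")
    t = np.arange(len(dates), dtype=float)
    mean = sc.baseline + sc.trend * t
    if sc.weekly is not None:
        mean = mean * np.asarray(sc.weekly)[dates.dayofweek]
    if sc.annual_amplitude:
        doy = dates.dayofyear.to_numpy(dtype=float)
        mean = mean * (1 + sc.annual_amplitude * np.cos(2 * np.pi * doy / 365.25))
    if with_lifts:
        for (kind, year), delta in config.lifts_for(stream).items():
            day = pd.Timestamp(cal.event_date(year, kind))
            loc = dates.get_indexer([day])[0]
            if loc >= 0:
                mean[loc] *= (1 + delta)
    if np.any(mean < 0):
        raise ValueError(f"{stream}: negative expected value (trend too steep?)")
    return dates, mean


def _stream_rng(config: SyntheticPanelConfig, stream: str) -> np.random.Generator:
    # one independent, reproducible substream per stream name
    order = sorted(config.streams)
    return np.random.default_rng([config.seed, order.index(stream)])


def generate_stream(config: SyntheticPanelConfig, stream: str) -> DailySeries:
    """One synthetic daily series; deterministic under the config's seed."""
    if stream not in config.streams:
        raise ValueError(f"unknown stream {stream!r}")
    sc = config.streams[stream]
    dates, mean = _expected_curve(config, stream)
    rng = _stream_rng(config, stream)
    if sc.noise is None:
        values = mean.copy()
    elif sc.noise == "poisson":
        values = rng.poisson(mean).astype(float)
    else:  # GaussianAR1, multiplicative
        n = len(mean)
        phi, sigma = sc.noise.phi, sc.noise.sigma
        innov_sd = sigma * np.sqrt(1 - phi ** 2)
        e = np.empty(n)
        z = rng.normal(0.0, 1.0, n)
        e[0] = sigma * z[0]
        for i in range(1, n):
            e[i] = phi * e[i - 1] + innov_sd * z[i]
        values = np.clip(mean * (1 + e), 0.0, None)
    if sc.kind == "raw_count" and sc.noise == "poisson":
        values = np.round(np.clip(values, 0, None))
    if sc.kind == "rsv":
        return normalize_series(values, None, "rsv", dates=dates, label=stream)
    return DailySeries(dates, values, sc.kind, stream)


def generate_panel(config: SyntheticPanelConfig
                   ) -> tuple[dict[str, DailySeries], dict]:
    """All configured streams on one date index, plus the ground-truth record.

    The truth record maps stream -> {(kind, year): {"delta", "expected_base",
    "expected_excess"}}, where expected_base is the event-day expectation
    without the lift and expected_excess = delta * expected_base, both on the
    generated series' scale.  For rsv streams the post-rescaling factor
    depends on the realized maximum, so excess truth is reported on the
    pre-rescaling scale.
    """
    if not config.streams:
        raise ValueError("no streams configured")
    panel = {name: generate_stream(config, name) for name in sorted(config.streams)}
    truth: dict[str, dict] = {}
    for name in sorted(config.streams):
        dates, base = _expected_curve(config, name, with_lifts=False)
        entry = {}
        for (kind, year), delta in sorted(config.lifts_for(name).items()):
            day = pd.Timestamp(cal.event_date(year, kind))
            loc = dates.get_indexer([day])[0]
            entry[(kind, year)] = {
                "delta": float(delta),
                "expected_base": float(base[loc]),
                "expected_excess": float(delta * base[loc]),
            }
        truth[name] = entry
    return panel, truth


# --- default study panel ---------------------------------------------------

#: Default lifts applied on campaign / New Year's days in the default panel.
DEFAULT_CAMPAIGN_LIFTS = {"news": 0.6, "tweets": 0.15, "search": 0.25,
                          "wikipedia": 0.2, "quitline": 0.4}
DEFAULT_BASELINE_LIFTS = {"news": 1.2, "tweets": 0.3, "search": 0.35,
                          "wikipedia": 0.3, "quitline": 0.6}


def default_panel_config(seed: int = 0,
                         span: tuple[str, str] = ("2008-01-01", "2014-12-31"),
                         event_years: Optional[Sequence[int]] = None,
                         ) -> SyntheticPanelConfig:
    """Five streams loosely emulating the case study's source magnitudes:
    news proportion ~1e-3, tweets ~300/day, search as RSV, Wikipedia
    per-million ~1, quitline ~500 calls/day.

    ``event_years`` defaults to every year whose campaign and New Year's
    days both fall inside ``span``."""
    lo = dt.date.fromisoformat(span[0])
    hi = dt.date.fromisoformat(span[1])
    if event_years is None:
        event_years = [y for y in range(lo.year, hi.year + 1)
                       if lo <= cal.baseline_date(y) <= hi
                       and lo <= cal.campaign_date(y) <= hi]
    weekly = tuple(cosine_weekly(0.2))
    ar1 = GaussianAR1(sigma=0.05, phi=0.3)

    def lifts(table):
        out = {}
        for year in event_years:
            out[("campaign", year)] = table
        return out

    streams = {
        "news": StreamConfig(baseline=1.2e-3, kind="proportion", trend=-8e-8,
                             weekly=weekly, annual_amplitude=0.10, noise=ar1),
        "tweets": StreamConfig(baseline=250.0, kind="raw_count", trend=0.05,
                               weekly=weekly, annual_amplitude=0.08, noise="poisson"),
        "search": StreamConfig(baseline=60.0, kind="rsv", trend=-2e-3,
                               weekly=weekly, annual_amplitude=0.12, noise=ar1),
        "wikipedia": StreamConfig(baseline=1.0, kind="per_million", trend=0.0,
                                  weekly=weekly, annual_amplitude=0.10, noise=ar1),
        "quitline": StreamConfig(baseline=500.0, kind="raw_count", trend=0.0,
                                 weekly=weekly, annual_amplitude=0.15, noise="poisson"),
    }
    event_lifts: dict[tuple[str, int], float] = {}
    per_stream: dict[str, dict] = {name: {} for name in streams}
    for year in event_years:
        for name in streams:
            per_stream[name][("campaign", year)] = DEFAULT_CAMPAIGN_LIFTS[name]
            per_stream[name][("baseline", year)] = DEFAULT_BASELINE_LIFTS[name]
    streams = {name: replace(sc, lifts=per_stream[name]) for name, sc in streams.items()}
    return SyntheticPanelConfig(span=(dt.date.fromisoformat(span[0]),
                                      dt.date.fromisoformat(span[1])),
                                streams=streams, event_lifts=event_lifts, seed=seed)


def recovery_stream_config(seed: int, delta: float, year: int = 2014,
                           kind: str = "campaign",
                           noise: object = "default") -> SyntheticPanelConfig:
    """The single-stream recovery-study design: a news-like stream on the
    366-day window ending on the event day of ``year``.

    Conditions: weekly profile amplitude ±20%, annual cosine amplitude 10%,
    multiplicative Gaussian AR(1) noise with stationary sd 5% of level
    (phi = 0.3), no trend, and one injected multiplicative lift ``delta`` on
    the event day.  These are the fixed conditions every per-year recovery,
    null-calibration and coverage simulation uses.
    """
    day = cal.event_date(year, kind)
    start = day - dt.timedelta(days=365)
    if noise == "default":
        noise = GaussianAR1(sigma=0.05, phi=0.3)
    return SyntheticPanelConfig(
        span=(start, day),
        streams={"news": StreamConfig(baseline=1.2e-3, kind="proportion",
                                      weekly=tuple(cosine_weekly(0.2)),
                                      annual_amplitude=0.10, noise=noise)},
        event_lifts={(kind, year): delta},
        seed=seed)


# --- labeled short-text corpus ---------------------------------------------

_RELEVANT_TEMPLATES = (
    "i will quit smoking for good starting today",
    "day three since i stopped smoking and the cravings are real",
    "trying to quit smoking with nicotine patches wish me luck",
    "going to stop smoking cigarettes this year for my health",
    "finally quitting smoking my lungs deserve better",
    "promised my kids i would stop smoking before summer",
)
_IRRELEVANT_TEMPLATES = (
    "the old engine wont stop smoking in traffic again",
    "i quit my diet because the bbq brisket was smoking all day",
    "gotta stop smoking the brakes on these downhill runs",
    "the chimney wont quit smoking up the whole kitchen",
    "my grill keeps smoking i should quit overloading the charcoal",
    "quitting the race car league the exhaust is smoking too much",
)
_FILLERS = ("today", "tbh", "lol", "honestly", "fr", "again", "ugh", "ok")


def generate_tweet_corpus(daily_rate: float, relevant_fraction: float,
                          span: tuple[dt.date, dt.date], seed: int = 0,
                          label_noise: float = 0.0) -> list[ShortText]:
    """Labeled short texts; every text passes the keyword filter by construction.

    Relevant texts discuss cessation; irrelevant texts contain the keywords
    in off-topic contexts (engines, grills, chimneys).  ``label_noise`` flips
    the recorded label with the given probability, emulating coder error.
    """
    if daily_rate <= 0:
        raise ValueError("daily_rate must be positive")
    if not 0 <= relevant_fraction <= 1:
        raise ValueError("relevant_fraction must be in [0, 1]")
    if not 0 <= label_noise <= 1:
        raise ValueError("label_noise must be in [0, 1]")
    rng = np.random.default_rng([seed, 97])
    days = pd.date_range(pd.Timestamp(span[0]), pd.Timestamp(span[1]), freq="D")
    corpus: list[ShortText] = []
    for day in days:
        for _ in range(rng.poisson(daily_rate)):
            is_rel = rng.random() < relevant_fraction
            bank = _RELEVANT_TEMPLATES if is_rel else _IRRELEVANT_TEMPLATES
            text = bank[rng.integers(len(bank))]
            if rng.random() < 0.5:
                text = text + " " + _FILLERS[rng.integers(len(_FILLERS))]
            label = RELEVANT if is_rel else IRRELEVANT
            if label_noise and rng.random() < label_noise:
                label = IRRELEVANT if label == RELEVANT else RELEVANT
            corpus.append(ShortText(text=text, timestamp=day.date(), label=label))
    return corpus
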