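"""Campaign effects relative to the New Year's Day baseline, and absolute
excess activity in native stream units.

New Year's Day is conventionally the day with the largest spike in
cessation-related activity, so the ratio (campaign effect) / (baseline
effect) expresses a campaign's practical impact against the strongest
recurring natural experiment.  Absolute excess (observed − counterfactual,
summed over event days) is only interpretable as items for raw-count
streams; for normalized kinds it stays in native normalized units — turning
relative search volume into query counts would need an external calibration
that these sources do not provide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .event_effect import (EffectEstimate, FittedEventModel, _as_day_list,
                           counterfactual_day)
from .streams_io import DailySeries

_UNIT_LABELS = {
    "raw_count": "count",
    "proportion": "native normalized units (proportion)",
    "per_million": "native normalized units (per million)",
    "rsv": "native normalized units (RSV)",
}


@dataclass(frozen=True)
class RelativeEffect:
    stream: str
    campaign_effect: float
    baseline_effect: float
    ratio: float
    defined: bool

    def as_record(self) -> dict:
        return {"stream": self.stream, "campaign_effect": self.campaign_effect,
                "baseline_effect": self.baseline_effect,
                "ratio": self.ratio if self.defined else None,
                "defined": self.defined}


@dataclass(frozen=True)
class ExcessReport:
    stream: str
    event_kind: str
    per_event: dict[str, float]     # ISO date -> observed - counterfactual
    total: float
    units: str

    def as_record(self) -> dict:
        return {"stream": self.stream, "event_kind": self.event_kind,
                "per_event": self.per_event, "total": self.total,
                "units": self.units}


def relative_effect(campaign: EffectEstimate, baseline: EffectEstimate) -> RelativeEffect:
    """Ratio of campaign to baseline point effects for one stream.

    Undefined (flagged, not raised) when the baseline effect is not positive.
    """
    if campaign.stream != baseline.stream:
        raise ValueError(f"stream mismatch: {campaign.stream!r} vs {baseline.stream!r}")
    if campaign.scope != baseline.scope:
        raise ValueError(f"scope mismatch: {campaign.scope!r} vs {baseline.scope!r}")
    defined = baseline.effect > 0
    ratio = campaign.effect / baseline.effect if defined else float("nan")
    return RelativeEffect(stream=campaign.stream, campaign_effect=campaign.effect,
                          baseline_effect=baseline.effect, ratio=ratio,
                          defined=defined)


def absolute_excess(series: DailySeries, fit: FittedEventModel,
                    event_days) -> ExcessReport:
    """Observed minus counterfactual on each event day, in native units."""
    per_event: dict[str, float] = {}
    total = 0.0
    for day in _as_day_list(event_days):
        ts = pd.Timestamp(day)
        excess = series.value_on(ts) - counterfactual_day(fit, ts)
        per_event[ts.date().isoformat()] = float(excess)
        total += excess
    return ExcessReport(stream=series.label, event_kind=fit.event_kind or "event",
                        per_event=per_event, total=float(total),
                        units=_UNIT_LABELS[series.kind])
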