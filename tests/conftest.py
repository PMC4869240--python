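import datetime as dt

import numpy as np
import pandas as pd
import pytest

from awarelift import (DailySeries, EventCalendar, campaign_date,
                       fit_event_model, ArimaOrder)
from awarelift.event_effect import _single_event_indicator


@pytest.fixture
def single_campaign_calendar():
    return EventCalendar.from_years([2014], kinds=("campaign",))


def constant_event_series(level=100.0, lift=0.5, n=120, jitter=1e-6, seed=0,
                          year=2014):
    """Constant series with one lifted event day (+ tiny jitter for
    identifiability); the analytically known event effect is ``lift``."""
    day = pd.Timestamp(campaign_date(year))
    dates = pd.date_range(day - pd.Timedelta(days=n - 1), day, freq="D")
    rng = np.random.default_rng(seed)
    values = level + jitter * rng.standard_normal(n)
    values[-1] = level * (1 + lift)
    series = DailySeries(dates, values, "raw_count", "flat")
    indicator = _single_event_indicator(dates, day)
    return series, indicator, day


@pytest.fixture
def flat_event_fit():
    series, indicator, day = constant_event_series()
    fit = fit_event_model(series, indicator, ArimaOrder(0, 0, 0, K=0),
                          event_kind="campaign", link="identity")
    return series, fit, day
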