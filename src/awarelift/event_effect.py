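"""Single-day event effects from ARIMA counterfactuals.

The estimator is quasi-experimental: a regression with seasonal-ARIMA errors
is fit to a daily series with a coefficient for the event day(s), the
counterfactual value an event day would have taken without the event is
imputed from the fit with the event coefficient's contribution removed, and
the effect is the ratio

    effect = (observed - counterfactual) / counterfactual,

a multiplicative lift comparable across streams regardless of units.  The
model mean is

    y_t = trend + beta_event * 1[event day] + annual Fourier pair(s) + u_t,

with ``u_t`` following ARIMA(p,d,q)(P,D,Q)_7: the weekly (circaseptan) cycle
enters through the seasonal ARIMA terms, the annual cycle through K Fourier
harmonic pairs on day-of-year (a period-365 seasonal ARIMA would be
impractical), and trend through differencing or an explicit trend term.
Strictly positive series are fit on the log scale by default, where
multiplicative weekly/annual structure — and a multiplicative event lift —
are exactly additive; series containing zeros fall back to the raw
(identity) scale.

Orders are selected by a stepwise AIC search in the Hyndman–Khandakar style:
d and D are chosen by a variance-reduction rule, four starting models are
fit, and ±1 neighbour moves (singly, and jointly on the (p,q) and (P,Q)
pairs) are taken greedily until no move improves AIC.  Confidence
intervals come from a parametric bootstrap: coefficient vectors are drawn
from the multivariate normal sampling distribution centred at the MLE with
the estimated coefficient covariance, and the effect is recomputed under
each draw, with percentile bounds.  Under each draw both the treated value
and the counterfactual are model-derived (effect draw = beta_draw /
counterfactual_draw), so the interval carries the event coefficient's full
sampling uncertainty; the point estimate always uses the actually observed
value per the ratio formula above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calendar_events import EventCalendar, event_date
from .errors import EstimationError
from .streams_io import DailySeries

SEASONAL_PERIOD = 7
_MAX_P = _MAX_Q = 5
_MAX_SP = _MAX_SQ = 2
_MAX_D, _MAX_SD, _MAX_K = 2, 1, 3
_MIN_OBS = 60


@dataclass(frozen=True)
class ArimaOrder:
    """Non-seasonal (p,d,q), weekly-seasonal (P,D,Q, s=7) orders and the
    number K of annual Fourier harmonic pairs."""
    p: int
    d: int
    q: int
    P: int = 0
    D: int = 0
    Q: int = 0
    K: int = 1

    def __post_init__(self):
        bounds = {"p": _MAX_P, "q": _MAX_Q, "P": _MAX_SP, "Q": _MAX_SQ,
                  "d": _MAX_D, "D": _MAX_SD, "K": _MAX_K}
        for name, cap in bounds.items():
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0 or v > cap:
                raise ValueError(f"order {name}={v!r} outside [0, {cap}]")

    @property
    def order(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)

    @property
    def seasonal_order(self) -> tuple[int, int, int, int]:
        return (self.P, self.D, self.Q, SEASONAL_PERIOD)

    def as_dict(self) -> dict:
        return {"p": self.p, "d": self.d, "q": self.q, "P": self.P,
                "D": self.D, "Q": self.Q, "K": self.K, "s": SEASONAL_PERIOD}


@dataclass
class FittedEventModel:
    """A regression-with-ARIMA-errors fit with an event coefficient.

    ``link`` records the fitting scale.  Strictly positive streams are fit on
    the log scale by default, where multiplicative weekly/annual structure
    and a multiplicative event lift are exactly additive and the event
    coefficient is a log-lift; series containing zeros (or an explicit
    ``link="identity"``) are fit on a mean-scaled copy of the raw values for
    numerical robustness across stream magnitudes, with coefficients,
    covariance, log-likelihood and AIC mapped back to original units.
    ``scale`` is the back-transform factor (the geometric mean level for the
    log link, where the likelihood refers to the log-transformed data and
    coefficients are scale-free log quantities).
    """
    order: ArimaOrder
    param_names: list[str]
    params: np.ndarray
    cov_params: np.ndarray
    loglik: float
    aic: float
    n_params: int
    span: tuple[pd.Timestamp, pd.Timestamp]
    event_kind: Optional[str]
    n_events: int
    label: str
    scale: float
    link: str                           # "log" or "identity"
    event_index: Optional[int]          # index into params, None if no event column
    indicator: np.ndarray = field(repr=False)
    _results: object = field(repr=False, default=None)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.span[0], self.span[1], freq="D")

    @property
    def beta_event(self) -> float:
        if self.event_index is None:
            return 0.0
        return float(self.params[self.event_index])


@dataclass(frozen=True)
class EffectEstimate:
    """Ratio effect of an event with percentile confidence bounds."""
    effect: float
    ci_low: float
    ci_high: float
    observed: float
    counterfactual: float
    stream: str
    scope: str                  # "pooled" or a year, e.g. "2014"
    event_kind: str
    n_draws: int
    seed: Optional[int]
    order: ArimaOrder
    n_discarded: int = 0
    point_in_ci: bool = True

    def as_record(self) -> dict:
        return {
            "stream": self.stream, "scope": self.scope, "event_kind": self.event_kind,
            "effect": self.effect, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "observed": self.observed, "counterfactual": self.counterfactual,
            "n_draws": self.n_draws, "seed": self.seed, "order": self.order.as_dict(),
            "n_discarded": self.n_discarded, "point_in_ci": self.point_in_ci,
        }


# --- design matrices --------------------------------------------------------

def fourier_terms(dates: pd.DatetimeIndex, K: int) -> np.ndarray:
    """K annual Fourier harmonic pairs on day-of-year (period 365.25 days)."""
    doy = dates.dayofyear.to_numpy(dtype=float)
    cols = []
    for k in range(1, K + 1):
        arg = 2 * np.pi * k * doy / 365.25
        cols.append(np.sin(arg))
        cols.append(np.cos(arg))
    return np.column_stack(cols) if cols else np.empty((len(dates), 0))


def _design(dates: pd.DatetimeIndex, indicator: np.ndarray, K: int
            ) -> tuple[np.ndarray, bool]:
    """Exog matrix [event, fourier...]; the event column is dropped when the
    indicator is identically zero (returns has_event=False)."""
    indicator = np.asarray(indicator, dtype=float)
    if len(indicator) != len(dates):
        raise ValueError("indicator not aligned with series")
    has_event = bool(np.any(indicator != 0))
    four = fourier_terms(dates, K)
    if has_event:
        return np.column_stack([indicator, four]), True
    return four, False


# --- fitting ----------------------------------------------------------------

@dataclass(frozen=True)
class FitSettings:
    """Optimizer settings; fixed so that fits are deterministic.

    The coefficient covariance uses the numerically differentiated observed
    information ("approx"), not the outer product of gradients: an event
    coefficient identified by a handful of days has a degenerate OPG.
    """
    maxiter: int = 200
    factr: float = 1e7          # L-BFGS tolerance (tight)
    approx: bool = False        # conditional (simple-differencing) likelihood
    cov_type: str = "approx"


SEARCH_SETTINGS = FitSettings(maxiter=20, factr=1e10, approx=True, cov_type="none")
FINAL_SETTINGS = FitSettings()


def _trend_spec(order: ArimaOrder) -> str:
    # differencing absorbs trend; otherwise fit an intercept (mean) only
    return "c" if order.d + order.D == 0 else "n"


def _raw_fit(y: np.ndarray, exog: Optional[np.ndarray], order: ArimaOrder,
             settings: FitSettings, start_params=None):
    from statsmodels.tsa.statespace.sarimax import SARIMAX

    mod = SARIMAX(y, exog=exog if exog is not None and exog.shape[1] else None,
                  order=order.order, seasonal_order=order.seasonal_order,
                  trend=_trend_spec(order), concentrate_scale=True,
                  simple_differencing=settings.approx)
    kwargs = dict(disp=0, maxiter=settings.maxiter, method="lbfgs",
                  factr=settings.factr, cov_type=settings.cov_type)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if start_params is not None:
            try:
                return mod.fit(start_params=start_params, **kwargs)
            except Exception:
                pass
        return mod.fit(**kwargs)


def _warm_params(target_names: Sequence[str], source: dict[str, float]) -> np.ndarray:
    return np.array([source.get(name, 0.0) for name in target_names])


def resolve_link(series: DailySeries, link: str = "auto") -> str:
    """"auto" picks log for strictly positive series, identity otherwise."""
    if link == "auto":
        return "log" if len(series) and series.values.min() > 0 else "identity"
    if link not in ("log", "identity"):
        raise ValueError(f"unknown link {link!r}")
    if link == "log" and (len(series) == 0 or series.values.min() <= 0):
        raise ValueError(f"{series.label}: log link requires strictly positive values")
    return link


def fit_event_model(series: DailySeries, indicator: np.ndarray, order: ArimaOrder,
                    event_kind: Optional[str] = None,
                    settings: FitSettings = FINAL_SETTINGS,
                    start_params: Optional[dict] = None,
                    link: str = "auto") -> FittedEventModel:
    """Maximum-likelihood fit of the event-regression ARIMA model.

    ``start_params`` may carry named warm-start values (e.g. from the order
    search); fits remain deterministic because optimizer settings are fixed.
    """
    indicator = np.asarray(indicator, dtype=float)
    link = resolve_link(series, link)
    y = series.values
    if link == "log":
        # centre the log series: better conditioning, and rescaling the
        # series is absorbed exactly (scale is the back-transform multiplier)
        logmean = float(np.mean(np.log(y)))
        yfit, scale = np.log(y) - logmean, float(np.exp(logmean))
    else:
        scale = float(np.mean(y))
        if scale <= 0:
            raise EstimationError(f"{series.label}: cannot fit an all-zero series")
        yfit = y / scale
    exog, has_event = _design(series.dates, indicator, order.K)
    try:
        res = _raw_fit(yfit, exog, order, settings,
                       start_params=None if start_params is None else
                       _warm_params_for(yfit, exog, order, settings, start_params))
    except Exception as exc:
        raise EstimationError(
            f"{series.label}: fit failed for order {order.as_dict()}: {exc}") from exc
    if not np.all(np.isfinite(np.asarray(res.params))):
        raise EstimationError(
            f"{series.label}: non-finite estimates for order {order.as_dict()}")

    names = list(res.model.param_names)
    params = np.asarray(res.params, dtype=float)
    cov = np.asarray(res.cov_params(), dtype=float)
    if not np.all(np.isfinite(cov)):
        warnings.warn(f"{series.label}: singular coefficient covariance; "
                      "using pseudo-inverse for CI draws", stacklevel=2)
        cov = np.nan_to_num(cov, nan=0.0, posinf=0.0, neginf=0.0)
    cov = (cov + cov.T) / 2

    # back to original units: level-like params (trend, exog) scale linearly
    # on the identity link; log-link coefficients are already scale-free
    level_like = np.array([not (n.startswith("ar.") or n.startswith("ma."))
                           for n in names], dtype=float)
    n = len(yfit)
    if link == "log":
        J = np.ones(len(names))
        loglik, aic = float(res.llf), float(res.aic)
    else:
        J = np.where(level_like, scale, 1.0)
        loglik = float(res.llf) - n * np.log(scale)
        aic = float(res.aic) + 2 * n * np.log(scale)
    n_params = int(round((float(res.aic) + 2 * float(res.llf)) / 2))
    event_index = names.index("x1") if has_event else None

    return FittedEventModel(
        order=order, param_names=names, params=params * J,
        cov_params=cov * np.outer(J, J), loglik=loglik, aic=aic,
        n_params=n_params, span=(series.dates[0], series.dates[-1]),
        event_kind=event_kind, n_events=int(np.sum(indicator != 0)),
        label=series.label, scale=scale, link=link, event_index=event_index,
        indicator=indicator, _results=res)


def _warm_params_for(yfit, exog, order, settings, start_params: dict) -> np.ndarray:
    from statsmodels.tsa.statespace.sarimax import SARIMAX
    mod = SARIMAX(yfit, exog=exog if exog is not None and exog.shape[1] else None,
                  order=order.order, seasonal_order=order.seasonal_order,
                  trend=_trend_spec(order), concentrate_scale=True,
                  simple_differencing=settings.approx)
    return _warm_params(mod.param_names, start_params)


# --- order selection --------------------------------------------------------

def _choose_differencing(y: np.ndarray) -> tuple[int, int]:
    """Variance-reduction rule: D in {0,1} at lag 7 first, then d in {0,1,2}."""
    def var(a):
        return float(np.var(a)) if len(a) > 2 else np.inf
    D = 1 if var(y[SEASONAL_PERIOD:] - y[:-SEASONAL_PERIOD]) < var(y) else 0
    z = y[SEASONAL_PERIOD:] - y[:-SEASONAL_PERIOD] if D else y
    variances = [var(np.diff(z, n=k)) if k else var(z) for k in range(_MAX_D + 1)]
    return int(np.argmin(variances)), D


class _Search:
    """Stepwise AIC search with cached, warm-started candidate fits."""

    def __init__(self, series: DailySeries, indicator: np.ndarray, d: int, D: int,
                 K: int, link: str, settings: FitSettings = SEARCH_SETTINGS):
        self.series, self.indicator = series, indicator
        self.d, self.D, self.K = d, D, K
        self.link = link
        self.settings = settings
        self.cache: dict[tuple[int, int, int, int], tuple[float, object]] = {}
        self._best_aic: float = np.inf
        self._best_k: int = 0
        self._best_params: Optional[dict] = None

    def _fit(self, order: ArimaOrder, start_params):
        try:
            return fit_event_model(self.series, self.indicator, order,
                                   settings=self.settings, link=self.link,
                                   start_params=start_params)
        except EstimationError:
            return None

    def aic(self, p: int, q: int, P: int, Q: int) -> float:
        key = (p, q, P, Q)
        if key not in self.cache:
            order = ArimaOrder(p, self.d, q, P, self.D, Q, self.K)
            fit = self._fit(order, self._best_params)
            if fit is not None and self._best_params is not None:
                # a fit warm-started from the incumbent starts at the
                # incumbent's likelihood, so its AIC can exceed the
                # incumbent's by at most 2 per extra parameter; a larger gap
                # means the optimizer stalled — retry from default starts
                slack = 2 * max(0, fit.n_params - self._best_k) + 0.5
                if fit.aic > self._best_aic + slack:
                    cold = self._fit(order, None)
                    if cold is not None and cold.aic < fit.aic:
                        fit = cold
            elif fit is None:
                fit = self._fit(order, None)
            if fit is None:
                self.cache[key] = (np.inf, None)
            else:
                self.cache[key] = (fit.aic, fit)
                if fit.aic < self._best_aic:
                    # warm-start later candidates from the best fit so far
                    self._best_aic = fit.aic
                    self._best_k = fit.n_params
                    self._best_params = dict(zip(fit.param_names,
                                                 np.asarray(fit._results.params)))
        return self.cache[key][0]

    def run(self, max_p: int, max_q: int, max_P: int, max_Q: int
            ) -> tuple[int, int, int, int]:
        def clip(k):
            return (min(k[0], max_p), min(k[1], max_q),
                    min(k[2], max_P), min(k[3], max_Q))

        # cheap models first, so expensive starts inherit warm starts
        starts = [clip(k) for k in [(0, 0, 0, 0), (1, 0, 1, 0),
                                    (0, 1, 0, 1), (2, 2, 1, 1)]]
        seen = []
        for s in starts:
            if s not in seen:
                seen.append(s)
        best = min(seen, key=lambda k: (self.aic(*k), sum(k), k))
        if not np.isfinite(self.aic(*best)):
            raise EstimationError(f"{self.series.label}: no candidate model converged")
        moves = ((1, 0, 0, 0), (-1, 0, 0, 0), (0, 1, 0, 0), (0, -1, 0, 0),
                 (0, 0, 1, 0), (0, 0, -1, 0), (0, 0, 0, 1), (0, 0, 0, -1),
                 (1, 1, 0, 0), (-1, -1, 0, 0), (0, 0, 1, 1), (0, 0, -1, -1))
        improved = True
        while improved:
            improved = False
            p, q, P, Q = best
            for dp, dq, dP, dQ in moves:
                cand = (p + dp, q + dq, P + dP, Q + dQ)
                if not (0 <= cand[0] <= max_p and 0 <= cand[1] <= max_q
                        and 0 <= cand[2] <= max_P and 0 <= cand[3] <= max_Q):
                    continue
                # accept the first improving move and restart the sweep;
                # ties break toward the smaller total order
                if (self.aic(*cand), sum(cand), cand) < (self.aic(*best), sum(best), best):
                    best = cand
                    improved = True
                    break
        return best


def select_order(series: DailySeries, indicator: np.ndarray, *,
                 max_p: int = 3, max_q: int = 3, max_P: int = 1, max_Q: int = 1,
                 K: int = 1, link: str = "auto") -> ArimaOrder:
    """Stepwise Hyndman–Khandakar-style order selection (AIC minimized).

    The event regressor and the K annual Fourier pair(s) are always included
    during the search.  Candidate fits use a fast conditional-likelihood
    approximation; refit the selected order with :func:`fit_event_model` for
    final inference.
    """
    order, _ = _select_order_with_params(series, indicator, max_p=max_p,
                                         max_q=max_q, max_P=max_P, max_Q=max_Q,
                                         K=K, link=link)
    return order


def _select_order_with_params(series: DailySeries, indicator: np.ndarray, *,
                              max_p: int = 3, max_q: int = 3, max_P: int = 1,
                              max_Q: int = 1, K: int = 1, link: str = "auto"
                              ) -> tuple[ArimaOrder, Optional[dict]]:
    if len(series) < _MIN_OBS:
        raise ValueError(f"series too short for order selection "
                         f"({len(series)} < {_MIN_OBS})")
    if not (max_p <= _MAX_P and max_q <= _MAX_Q and max_P <= _MAX_SP
            and max_Q <= _MAX_SQ):
        raise ValueError("search bounds exceed hard order caps")
    link = resolve_link(series, link)
    yfit = (np.log(series.values) if link == "log"
            else series.values / np.mean(series.values))
    d, D = _choose_differencing(yfit)
    search = _Search(series, indicator, d, D, K, link)
    p, q, P, Q = search.run(max_p, max_q, max_P, max_Q)
    order = ArimaOrder(p, d, q, P, D, Q, K)
    best_fit = search.cache[(p, q, P, Q)][1]
    warm = None
    if best_fit is not None:
        warm = dict(zip(best_fit.param_names, np.asarray(best_fit._results.params)))
    return order, warm


# --- counterfactual and effects ---------------------------------------------

def _as_day_list(days) -> list:
    if isinstance(days, (str, bytes)) or np.ndim(days) == 0:
        return [days]
    return list(days)


def _event_locs(fit: FittedEventModel, days) -> list[int]:
    dates = fit.dates
    locs = []
    for day in _as_day_list(days):
        ts = pd.Timestamp(day)
        loc = dates.get_indexer([ts])[0]
        if loc < 0:
            raise ValueError(f"{ts.date()} outside fitted span "
                             f"{dates[0].date()}..{dates[-1].date()}")
        locs.append(int(loc))
    return locs


def _scaled_forecasts(res) -> np.ndarray:
    """One-step-ahead predicted means (scaled units) from a results object."""
    return np.asarray(res.get_prediction().predicted_mean)


def counterfactual_day(fit: FittedEventModel, day) -> float:
    """Model-implied value for ``day`` with the event contribution removed.

    The one-step conditional mean (on the fitting scale) given the observed
    history, with the event coefficient's contribution (beta * indicator)
    subtracted, mapped back to native units; with the event coefficient
    constrained to zero it equals the model's conditional value exactly.
    """
    loc = _event_locs(fit, day)[0]
    pred = _scaled_forecasts(fit._results)[loc]
    beta = (np.asarray(fit._results.params)[fit.event_index]
            if fit.event_index is not None else 0.0)
    base = pred - beta * fit.indicator[loc]
    if fit.link == "log":
        return float(np.exp(base) * fit.scale)
    return float(base * fit.scale)


def _forecast_fast(mod, params: np.ndarray) -> np.ndarray:
    """One-step forecasts under ``params`` via the low-level Kalman filter."""
    mod.update(params, transformed=True)
    try:
        kf = mod.ssm._filter()
        return np.asarray(kf.forecast)[0]
    except (AttributeError, TypeError):
        return mod.ssm.filter().forecasts[0]


def _psd_root(cov: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh((cov + cov.T) / 2)
    return V * np.sqrt(np.clip(w, 0.0, None))


def effect_with_ci(fit: FittedEventModel, series: DailySeries, days, *,
                   n_draws: int = 10_000, alpha: float = 0.05,
                   seed: Optional[int] = None, scope: str = "pooled") -> EffectEstimate:
    """Point ratio effect with a parametric-bootstrap percentile CI.

    The point effect is (observed − counterfactual)/counterfactual at the
    average level across the event day(s).  For the interval, ``n_draws``
    coefficient vectors are sampled from MVN(MLE, covariance); under each
    draw both the treated value and the counterfactual are model-derived and
    the effect is their ratio minus one.  On the log link this reduces to
    exp(beta_draw) − 1 in closed form; on the identity link the
    counterfactual is recomputed by re-filtering under each draw, and draws
    with a non-positive counterfactual or invalid dynamics are discarded and
    counted.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    if fit.event_index is None:
        raise ValueError("model was fit without an event regressor")
    locs = _event_locs(fit, days)
    res = fit._results
    ev = fit.event_index

    observed = float(np.mean([series.value_on(pd.Timestamp(d))
                              for d in _as_day_list(days)]))
    fc = _scaled_forecasts(res)
    params0 = np.asarray(res.params, dtype=float)
    base_each = fc[locs] - params0[ev] * fit.indicator[locs]
    if fit.link == "log":
        counterfactual = float(np.mean(np.exp(base_each)) * fit.scale)
    else:
        counterfactual = float(np.mean(base_each) * fit.scale)
    if counterfactual <= 0:
        raise EstimationError(f"{fit.label}: non-positive counterfactual")
    effect = (observed - counterfactual) / counterfactual

    cov = np.asarray(res.cov_params(), dtype=float)
    cov = np.nan_to_num((cov + cov.T) / 2, nan=0.0, posinf=0.0, neginf=0.0)
    rng = np.random.default_rng(seed)
    draws = params0[None, :] + rng.standard_normal((n_draws, len(params0))) @ _psd_root(cov).T

    effect_draws = np.full(n_draws, np.nan)
    if fit.link == "log":
        # treated/counterfactual = exp(beta) on every event day: closed form
        effect_draws = np.exp(draws[:, ev]) - 1.0
    else:
        mod = res.model
        for i in range(n_draws):
            dp = draws[i]
            try:
                fc_d = _forecast_fast(mod, dp)
            except Exception:
                continue
            cf_d = float(np.mean(fc_d[locs])) - dp[ev]
            if cf_d > 0 and np.isfinite(cf_d):
                effect_draws[i] = dp[ev] / cf_d
        # restore point estimates on the shared model object
        mod.update(params0, transformed=True)

    valid = np.isfinite(effect_draws)
    n_discarded = int(n_draws - valid.sum())
    if valid.sum() == 0:
        raise EstimationError(f"{fit.label}: all CI draws discarded")
    if n_discarded > 0.10 * n_draws:
        warnings.warn(f"{fit.label}: {n_discarded}/{n_draws} CI draws discarded",
                      stacklevel=2)
    lo, hi = np.percentile(effect_draws[valid], [100 * alpha / 2, 100 * (1 - alpha / 2)])
    point_in_ci = bool(lo <= effect <= hi)
    if not point_in_ci:
        warnings.warn(f"{fit.label}: point effect {effect:.3f} outside percentile "
                      f"CI ({lo:.3f}, {hi:.3f}); skewed draw distribution",
                      stacklevel=2)
    return EffectEstimate(effect=float(effect), ci_low=float(lo), ci_high=float(hi),
                          observed=observed, counterfactual=counterfactual,
                          stream=fit.label, scope=scope,
                          event_kind=fit.event_kind or "event",
                          n_draws=n_draws, seed=seed, order=fit.order,
                          n_discarded=n_discarded, point_in_ci=point_in_ci)


# --- per-year and pooled entry points ---------------------------------------

#: Days in the per-year estimation window: 365 days of history + the event day.
PER_YEAR_WINDOW = 366


def _single_event_indicator(dates: pd.DatetimeIndex, day: pd.Timestamp) -> np.ndarray:
    ind = np.zeros(len(dates))
    ind[dates.get_indexer([day])[0]] = 1.0
    return ind


def estimate_per_year(series: DailySeries, calendar: EventCalendar, year: int,
                      kind: str, *, n_draws: int = 10_000, alpha: float = 0.05,
                      seed: Optional[int] = None, link: str = "auto",
                      select_kwargs: Optional[dict] = None) -> EffectEstimate:
    """Event effect for one year, fit to the year preceding the event.

    The model is fit to the 366-day window ending on (and including) the
    event day, with a single-day indicator.
    """
    day = pd.Timestamp(event_date(year, kind))
    start = day - pd.Timedelta(days=PER_YEAR_WINDOW - 1)
    if series.dates[0] > start or series.dates[-1] < day:
        raise ValueError(f"{series.label}: insufficient history for {kind} {year} "
                         f"(need {start.date()}..{day.date()})")
    locs = series.dates.get_indexer([start, day])
    window = DailySeries(series.dates[locs[0]:locs[1] + 1],
                         series.values[locs[0]:locs[1] + 1], series.kind, series.label)
    ind = _single_event_indicator(window.dates, day)
    order, warm = _select_order_with_params(window, ind, link=link,
                                            **(select_kwargs or {}))
    fit = fit_event_model(window, ind, order, event_kind=kind,
                          start_params=warm, link=link)
    return effect_with_ci(fit, window, day, n_draws=n_draws, alpha=alpha,
                          seed=seed, scope=str(year))


def estimate_pooled(series: DailySeries, calendar: EventCalendar, kind: str, *,
                    n_draws: int = 10_000, alpha: float = 0.05,
                    seed: Optional[int] = None, link: str = "auto",
                    select_kwargs: Optional[dict] = None) -> EffectEstimate:
    """Pooled effect: one fit over the full series with a shared event
    coefficient on all event days of the requested kind; the effect and CI
    are computed at the average counterfactual level across event days."""
    from .calendar_events import build_event_indicator

    days = [d for d in calendar.dates(kind)
            if series.dates[0] <= pd.Timestamp(d) <= series.dates[-1]]
    if len(days) < 2:
        raise ValueError(f"{series.label}: pooled estimate needs >= 2 {kind} events "
                         f"in span, found {len(days)}")
    sub_cal = EventCalendar(tuple((d, kind) for d in days),
                            span=(series.dates[0].date(), series.dates[-1].date()))
    ind = build_event_indicator(series.dates, sub_cal, kind)
    order, warm = _select_order_with_params(series, ind, link=link,
                                            **(select_kwargs or {}))
    fit = fit_event_model(series, ind, order, event_kind=kind,
                          start_params=warm, link=link)
    return effect_with_ci(fit, series, days, n_draws=n_draws, alpha=alpha,
                          seed=seed, scope="pooled")
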