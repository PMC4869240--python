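import numpy as np
import pandas as pd
import pytest

from awarelift import (ArimaOrder, DailySeries, EventCalendar, campaign_date,
                       counterfactual_day, effect_with_ci, estimate_per_year,
                       fit_event_model, select_order)
from awarelift.event_effect import (_choose_differencing, _design,
                                    _single_event_indicator, fourier_terms)
from awarelift.synthetic_data import recovery_stream_config
from awarelift import generate_panel
from tests.conftest import constant_event_series


class TestOrderBookkeeping:
    def test_order_caps_enforced(self):
        with pytest.raises(ValueError):
            ArimaOrder(6, 0, 0)
        with pytest.raises(ValueError):
            ArimaOrder(1, 0, 1, P=3)
        with pytest.raises(ValueError):
            ArimaOrder(1, 3, 0)

    def test_differencing_rule(self):
        rng = np.random.default_rng(0)
        n = 400
        white = rng.normal(0, 1, n) + 10
        assert _choose_differencing(white) == (0, 0)
        weekly = 10 * (1 + 0.5 * np.cos(2 * np.pi * np.arange(n) / 7))
        assert _choose_differencing(weekly + rng.normal(0, 0.1, n))[1] == 1
        walk = np.cumsum(rng.normal(0, 1, n))
        assert _choose_differencing(walk)[0] >= 1

    def test_fourier_design_shapes(self):
        dates = pd.date_range("2014-01-01", periods=30, freq="D")
        assert fourier_terms(dates, 2).shape == (30, 4)
        ind = np.zeros(30)
        X, has_event = _design(dates, ind, 1)
        assert X.shape == (30, 2) and not has_event
        ind[3] = 1
        X, has_event = _design(dates, ind, 1)
        assert X.shape == (30, 3) and has_event


class TestFitAndCounterfactual:
    def test_flat_series_recovers_event_coefficient(self, flat_event_fit):
        series, fit, day = flat_event_fit
        assert fit.beta_event == pytest.approx(50.0, abs=1e-3)
        cf = counterfactual_day(fit, day)
        assert cf == pytest.approx(100.0, abs=1e-3)
        est = effect_with_ci(fit, series, day, n_draws=500, seed=0, scope="2014")
        assert est.effect == pytest.approx(0.5, abs=1e-4)
        # near-zero noise: the parametric-bootstrap interval collapses
        assert est.ci_high - est.ci_low < 1e-3

    def test_no_event_indicator_gives_identity_counterfactual(self):
        series, _, day = constant_event_series(lift=0.0)
        fit = fit_event_model(series, np.zeros(len(series)), ArimaOrder(0, 0, 0, K=0),
                              link="identity")
        assert fit.event_index is None and fit.beta_event == 0.0
        pred = fit._results.get_prediction().predicted_mean * fit.scale
        for i in (5, 50, len(series) - 1):
            assert counterfactual_day(fit, series.dates[i]) == pytest.approx(
                float(pred[i]), abs=0, rel=0)

    def test_counterfactual_outside_span_rejected(self, flat_event_fit):
        _, fit, _ = flat_event_fit
        with pytest.raises(ValueError, match="outside fitted span"):
            counterfactual_day(fit, "1999-01-01")

    def test_aic_identity(self, flat_event_fit):
        _, fit, _ = flat_event_fit
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik, rel=1e-10)

    def test_refit_is_a_fixed_point(self):
        series, indicator, _ = constant_event_series(jitter=0.5, seed=8)
        fit = fit_event_model(series, indicator, ArimaOrder(1, 0, 0, K=0))
        warm = dict(zip(fit.param_names, np.asarray(fit._results.params)))
        again = fit_event_model(series, indicator, fit.order, start_params=warm,
                                link=fit.link)
        assert again.loglik == pytest.approx(fit.loglik, abs=1e-6)

    def test_covariance_symmetric_psd(self):
        series, indicator, _ = constant_event_series(jitter=0.5, seed=8)
        fit = fit_event_model(series, indicator, ArimaOrder(1, 0, 0, K=0))
        cov = fit.cov_params
        assert np.allclose(cov, cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(cov).min() > -1e-8 * max(1, abs(cov).max())

    @pytest.mark.parametrize("link,tol", [("identity", 1e-8), ("log", 1e-8)])
    def test_scale_equivariance_of_ratio_effect(self, link, tol):
        series, indicator, day = constant_event_series(seed=3, jitter=5.0)
        scaled = DailySeries(series.dates, series.values * 1000.0,
                             "raw_count", "scaled")
        order = ArimaOrder(1, 0, 0, K=0)
        e1 = effect_with_ci(fit_event_model(series, indicator, order, link=link),
                            series, day, n_draws=500, seed=1, scope="x")
        e2 = effect_with_ci(fit_event_model(scaled, indicator, order, link=link),
                            scaled, day, n_draws=500, seed=1, scope="x")
        assert e1.effect == pytest.approx(e2.effect, abs=tol)


class TestEffectArithmetic:
    def test_observed_equal_counterfactual_gives_zero(self):
        series, indicator, day = constant_event_series(lift=0.0, seed=5,
                                                       jitter=1.0)
        fit = fit_event_model(series, indicator, ArimaOrder(0, 0, 0, K=0))
        est = effect_with_ci(fit, series, day, n_draws=500, seed=2, scope="x")
        assert est.effect == pytest.approx(0.0, abs=1e-2)
        assert est.ci_low <= 0 <= est.ci_high


class TestSelectOrder:
    def test_white_noise_selects_empty_order(self):
        rng = np.random.default_rng(0)
        n = 300
        dates = pd.date_range("2012-01-01", periods=n, freq="D")
        series = DailySeries(dates, 50 + rng.normal(0, 1, n), "raw_count", "wn")
        ind = np.zeros(n)
        ind[-1] = 1
        order = select_order(series, ind)
        assert (order.p, order.q, order.P, order.Q) == (0, 0, 0, 0)
        assert (order.d, order.D) == (0, 0)

    def test_ar1_selects_autoregression(self):
        rng = np.random.default_rng(7)
        n = 400
        e = np.zeros(n)
        for i in range(1, n):
            e[i] = 0.8 * e[i - 1] + rng.normal()
        dates = pd.date_range("2012-01-01", periods=n, freq="D")
        series = DailySeries(dates, 50 + e - e.min(), "raw_count", "ar1")
        ind = np.zeros(n)
        ind[-1] = 1
        order = select_order(series, ind)
        assert order.p + order.q >= 1

    def test_short_series_rejected(self):
        dates = pd.date_range("2014-01-01", periods=30, freq="D")
        series = DailySeries(dates, np.ones(30), "raw_count", "short")
        with pytest.raises(ValueError, match="too short"):
            select_order(series, np.zeros(30))


class TestEstimateEntryPoints:
    def test_per_year_requires_full_window(self):
        cal = EventCalendar.from_years([2014], kinds=("campaign",))
        dates = pd.date_range("2014-06-01", "2014-12-31", freq="D")
        series = DailySeries(dates, np.full(len(dates), 10.0), "raw_count", "x")
        with pytest.raises(ValueError, match="insufficient history"):
            estimate_per_year(series, cal, 2014, "campaign", n_draws=100)

    def test_per_year_deterministic_under_seed(self):
        cal = EventCalendar.from_years([2014], kinds=("campaign",))
        panel, _ = generate_panel(recovery_stream_config(21, 0.5))
        a = estimate_per_year(panel["news"], cal, 2014, "campaign",
                              n_draws=200, seed=9)
        b = estimate_per_year(panel["news"], cal, 2014, "campaign",
                              n_draws=200, seed=9)
        assert a == b

    def test_minimum_draws_enforced(self, flat_event_fit):
        series, fit, day = flat_event_fit
        with pytest.raises(ValueError, match="at least 100"):
            effect_with_ci(fit, series, day, n_draws=10)
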