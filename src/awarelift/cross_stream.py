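"""Year-by-year association between media effects and downstream effects.

Per-year percent increases in media coverage are the predictor and per-year
percent increases in an outcome stream (tweets, searches, page views, calls)
the response, related by ordinary least squares with an intercept.  The fit
answers questions of the form "what outcome increase does a 50% media
increase predict?"; confidence intervals use the same multivariate-normal
coefficient-draw convention as the event estimator, for internal consistency
even at very small n (typically 6 years).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import EstimationError


@dataclass(frozen=True)
class Prediction:
    media_increase: float
    predicted: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class CrossStreamFit:
    outcome: str
    slope: float                # outcome %-points per media %-point
    intercept: float
    cov: np.ndarray             # 2x2 over (intercept, slope)
    n_years: int
    prediction_at: Prediction

    def as_record(self) -> dict:
        p = self.prediction_at
        return {"outcome": self.outcome, "slope": self.slope,
                "intercept": self.intercept, "n_years": self.n_years,
                "prediction_at": {"media_increase": p.media_increase,
                                  "predicted": p.predicted,
                                  "ci_low": p.ci_low, "ci_high": p.ci_high}}


def _draw_predictions(intercept: float, slope: float, cov: np.ndarray,
                      media_increase: float, n_draws: int, alpha: float,
                      seed: Optional[int]) -> tuple[float, float]:
    w, V = np.linalg.eigh((cov + cov.T) / 2)
    root = V * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    coefs = np.array([intercept, slope]) + rng.standard_normal((n_draws, 2)) @ root.T
    preds = coefs[:, 0] + coefs[:, 1] * media_increase
    lo, hi = np.percentile(preds, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def fit_media_relation(media_effects: Sequence[float],
                       outcome_effects: Sequence[float], *,
                       outcome: str = "outcome", media_increase: float = 50.0,
                       n_draws: int = 10_000, alpha: float = 0.05,
                       seed: Optional[int] = None) -> CrossStreamFit:
    """OLS of per-year outcome increases on per-year media increases.

    Inputs are matched by year and expressed in percent points (61 for a 61%
    increase).  At least 3 years are required; a predictor with zero
    variance cannot identify a slope.
    """
    x = np.asarray(media_effects, dtype=float)
    y = np.asarray(outcome_effects, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("media and outcome effect lists must be matched 1-D")
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 matched years, got {n}")
    if np.ptp(x) == 0:
        raise EstimationError("zero variance in media effects: slope unidentified")

    X = np.column_stack([np.ones(n), x])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - 2
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)

    lo, hi = _draw_predictions(coef[0], coef[1], cov, media_increase,
                               n_draws, alpha, seed)
    pred = Prediction(media_increase=float(media_increase),
                      predicted=float(coef[0] + coef[1] * media_increase),
                      ci_low=lo, ci_high=hi)
    return CrossStreamFit(outcome=outcome, slope=float(coef[1]),
                          intercept=float(coef[0]), cov=cov, n_years=n,
                          prediction_at=pred)


def predict_outcome_increase(fit: CrossStreamFit, media_increase: float = 50.0,
                             *, n_draws: int = 10_000, alpha: float = 0.05,
                             seed: Optional[int] = None) -> Prediction:
    """Predicted outcome increase (intercept + slope * media_increase) with a
    coefficient-draw percentile CI."""
    lo, hi = _draw_predictions(fit.intercept, fit.slope, fit.cov, media_increase,
                               n_draws, alpha, seed)
    return Prediction(media_increase=float(media_increase),
                      predicted=float(fit.intercept + fit.slope * media_increase),
                      ci_low=lo, ci_high=hi)
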