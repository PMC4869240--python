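# Methods

## The estimand

A single-day awareness campaign (the Great American Smokeout, held the third
Thursday of November) is expected to produce a one-day spike in each of five
daily infoveillance streams: cessation-related news coverage (as a
proportion of all news stories), tweet counts, Google relative search volume
(RSV), Wikipedia page views per million, and quitline call counts.  The
quantity of interest for stream *y* and event day *T* is the ratio effect

    delta = (y_T - c_T) / c_T,

where `c_T` is the counterfactual: the value the stream would have taken on
`T` had the day been ordinary.  Because the effect is a ratio it is
comparable across streams regardless of normalization or units.  New Year's
Day plays the role of a baseline event — the strongest recurring natural
spike in cessation activity — and campaign effects are also reported
relative to it (campaign effect divided by baseline effect).

## Counterfactual model

The counterfactual is imputed from a regression with seasonal-ARIMA errors
fit to the daily series with an indicator regressor for the event day(s):

    z_t = mu + beta * 1[event day] + sum_k (a_k sin + b_k cos)(2 pi k doy_t / 365.25) + u_t,
    u_t ~ ARIMA(p,d,q)(P,D,Q)_7

* **Weekly (circaseptan) cycle** enters through the seasonal ARIMA terms at
  period 7 (selected, not imposed).
* **Annual cycle** enters as K Fourier harmonic pairs on day-of-year
  (default K=1); a period-365 seasonal ARIMA is not practical at daily
  resolution.
* **Trend** is absorbed by differencing when the variance rule selects d or
  D > 0, otherwise an intercept is fit (differencing is how the model
  "corrects for trending" in streams like growing tweet volume).

`z_t` is the log of the series when all values are strictly positive (the
default), or the mean-scaled raw values otherwise.  The log link is the
default because the plausible data-generating process for these streams is
multiplicative: weekly and annual cycles scale the level, and a campaign
multiplies the level on one day.  On the raw scale an additive fit
misallocates the annual component on the event day — the event is always a
Thursday, whose weekly multiplier differs from 1, so the additive annual
term over- or under-shoots by (annual deviation) x (1 − weekly multiplier).
In simulation this produced a systematic counterfactual bias of about +1.7%
and confidence intervals that undercovered; on the log scale the structure
is exactly additive and both problems disappear.  The published intervals
this framework emulates are strongly right-skewed (e.g. +110% with CI 32 to
412), which is the signature of a log-scale sampling distribution.  Series
containing zeros fall back to the identity link, which retains the full
re-filtering bootstrap described below.

The counterfactual for an event day is the model's one-step-ahead
conditional value with the event coefficient's contribution removed,
back-transformed to native units:

    c_T = g(E[z_T | z_1..z_{T-1}] - beta),   g = exp or (x scale).

With beta constrained to zero this equals the model's conditional value
exactly (this identity is tested to machine precision).

## Order selection

d and D are chosen by a variance-reduction rule (D in {0,1} at lag 7 first,
then d in {0,1,2}, each minimizing the sample variance of the differenced
series).  Conditional on (d, D), a stepwise search minimizes AIC starting
from four models — (0,0)(0,0), (1,0)(1,0), (0,1)(0,1), (2,2)(1,1) — and
considering +-1 moves on p, q, P, Q (singly and jointly for the pairs),
replacing the current model as soon as an improving move is found, until no
move improves AIC.  Ties break toward the smaller total order, then
lexicographically.  Default search bounds are p,q <= 3 and P,Q <= 1 (hard
caps 5 and 2); the event indicator and the annual Fourier pair are always
present during the search.

Candidate fits during the search use a conditional-likelihood approximation
(simple differencing) with a loose optimizer tolerance and warm starts from
the incumbent best fit; because a warm-started nested fit begins at the
incumbent's likelihood, its AIC can legitimately exceed the incumbent's by
at most 2 per extra parameter — a larger gap flags a stalled optimizer and
triggers a cold retry.  The selected model is refit exactly (full
state-space likelihood, tight tolerance) before any inference.  In a 50-
series simulation against an exhaustive sweep of the bounded grid under the
same AIC evaluator, the stepwise search's AIC is within 2 of the exhaustive
minimum in 92% of series.

## Confidence intervals

Intervals are parametric-bootstrap percentile intervals: `n_draws`
(default 10,000) coefficient vectors are sampled from the multivariate
normal with mean at the maximum-likelihood estimates and covariance equal to
the estimated coefficient covariance, and the effect is recomputed under
each draw, with the interval taken from the empirical 2.5/97.5 percentiles.
Under a draw both the treated value and the counterfactual are model-derived,
so the draw effect is (treated − counterfactual)/counterfactual evaluated at
the drawn coefficients; on the log link this collapses to exp(beta_draw) − 1
in closed form, and on the identity link the counterfactual is recomputed by
re-filtering the data under each draw (draws with non-positive
counterfactuals or invalid dynamics are discarded and counted, with a
warning above 10%).  Holding the observed value fixed and perturbing only
the counterfactual would strip the event coefficient's sampling uncertainty
from the interval and shrink it several-fold below the effect's actual
sampling spread; it is not done here.  The point estimate always uses the
actually observed value: (observed − counterfactual)/counterfactual.

The coefficient covariance is the numerically differentiated observed
information ("approx" in statsmodels terms).  The outer-product-of-gradients
estimator is unusable here: a coefficient identified by one or a handful of
days has a near-degenerate OPG, which in simulation produced variances four
orders of magnitude too large.

Two practical notes: the percentile interval of a skewed draw distribution
can exclude the plug-in point estimate (this is flagged, not an error), and
with an exactly zero covariance the interval collapses to the model-implied
point effect.

## Per-year and pooled estimators

* **Per-year**: the model is fit to the 366-day window ending on (and
  including) the event day — one year of history plus the treated day — with
  a single-day indicator.
* **Pooled**: one fit over the full series with a shared event coefficient
  on all event days of a kind; the effect and interval are evaluated at the
  average counterfactual level across the event days.

## Cross-stream association and baseline comparison

Per-year media (news) percent increases predict per-year increases in each
other stream by ordinary least squares with an intercept; the reported
"outcome increase at a 50% media increase" is the fitted value
intercept + slope x 50 (the slope is reported alongside so the
through-the-origin reading can be recomputed).  Intervals use the same
MVN-coefficient-draw convention as the event estimator, for internal
consistency at n as small as 6 years.

The campaign-to-baseline ratio divides campaign by New Year's Day point
effects per stream and is flagged undefined when the baseline effect is not
positive.  Absolute excess activity is observed minus counterfactual summed
over event days, reported in native units: interpretable as items (calls,
tweets) only for raw-count streams; for RSV, proportion, or per-million
streams it stays in normalized units because converting, say, RSV points to
query counts requires an external calibration these sources do not provide.

## Synthetic data

The generator produces exactly the structures the model adjusts for.  The
expected value on day t is

    (baseline + trend*t) * weekly[dow(t)] * (1 + A cos(2 pi doy/365.25)) * (1 + delta on event days)

with noise either Poisson (count streams) or multiplicative Gaussian AR(1)
(value = mean x (1+e), e autocorrelated with stationary sd sigma).  Lifts
are multiplicative so that the generator's truth and the estimator's ratio
estimand are the same number.  The default five-stream panel loosely mimics
the real sources' magnitudes (news proportion ~1e-3, tweets ~300/day, search
as RSV, Wikipedia per-million ~1, quitline ~500 calls/day).

The recovery-study stream used throughout validation is news-like: 366 days
ending on the 2014 campaign day, weekly profile 1 + 0.2 cos(2 pi i/7),
annual amplitude 0.10, AR(1) noise with sigma = 5% of level and phi = 0.3
(phi is not dictated by the study design; 0.3 gives mild day-to-day
persistence typical of these streams), no trend.  What passing recovery
tests show is that the estimator inverts this generative family; they do not
show robustness to features real streams have and the generator does not:
media-driven multi-day decay after events, holiday anomalies other than the
modeled events, changing weekly profiles, or measurement artifacts such as
Google's integer rounding and sampling jitter (an integer-rounding dialect
is available for RSV but off by default).

The labeled short-text corpus is template-based: cessation sentences versus
keyword-matching but off-topic sentences (engines, grills, chimneys), with
optional symmetric label noise to emulate coder error.  It validates the
filter/classifier machinery, not natural-language generalization.

## Study sizes and tolerances

Simulation studies in the test suite use 200 replicates per arm (recovery
arms at lifts 0.25/0.5/1.0, a null arm, and coverage at 0.5), n_draws=1000
where intervals are assessed and 100 where only the mean estimate is used;
the order-search oracle uses 50 series of length 180.  The standalone
acceptance script runs the same studies at 60 replicates and 20 series per
arm for a quick single pass.  Optimizer settings are fixed (L-BFGS,
tolerance 1e7 x machine epsilon on the final fit) so that estimates are
deterministic given data and seed; all Monte-Carlo randomness flows from a
single user seed.

## Known limitations

* Single-day events only: no pulse-decay or multi-day intervention shapes;
  a campaign that diffuses over several days will be underestimated.
* The per-year estimator conditions on one year of history; effects in the
  first year of a panel are not estimable.
* The log-link draw interval ignores parameter uncertainty in the
  counterfactual level (it cancels only in the ratio's numerator/denominator
  pair); this is second-order relative to the event coefficient's
  uncertainty.
* The identity-link bootstrap re-filters per draw and is ~1000x slower than
  the log-link closed form; it is the fallback, not the default.
* AIC-based selection on 366-day windows occasionally includes a spurious
  ARMA term; the event coefficient is insensitive to this in simulation.
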