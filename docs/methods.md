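# Methods

## Problem and model

The package forecasts end-of-season county maize yield from in-season
daily inputs. A sample is one county-year: a 10 × 214 matrix (channels ×
days, April 1 – October 31) paired with one scalar target, the county
yield de-trended to a 2013 base. The regressor is a many-to-one stacked
LSTM: each layer applies the standard gate equations

    i_t = σ(W_i h_{t−1} + U_i x_t + b_i)
    f_t = σ(W_f h_{t−1} + U_f x_t + b_f)
    o_t = σ(W_o h_{t−1} + U_o x_t + b_o)
    c̃_t = tanh(W_c h_{t−1} + U_c x_t + b_c)
    c_t = f_t ⊙ c_{t−1} + i_t ⊙ c̃_t
    h_t = o_t ⊙ tanh(c_t)

from zero initial states; a linear map on the top layer's final hidden
state yields the prediction. Training minimizes mean squared error by
mini-batch gradient descent with exact backpropagation-through-time
gradients written out by hand in NumPy; the test suite validates them
against central finite differences at 1e−4 relative error, and the forward
pass against an independent scalar unrolling of the six equations at
1e−10. One model is trained per state, and one per truncation length for
early prediction — partial-season forecasting retrains on truncated
sequences rather than padding.

## Calendar

The growing-season window is April 1 – October 31 inclusive: 214 days in
every year (leap days never intersect it), day index 0 = April 1. Month
boundaries fall at day indices 29/60/90/121/152/182/213. Monthly forecast
cutoffs keep the days observed before the issue month: August → 122 days,
September → 153, October → 183, November → the full 214. Hourly data,
where simulated, is 24 steps/day (5,136 per season).

## Feature channels

The candidate set has 28 channels per sample, each broadcast to length
214: 14 time-constant soil attributes, the monthly drought index (PDSI)
repeated over each month's days, six daily weather channels, cumulative
rainfall and cumulative growing degree days (prefix sums of the dailies),
July rainfall and July maximum temperature as constants, the corn-acres
ratio, and two interactions (Tmax × droughty, Tmax × PDSI). GDD uses base
50 °F and cap 86 °F; the printed formula can go negative on cold days
(e.g. Tmax < 50 °F), so the daily value is clamped at zero per standard
agronomic practice. The cap applies to Tmax only; Tmin is floored at 50 °F
but not capped above.

The canonical model input is the ten-channel subset (Tmax, Tmin, Tmean,
rain, wind, rootznaws, droughty, PDSI, cum. rain, cum. GDD) in that fixed
order — the variable axis of the cube. MRMR ranking is a report, not an
auto-selector: the pipeline logs the ranking and trains on the canonical
set.

### MRMR details

Daily channels are summarized to one scalar per sample before mutual
information — the season mean by default (`sum` and `last` are options);
how to compare a 214-step series against a scalar target admits several
readings and this is the simplest. Variables are discretized into 10
quantile bins (a variable with ≤ bins distinct values keeps one code per
value). Selection is greedy: maximal relevance first, then relevance minus
mean redundancy with the selected set (MID; MIQ available). Ties break
lexicographically by channel name.

## De-trending

Genetic gain is removed before training and restored before scoring.
Percentage scheme: adjusted = yield × 1.015^(base − year). Absolute
scheme: +2.5 bu/ac per year-step ending in or before 2000 and +4.67
thereafter (the boundary step 1999→2000 takes the 2.5 increment; the
published description leaves the boundary step ambiguous). Base year 2013.
Both schemes invert exactly; predictions are re-trended to each sample's
year because only the nominal scale is comparable to observed yields.

## Augmentation and the cube

Training samples are augmented with the arithmetic mean (channels and
target) of every unordered within-CRD county pair, per training year only
— pairing is meaningful because the drought index is CRD-level and county
variables are already areal averages. Originals are retained; a CRD-year
with n counties contributes n + C(n,2) samples. Augmentation precedes
standardization and operates on de-trended targets. Samples stack into a
3-D cube (variables × time × samples); per-variable z-scoring statistics
are computed on training samples only and stored with the cube (recurrent
nets are scale-sensitive; the raw values are kept on disk so serialization
round-trips bit-exactly).

## Training and hyperparameter search

Targets are z-scored inside the trainer (statistics stored with the
parameters, inverted at prediction time): optimizer steps are of order the
learning rate, and an output bias would otherwise need ~1e5 updates to
reach the ~180 bu/ac scale of de-trended yields.

Weights initialize uniform ±1/√fan-in; the forget-gate bias starts at 1 so
early gradients flow. Optimizers: SGD with momentum and 1/(1 + decay·t)
learning-rate decay, or RMSprop (ρ = 0.9, ε = 1e−7) taking the learning
rate only. Random search samples uniformly from fixed choice sets —
hidden {8, 16, 32, 64, 128, 214}, batch {16, 64, 128, 512, 1024}, dropout
{0.0–0.7 by 0.1}, learning rate {1e−7…1e−3}, momentum and decay
{1e−4…0.1}, optimizer {sgd, rmsprop} — and ranks candidates by validation
MSE; a diverging candidate scores +∞ rather than aborting the search.
Dropout is inverted, applied to each layer's output during training only,
one mask per sample shared across time.

The validation split holds out the most recent 20 % of training years.
Epoch budgets are deliberately asymmetric: search candidates train briefly
(default 5 epochs, early-stopping patience 3) on the original samples
only, and the winning configuration is refit on the full augmented
training set with a longer budget (default 20 epochs, patience 4). The
short search budget identifies configurations that learn at all; the
augmented refit does the accurate fitting. Training is deterministic given
(config, seed, data); a non-finite loss raises with the offending
configuration.

## Evaluation

County predictions are re-trended, then scored: MAE (bu/ac), MAPE (%,
per-sample |error|/truth averaged; a zero true yield is an error), and the
share of absolute errors within ±20 and ±30 bu/ac. State and Corn-Belt
estimates are harvested-acre-weighted means of county predictions (an
unweighted mean is the logged fallback when acreage is absent — whether
the original aggregation was weighted is not stated, and weighting is the
production-consistent choice); their MAE/MAPE are computed on the yearly
aggregated series. October is exposed as the recommended "full-season"
cutoff: November models can absorb post-harvest noise because true harvest
dates are unknown.

Daily (as-of-day) forecasting keeps the observed prefix verbatim, fills
the remaining days from the per-county mean of the prior 10 seasons, and
recomputes cumulative channels over the stitched series.

## Synthetic data generator

The generator emulates the statistical structure the pipeline relies on,
not meteorology:

- **Geography**: a balanced state → CRD → county hierarchy; harvested
  acres (2e4–1.2e5) and corn-acres ratio (0.2–0.6) per county.
- **Weather**: Tmax follows a smooth seasonal curve peaking ~86 °F in
  mid-July plus a year-level shift (sd 1.5 °F), an AR(1) CRD-shared daily
  anomaly (sd 5 °F, φ 0.7 — this within-CRD correlation is what makes pair
  averaging meaningful), and county-day noise (sd 2 °F). Tmin sits ~20 °F
  below Tmax. Rain is intermittent (wet-day probability ~0.3, modulated by
  an AR(1) CRD moisture anomaly; exponential amounts, mean 0.32 in).
  Hourly mode lays a sinusoidal diurnal profile through (Tmin, Tmax), so
  daily max/min/mean re-derive exactly.
- **PDSI**: stationary AR(1) over the seven season months per CRD-year
  (marginal sd 2.5, φ 0.8), clipped to [−10, 10]; counties inherit their
  CRD's series exactly.
- **Soil**: one draw per county, constant forever; rootznaws 120–330 mm,
  droughty Bernoulli(0.3).
- **Yield**: detrended yield = 180 + 8·z(cumGDD) + 5·z(rain) − 1.5·z(rain)²
  − 6·droughty·heat/30 + 2.5·PDSI̅ + county effect (sd 5) + noise (sd 8)
  bu/ac, where z() standardizes season totals against fixed agronomic
  references (2,900 °F·day, 22 in) and heat is the season sum of
  Tmax − 90 °F exceedance. The genetic-gain trend multiplies the whole
  stationary response (percentage scheme) so percentage de-trending
  removes it exactly; yields are floored at 5 bu/ac to keep MAPE finite.

What the generator does **not** emulate: spatially smooth weather beyond
the CRD block structure, storm systems, planting-date or management
variation, irrigation, satellite-observable canopy state, and reporting
noise in official yield records. Passing tests therefore demonstrate that
the pipeline recovers the kinds of signal it assumes (thermal accumulation,
water supply, drought stress) at realistic noise levels — not that the
real-data accuracy figures are reproduced.

## Problem sizes and numerical choices

The shipped study scale is one state of 30 counties in 5 CRDs over 24
years (train 20, test 4): 600 original samples, 2,100 after augmentation,
and an 8-draw hyperparameter search — large enough for signal recovery,
small enough for a laptop CPU. Batched tensors use float32 during
training (float64 elsewhere); BPTT passes are chunked at 256 samples to
bound peak memory at the widest hidden size. Standardization guards
zero-variance channels (sd → 1). All randomness flows through explicitly
seeded generators; derived seeds stay below 2³¹.

## Known limitations

- The real panels (commercial weather, NASS yields, NOAA PDSI, SSURGO
  soil) are not ingested; adapters would need to map them onto the CSV
  panel schemas.
- MRMR on time series depends on the summary statistic; the season mean is
  one defensible choice among several, which is why it is configurable.
- Augmentation implements pairs only; triples are not supported.
- The 12 soil constants beyond rootznaws/droughty are plausible
  placeholders drawn from standard soil-survey attributes; any county
  constant slots into the same channel mechanism.
- No GPU path; the widest configurations (hidden 214, batch 1024) train
  slowly on one CPU and rely on early stopping.
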