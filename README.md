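# maizecast

County-scale maize (corn) yield forecasting for the US Corn Belt with a
many-to-one LSTM over daily in-season weather.

Survey-based public yield forecasts are state-level, monthly, and late;
private weather-driven forecasts are accurate but closed. `maizecast`
implements the data-driven alternative end to end: county yields are
modelled as `Y = f(X)`, where `X` is a multivariate daily time series over
the April 1 – October 31 growing season (214 days) and `f` is a stacked
two-layer LSTM whose final hidden state maps linearly to a single scalar —
the county's end-of-season yield in bu/ac. Because the daily county weather
panels that drive such models are commercial, the package ships a synthetic
panel generator with the same statistical structure, so every stage is
testable and reproducible offline.

## The pipeline

1. **Panels** — yearly county yields; daily county weather (Tmax/Tmin/Tmean
   °F, rainfall, max-hourly rainfall, wind); 14 per-county soil constants
   (led by `rootznaws`, root-zone available water storage, and `droughty`,
   drought vulnerability); monthly Palmer Drought Severity Index (PDSI,
   in [−10, 10]) per crop reporting district (CRD); per-county corn-acres
   ratio.
2. **Features** — growing degree days
   `GDD = (min(86, Tmax) + max(50, Tmin))/2 − 50` (floored at 0),
   cumulative GDD and rainfall, July aggregates, interaction channels;
   28 candidate channels in all.
3. **De-trending** — genetic gain is removed by projecting yields onto a
   2013 base: ×1.015 per year (percentage scheme) or +2.5 bu/ac/yr through
   2000 and +4.67 after (absolute scheme). Predictions are re-trended to
   the target year before scoring.
4. **Selection** — minimum-redundancy-maximum-relevance (MRMR) ranking on
   quantile-binned mutual information; the canonical model input is the
   ten-channel set (Tmax, Tmin, Tmean, rain, wind, rootznaws, droughty,
   PDSI, cumulative rain, cumulative GDD).
5. **Augmentation** — every within-CRD county pair in a training year is
   averaged (channels and target) into an extra sample: a CRD-year with n
   counties yields n + C(n,2) samples.
6. **Cube** — samples stack into a 3-D tensor (variables × time × samples),
   z-scored per variable on training samples only.
7. **Model** — a two-layer LSTM with the standard gate equations
   (`i, f, o = σ(W h + U x + b)`, `c̃ = tanh(·)`, `c_t = f⊙c_{t−1} + i⊙c̃`,
   `h_t = o⊙tanh(c_t)`), trained on MSE by exact backpropagation-through-
   time with SGD+momentum or RMSprop, hyperparameters drawn by random
   search from fixed choice sets (hidden ∈ {8,…,214}, batch ∈ {16,…,1024},
   dropout ∈ {0–0.7}, lr ∈ {1e−7…1e−3}, …).
8. **Early prediction** — forecasts issued in August/September/October use
   the first 122/153/183 days; daily forecasting keeps the observed prefix
   and fills the future from a 10-year climatology. County predictions
   aggregate to state and Corn-Belt level by harvested-acre weighting and
   are scored by MAE, MAPE and the share within ±20/±30 bu/ac.

## Worked example

```python
import numpy as np
from maizecast import (
    PipelineConfig, run_state_experiment,
)

cfg = PipelineConfig(
    n_states=1, crds_per_state=5, counties_per_crd=6,
    years=list(range(1993, 2017)),   # train 1993-2012, test 2013-2016
    budget=8, seed=1,
)
report, art = run_state_experiment(cfg, cutoff="nov", return_artifacts=True)
print(art["results"]["S01"].summary())   # one fitted model per state
print(report.metrics)
```

prints

```
Many-to-one LSTM yield model
==================================
layers:            2 x 32 hidden units
input channels:    10 (tmax_f, tmin_f, tmean_f, rain_in, wind_mph, rootznaws, droughty, pdsi, cum_rain_in, cum_gdd)
sequence length:   214 days
trainable params:  13857
optimizer:         rmsprop (lr=0.001)
dropout:           0.6
epochs run:        20
final train MSE:   89.258 (bu/ac)^2
best val MSE:      70.673 (bu/ac)^2
{'mae': 9.3193, 'mape': 4.627, 'n': 120, 'within_20': 0.9083, 'within_30': 0.9917}
```

`mae` is the mean absolute county error in bu/ac over the four test years;
`within_20`, the share of the 120 county-year predictions within ±20 bu/ac
of the true (synthetic) yield, is the pipeline's headline accuracy figure
(90.8 % here, against the ≥ 80 % the method is expected to deliver).

The same run is available from the shell:

```bash
maizecast run --config src/maizecast/configs/quickstart.yaml
```

which writes the five panels as CSV, the MRMR ranking, the trained model,
per-county predictions, an evaluation JSON and a manifest of content
hashes under `maizecast_run/`.

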