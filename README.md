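# goosurv

Post-release first-year survival analysis for GPS/GSM-tracked geese: from raw
hourly telemetry and daily station weather to behavioural covariates,
rule-based mortality determination, kernel home ranges, spatial structure,
and Kaplan–Meier / Cox proportional-hazards inference — together with a
synthetic telemetry generator that carries known ground truth for every stage.

## The scientific problem

Reintroduction and release programs for migratory waterbirds lose a large
fraction of birds in the first year, but *when*, *where* and *why* they die is
hard to establish from carcass recovery alone. Modern neck-collar and backpack
trackers report, every hour: position (with an accuracy class), speed,
heading, altitude, a movement count derived from on-board acceleration,
device temperature and battery voltage. From these streams one can

1. determine each bird's **fate** — confirmed death, abrupt loss (hunting or
   tag failure), or survival to the study horizon — and the **time of death**;
2. build per-individual **covariates**: average daily activity (ActAvg), stay
   duration before the first northward migration (StayDur), home-range size
   (95% kernel isopleth, KDE), release timing, body mass, and mean weather in
   the two weeks before departure (wind speed, visibility, temperature,
   precipitation);
3. ask which covariates predict first-year mortality.

### Mortality determination

A death is *biologically confirmed* only when three independent telemetry
signatures hold simultaneously, each over a sustained window:

* **thermal equilibration** — |device − ambient| ≤ 2 °C continuously ≥ 72 h
  (a live goose keeps the housing well above ambient);
* **behavioural quiescence** — < 10 movement counts per hour for ≥ 24 h;
* **spatial confinement** — every fix within 200 m of the window's medoid
  for ≥ 72 h.

The death time is the start of the earliest triple overlap. Streams that
terminate abruptly from a normal-activity state are treated as hunting/tag
loss and right-censored at the last fix; survivors are right-censored at
365 days.

### The survival model

With per-individual survival time `T`, event indicator `δ` and covariates
`X`, the package fits the Cox proportional-hazards model

```
h(t | X) = h0(t) · exp(β′X)
```

by Newton–Raphson on the **Efron partial likelihood** (ties handled
natively), reports hazard ratios `exp(β)` with 95% Wald intervals, Harrell's
concordance, and `AIC = −2 log PL + 2k`. Group survival is compared with
Kaplan–Meier curves `S(t) = Π (1 − d_i/n_i)` and the log-rank test.
Collinearity is screened with variance-inflation factors (drop while
VIF > 5), model selection enumerates **all covariate subsets**, keeps the
ΔAIC < 2 set and picks its most parsimonious member; proportional hazards is
checked by correlating scaled Schoenfeld residuals against Kaplan–Meier
transformed time. Spatial structure uses complete-linkage clustering on
great-circle distances and **Global Moran's I** (E[I] = −1/(n−1)) on survival
times with inverse-distance weights between 50%-kernel centroids.

The whole survival layer is implemented natively (no survival-analysis
dependency); `lifelines` is used **only** as an independent cross-check in
the test suite.

## Worked example

Simulate survival data from the generating hazard (hazard ratios 0.461 for
standardized activity and 2.311 for standardized pre-departure wind speed)
and recover the coefficients:

```python
import numpy as np
from goosurv import synthetic, survival

df = synthetic.simulate_survival_data(500, seed=42)
fit = survival.cox_fit(df, ["actavg_z", "wdsp_z"])
print(fit.summary().round(3))
#            coef     se     HR  HR 95% CI low  HR 95% CI high    p
# actavg_z -0.929  0.075  0.395          0.341           0.457  0.0
# wdsp_z    0.989  0.071  2.689          2.339           3.091  0.0
print(fit.aic, fit.concordance)   # 3022.8  0.775

km = survival.km_fit(df["survival_days"], df["event"])
print(km.survival_at(180), km.median)   # 0.604  290.8
```

Full telemetry round trip — generate a cohort with known fates, run the
pipeline, and score the classification against ground truth:

```python
from goosurv import pipeline, synthetic

res = pipeline.simulate_and_validate(synthetic.ScenarioConfig(n_individuals=12, seed=3))
# {'n': 12, 'fate_accuracy': 1.0,
#  'confusion': {'dead_confirmed': {'dead_confirmed': 4},
#                'hunting_or_loss': {'hunting_or_loss': 2},
#                'censored': {'censored': 6}},
#  'n_death_times_checked': 4, 'max_death_time_error_h': 1.0,
#  'departure_date_mae_d': 0.25, 'passed': True}
```

Or from the command line:

```bash
goosurv simulate --n 40 --seed 0 --out data/         # fixes.csv, weather.csv, meta.csv + truth
goosurv run --fixes data/fixes.csv --weather data/weather.csv \
            --meta data/meta.csv --out report/       # covariates, KM curves, Cox table, ...
goosurv validate --n 40 --seed 0                     # round-trip score vs ground truth
```

`goosurv run` writes `covariates.csv`, `fates.csv`, `km_curves.csv`,
`logrank_tests.csv`, `clusters.csv`, `model_table.csv`, `morans.json`,
`final_model.json`, `criteria_windows.json` and `run_config.yaml`
(configuration + hash for provenance).

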