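# Methods

This note records the modelling assumptions, parameter defaults and numerical
choices behind `goosurv`, in enough detail to audit any number the package
produces.

## 1. Data model

Three plain-CSV inputs:

* **fixes** — one row per hourly record: `individual_id, timestamp (ISO-8601
  UTC), longitude, latitude, speed, heading, altitude, exercise_volume,
  device_temp, voltage, accuracy`. `exercise_volume` is the tracker's hourly
  movement count; `accuracy` is a positioning class A–E (nominal error bounds
  5/10/20/100/2000 m) or `invalid` (no position).
* **weather** — one row per station-day in the GSOD dialect (`TEMP, DEWP,
  SLP, STP, VISIB, WDSP, MXSPD, MAX, MIN, PRCP`), sentinel codes (9999.9,
  999.9, 99.99) mapped to missing on read. Duplicate dates are a hard error;
  interior gap dates are reported, not filled.
* **meta** — one row per released individual: species, release site, source
  (wild-capture vs rescue), tracker attachment, release year, release
  timestamp, body mass (kg).

Analysis uses only accuracy classes **A–C** (≤ 20 m nominal error). Duplicate
(individual, timestamp) rows collapse to the best accuracy class, ties broken
by file order. The study region's civil day is **UTC+8**; all "dates"
(activity days, departure dates) are local civil dates.

## 2. Activity

The trackers compute overall dynamic body acceleration
ODBA = |ax| + |ay| + |az| over gravity-removed axes and increment the hourly
movement counter whenever ODBA **strictly exceeds 0.15 G**. `activity.odba`
and `count_movements` reproduce this for simulation/testing; the pipeline
trusts the shipped `exercise_volume`.

* *daily activity* = sum of hourly counts over a local civil day;
* **ActAvg** = mean of daily activity over the window from release to
  departure (or fate end), **excluding days with < 20 observed hours** to
  avoid downward bias from partial days. The window is inclusive of its start
  date, exclusive of its end date.

## 3. Migration

Departure is a rule this package defines: anchored on the wintering centroid
(mean position of the first 72 h), an individual departs at the first fix
with great-circle displacement ≥ 50 km **and** latitude above the centroid,
provided displacement stays ≥ 50 km for the following 48 h and the excursion
ends farther north than it began. **StayDur** is whole days from release to
that date; non-migrants get days to fate end and a flag. Pre-departure
weather covariates are per-variable means over the 14 days *preceding* the
departure date (half-open window, missing station days skipped per variable).

## 4. Mortality classification

Confirmed death requires the **simultaneous overlap** of three sustained
criteria; the death time is the earliest overlap start:

| criterion | rule | window |
|---|---|---|
| thermal equilibration | \|device − ambient\| ≤ 2 °C (inclusive) | ≥ 72 h |
| quiescence | hourly counts < 10 (strict) | ≥ 24 h |
| confinement | all fixes within 200 m of the window's medoid | ≥ 72 h |

Numerical choices, all deliberate:

* The thermal bound is **inclusive** (2.0 °C qualifies) and the quiescence
  bound **strict** (exactly 10 counts does not), matching the definitions of
  "within tolerance" and "fewer than".
* Ambient temperature is the station's daily TEMP linearly interpolated to
  hours, anchored at **local noon** (04:00 UTC).
* Predicate series are reindexed to hourly cadence and transmission gaps of
  ≤ `gap_fill_h = 6` hours flanked by qualifying hours are bridged; longer
  gaps break a run. Six hours tolerates realistic GSM outages and dropped
  accuracy classes while being far shorter than the shortest window (24 h).
* Confinement uses the **exact medoid** (the fix minimizing total distance to
  the window's other fixes), not a centroid, so one outlier cannot drag the
  center. Any qualifying window has consecutive steps ≤ 2 × radius, so the
  O(m³) exact scan only runs inside movement-pruned segments; the result is
  provably identical to the exhaustive all-pairs scan (verified against one
  in the tests).
* A stream that ends ≥ 72 h before the horizon **from a normal-activity
  state** — no robust decline and final-24 h mean counts at or above the
  quiescence threshold — is hunting/tag loss, right-censored at the last fix.
  "Robust decline" means the Theil–Sen slope's 95% band is entirely below
  zero for **all three** of counts, altitude and speed over the final 72 h;
  pure noise essentially never qualifies, a genuine pre-death decline does.
* Everything else is censored at min(tracked days, 365).

## 5. Space use and spatial statistics

Positions are projected to a local azimuthal-equidistant plane (hand-rolled;
exact for the ranges involved). The utilization distribution is a Gaussian
KDE evaluated by binning points on a metric grid and convolving with
`scipy.ndimage.gaussian_filter` (truncate = 6 bandwidths, so mass loss is
negligible). Bandwidth is Silverman's per-axis rule h = σ·n^(−1/6); the cell
size is a quarter of the smaller bandwidth; the grid extends 3 bandwidths
past the data. Home range = area of the smallest highest-density region
holding 95% of mass; core = 50%. On isotropic-Gaussian data these areas
agree with the closed form π·s²·χ²₂(p) to ≈ 1%.

Individuals are clustered by complete linkage on great-circle distances
between median locations, k chosen by silhouette over 2..min(8, n−1) unless
fixed. Global Moran's I on survival times uses row-standardized
inverse-great-circle-distance weights between 50%-kernel centroids, with the
Cliff–Ord randomization variance for a normal p and a ≥ 999-draw permutation
p (two-sided, (exceedances+1)/(draws+1)).

## 6. Survival inference (native implementation)

* **Kaplan–Meier**: product-limit over distinct event times; median = first
  time with S ≤ 0.5. Verified against exact rational arithmetic.
* **Log-rank**: multi-group observed−expected with the hypergeometric
  variance; χ² via the pseudo-inverse of the (G−1)-dimensional covariance.
  Verified against a hand computation and a label-permutation reference.
* **Cox PH**: Newton–Raphson with step-halving on the **Efron** partial
  likelihood, computed with suffix cumulative sums (risk sets) plus
  per-tie-group fractional corrections; the linear predictor is shifted by
  its maximum before exponentiation. Convergence at gradient norm < 1e-9.
  Covariates are z-scored internally (coefficients reported on both scales).
  Monotone likelihood is flagged (`possible_separation`) when |β| > 15 or
  SE > 100 on the standardized scale; flagged fits are excluded from model
  selection. Verified against `lifelines` to ≤ 1e-6.
* **Schoenfeld PH check**: scaled residuals β + m·(r·Σ̂) are Pearson-correlated
  with g(t) = 1 − S_KM(t); p from the t-test with m−2 df. Calibrated under
  proportional hazards and powerful against a reversing effect in the tests.
* **VIF screen**: VIF_j = 1/(1−R²_j) from the auxiliary regression of
  covariate j on the others; iteratively drop the largest while > 5, ties
  broken alphabetically for determinism.
* **Model selection**: all 2^k covariate subsets (k ≤ 15) ranked by
  AIC = −2 log PL + 2k; the ΔAIC < 2 set is retained and its most
  parsimonious member is the final model (ties by lower AIC). A forward
  stepwise path (likelihood-ratio entry at p < 0.05) is reported as a
  diagnostic only.

## 7. Synthetic cohort generator

The generator's defaults *are* the study conditions: 40 individuals released
at two lake reserves from 2023-12-10 over a 14-day stagger, tracked hourly to
a 365-day horizon, with GSOD-style station weather. Design attributes are
resampled from a 37-bird reference composition (20 Duchang / 17 Nanjishan,
30 capture / 7 rescue, 17 neck / 20 backpack, 25 *A. fabalis* /
12 *A. albifrons*, 25×2019 / 12×2022; devices 23–34 g on ≈ 3 kg birds, i.e.
≤ 1.13% of body mass, under the 3% telemetry-load rule of thumb).

Fates follow a default mix of 35% surviving migrants, 30% natural deaths,
15% hunting losses and 20% censored residents — chosen to exercise every
classifier branch with ≥ 2 individuals per class at n = 40 while keeping
events plentiful enough for the survival layer; it is a scenario parameter,
not an estimate. Natural-death times are drawn from an exponential hazard
with baseline 0.005/day and **generating log hazard ratios log 0.461 on
standardized true ActAvg and log 2.311 on the standardized 14-day
pre-departure wind mean**, truncated to the pre-departure window. Two
alternative modes exist:

* `hazard_driven_fates=True` replaces the fate quota with genuinely
  hazard-driven competing risks (exponential death vs hunting truncation vs
  horizon) — a coherent Cox data-generating process for coefficient-recovery
  checks on full cohorts;
* `simulate_survival_data` draws covariate-level survival data directly from
  the Cox model (baseline 0.0025/day), used for the CI-coverage study.

Signature design guarantees the classifier round trip *by construction, not
tuning*: post-death device temperature is ambient + clipped N(0, 0.5) noise
(±1.5 °C < the 2 °C tolerance), post-death counts are Poisson(0.3) (< 10),
the carcass is static while live positions carry 2.5 km scatter (≫ 2×200 m,
so a live bird never looks confined); the pre-death decline ramps activity
mean down to 11 counts/h (≥ the quiescence bound) so death, not decline, sets
the quiescence onset. Accuracy classes are drawn i.i.d. from a realistic
mixture (45/30/15/6/2/2% for A/B/C/D/E/invalid); the 10% drop rate makes a
> 6 h accuracy-induced gap (which would break a criterion run) essentially
impossible (p ≈ 1e-7 per hour). All randomness flows from one seed; equal
seeds give byte-identical outputs.

Known realism limits: weather is a smooth seasonal + synoptic model of one
station; migration is a straight northward drift; activity ignores
moult/breeding phenology; hunting is independent of covariates. In the quota
(default) mode, death *times* are hazard-weighted but death *counts* are
fixed, so full-cohort Cox fits are for pipeline plumbing, not unbiased
coefficient recovery — use the hazard-driven mode or the direct simulator for
that. Pipeline-recomputed covariates (ActAvg from noisy counts, WDSP from the
detected departure) attenuate coefficients slightly relative to the
generating truth; recovery checks therefore use the exported true covariates.

## 8. Scaled problem sizes

Tests and the acceptance script run cohorts of 8–120 individuals and
replicate counts of 40–100, chosen so the full suite completes in about a
minute on one CPU while every statistical claim retains power; these sizes
are the package's own choices, as are all thresholds above, and each is a
single parameter away from larger runs.
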