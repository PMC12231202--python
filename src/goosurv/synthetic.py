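"""Synthetic telemetry cohorts with exported ground truth.

The generator emulates the three pipeline inputs — hourly fix tables, daily
GSOD-style station weather, and release metadata — for a cohort of geese
wintering at a Poyang-like lake system, with known per-individual fates:

* ``natural_death`` — a 72 h linear-in-mean decline in activity, altitude and
  speed, followed by a post-death signature satisfying all three mortality
  criteria (device temperature tracking ambient within the tolerance,
  near-zero hourly counts, static position), then signal termination;
* ``hunting_loss`` — abrupt stream truncation from a normal-activity state;
* ``survivor_migrant`` — sustained northward displacement from the departure
  date, tracked to the study horizon;
* ``censored_resident`` — resident to the horizon.

Release-design attributes are drawn with the composition of the real study
cohort (:func:`reference_design`). Natural-death hazards carry log-hazard
coefficients on standardized activity and pre-departure wind-speed
covariates, so Cox fits on generated data can be checked against the
generating values. All randomness flows from one seed; the same seed gives
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import LOCAL_UTC_OFFSET_H, daily_activity
from .mortality import ambient_hourly
from .telemetry_io import (
    ACCURACY_BOUND_M,
    ACCURACY_LEVELS,
    FIX_COLUMNS,
    META_COLUMNS,
    WEATHER_VARS,
    write_fixes,
    write_meta,
    write_weather,
)

FATES = ("survivor_migrant", "natural_death", "hunting_loss", "censored_resident")

#: Release-site coordinates (lon, lat), northern and southern lake reserves.
SITE_COORDS = {"Duchang": (116.18, 29.30), "Nanjishan": (116.40, 28.88)}

#: Tracker models: attachment style and device mass (g).
DEVICE_MODELS = (
    {"model": "NG4625S", "tracker": "neck", "mass_g": 30.0},
    {"model": "NG4625P", "tracker": "neck", "mass_g": 34.0},
    {"model": "BG3621S", "tracker": "backpack", "mass_g": 23.0},
)

#: Mean body mass of the study species (kg).
MEAN_BODY_MASS_KG = 3.0


@dataclass
class HazardSpec:
    """Exponential baseline with log-hazard coefficients on standardized
    ActAvg and pre-departure wind speed (generating HRs 0.461 and 2.311)."""

    baseline_per_day: float = 0.005
    log_hr_actavg: float = float(np.log(0.461))
    log_hr_wdsp: float = float(np.log(2.311))


@dataclass
class ActivitySpec:
    day_mean: float = 60.0       # mean hourly movement counts in daylight
    between_sd: float = 15.0     # between-individual sd of the daytime level
    night_floor: float = 12.0    # minimum nocturnal hourly mean
    day_hours: tuple = (7, 18)   # local daylight hours, inclusive


@dataclass
class WeatherSpec:
    temp_mean: float = 17.0      # annual mean (degC)
    temp_amplitude: float = 12.0
    temp_sd: float = 2.0
    wdsp_mean: float = 3.5       # m/s
    wdsp_synoptic_amp: float = 1.5
    wdsp_period_d: float = 19.0
    wdsp_sd: float = 0.9
    visib_mean: float = 12.0     # km
    visib_sd: float = 4.0
    slp_mean: float = 1018.0     # hPa
    slp_sd: float = 3.0
    prcp_wet_prob: float = 0.35
    prcp_mean_mm: float = 8.0


@dataclass
class NoiseSpec:
    gps_jitter_by_class: dict = field(default_factory=lambda: dict(ACCURACY_BOUND_M))
    accuracy_mix: dict = field(
        default_factory=lambda: {"A": 0.45, "B": 0.30, "C": 0.15, "D": 0.06, "E": 0.02, "invalid": 0.02}
    )


@dataclass
class ScenarioConfig:
    n_individuals: int = 40
    start_date: str = "2023-12-10"
    horizon_days: int = 365
    fate_mix: dict = field(
        default_factory=lambda: {
            "survivor_migrant": 0.35,
            "natural_death": 0.30,
            "hunting_loss": 0.15,
            "censored_resident": 0.20,
        }
    )
    hazard_spec: HazardSpec = field(default_factory=HazardSpec)
    activity_spec: ActivitySpec = field(default_factory=ActivitySpec)
    weather_spec: WeatherSpec = field(default_factory=WeatherSpec)
    noise_spec: NoiseSpec = field(default_factory=NoiseSpec)
    # When True, deaths arise from the hazard itself (exponential death times
    # competing with administrative censoring) instead of the fixed fate_mix
    # quota for natural_death -- a coherent Cox data-generating process used
    # for coefficient-recovery checks.
    hazard_driven_fates: bool = False
    release_stagger_days: int = 14
    departure_offset_days: tuple = (70.0, 110.0)
    decline_hours: float = 72.0
    post_death_hours: float = 84.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be >= 0")
        if self.horizon_days < 1:
            raise ValueError("horizon_days must be >= 1")
        if set(self.fate_mix) - set(FATES):
            raise ValueError(f"unknown fate class in fate_mix: {set(self.fate_mix) - set(FATES)}")
        if abs(sum(self.fate_mix.values()) - 1.0) > 1e-9:
            raise ValueError("fate_mix must sum to 1")
        if any(v < 0 for v in self.fate_mix.values()):
            raise ValueError("fate_mix proportions must be >= 0")
        for sd in (self.activity_spec.between_sd, self.weather_spec.temp_sd,
                   self.weather_spec.wdsp_sd, self.weather_spec.visib_sd, self.weather_spec.slp_sd):
            if sd < 0:
                raise ValueError("spec standard deviations must be >= 0")
        if abs(sum(self.noise_spec.accuracy_mix.values()) - 1.0) > 1e-9:
            raise ValueError("accuracy mixture must sum to 1")


@dataclass
class GroundTruth:
    individuals: pd.DataFrame     # fate, death/departure times, true covariates
    daily_activity: pd.DataFrame  # pre-noise daily activity per individual
    hazard: dict                  # generating hazard coefficients


@dataclass
class SimulatedCohort:
    fixes: pd.DataFrame
    weather: pd.DataFrame
    meta: pd.DataFrame
    truth: GroundTruth
    config: ScenarioConfig


# ---------------------------------------------------------------------------
# study-design template
# ---------------------------------------------------------------------------

def reference_design() -> pd.DataFrame:
    """The released study cohort's design composition (N = 37): release site
    20 Duchang / 17 Nanjishan, source 30 capture / 7 rescue, tracker 17 neck /
    20 backpack, species 25 A. fabalis / 12 A. albifrons, release year
    25 x 2019 / 12 x 2022; devices of 23-34 g on ~3.0 kg birds.
    """
    n = 37
    rng = np.random.default_rng(20190322)
    cols = {
        "release_site": ["Duchang"] * 20 + ["Nanjishan"] * 17,
        "source": ["capture"] * 30 + ["rescue"] * 7,
        "tracker": ["neck"] * 17 + ["backpack"] * 20,
        "species": ["A. fabalis"] * 25 + ["A. albifrons"] * 12,
        "release_year": [2019] * 25 + [2022] * 12,
    }
    df = pd.DataFrame({k: rng.permutation(v) for k, v in cols.items()})
    df.insert(0, "individual_id", [f"ref{i:02d}" for i in range(1, n + 1)])
    neck_models = [m for m in DEVICE_MODELS if m["tracker"] == "neck"]
    masses, models = [], []
    neck_i = 0
    for trk in df["tracker"]:
        if trk == "neck":
            m = neck_models[neck_i % len(neck_models)]
            neck_i += 1
        else:
            m = DEVICE_MODELS[2]
        masses.append(m["mass_g"])
        models.append(m["model"])
    df["device_model"] = models
    df["device_mass_g"] = masses
    df["weight"] = np.round(rng.normal(MEAN_BODY_MASS_KG, 0.3, n).clip(2.1, 4.0), 3)
    return df


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

def _simulate_weather(cfg: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    ws = cfg.weather_spec
    start = pd.Timestamp(cfg.start_date) - pd.Timedelta(days=20)
    end = pd.Timestamp(cfg.start_date) + pd.Timedelta(days=cfg.horizon_days + 30)
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    t = np.arange(len(dates), dtype=float)
    temp = ws.temp_mean - ws.temp_amplitude * np.cos(2 * np.pi * (doy - 15) / 365.0)
    temp = temp + rng.normal(0, ws.temp_sd, len(dates))
    phase = rng.uniform(0, 2 * np.pi)
    wdsp = np.clip(
        ws.wdsp_mean
        + ws.wdsp_synoptic_amp * np.sin(2 * np.pi * t / ws.wdsp_period_d + phase)
        + rng.normal(0, ws.wdsp_sd, len(dates)),
        0.2,
        None,
    )
    wet = rng.random(len(dates)) < ws.prcp_wet_prob
    prcp = np.where(wet, rng.exponential(ws.prcp_mean_mm, len(dates)), 0.0)
    df = pd.DataFrame(
        {
            "date": dates,
            "TEMP": temp,
            "DEWP": temp - 3.0 + rng.normal(0, 1.5, len(dates)),
            "SLP": ws.slp_mean - 6.0 * np.sin(2 * np.pi * (doy - 60) / 365.0)
            + rng.normal(0, ws.slp_sd, len(dates)),
            "VISIB": np.clip(ws.visib_mean + rng.normal(0, ws.visib_sd, len(dates)), 0.5, 40.0),
            "WDSP": wdsp,
            "MXSPD": wdsp + 2.5 + np.abs(rng.normal(0, 1.0, len(dates))),
            "MAX": temp + 4.0 + np.abs(rng.normal(0, 1.0, len(dates))),
            "MIN": temp - 4.0 - np.abs(rng.normal(0, 1.0, len(dates))),
            "PRCP": prcp,
        }
    )
    df["STP"] = df["SLP"] - 5.0 + rng.normal(0, 0.5, len(dates))
    df = df.round(2)
    return df.loc[:, ["date", *WEATHER_VARS]]


# ---------------------------------------------------------------------------
# per-individual track
# ---------------------------------------------------------------------------

def _empty_fixes() -> pd.DataFrame:
    return pd.DataFrame(columns=list(FIX_COLUMNS))


def _build_track(
    rng: np.random.Generator,
    ind: str,
    cfg: ScenarioConfig,
    weather: pd.DataFrame,
    release_ts: pd.Timestamp,
    site_lonlat: tuple[float, float],
    a_day: float,
    fate: str,
    death_ts: pd.Timestamp | None,
    loss_ts: pd.Timestamp | None,
    departure_ts: pd.Timestamp | None,
) -> pd.DataFrame:
    aspec = cfg.activity_spec
    a_night = max(aspec.night_floor, a_day / 3.0)
    horizon_ts = release_ts + pd.Timedelta(days=cfg.horizon_days)
    if fate == "natural_death":
        end_ts = death_ts + pd.Timedelta(hours=cfg.post_death_hours)
    elif fate == "hunting_loss":
        end_ts = loss_ts
    else:
        end_ts = horizon_ts
    ts = pd.date_range(release_ts + pd.Timedelta(hours=1), end_ts, freq="h")
    n = len(ts)
    local_h = ((ts.hour + LOCAL_UTC_OFFSET_H) % 24).to_numpy()
    is_day = (local_h >= aspec.day_hours[0]) & (local_h <= aspec.day_hours[1])
    lam = np.where(is_day, a_day, a_night).astype(float)

    post = np.zeros(n, dtype=bool)
    decline = np.zeros(n, dtype=bool)
    progress = np.zeros(n)
    if death_ts is not None:
        hours_to_death = (death_ts - ts).total_seconds() / 3600.0
        decline = (hours_to_death >= 0) & (hours_to_death < cfg.decline_hours)
        post = hours_to_death < 0
        progress[decline] = 1.0 - hours_to_death[decline] / cfg.decline_hours
        lam[decline] = 11.0 + (lam[decline] - 11.0) * (1.0 - progress[decline])
        lam[post] = 0.3
    counts = rng.poisson(lam)

    altitude = 45.0 + rng.normal(0, 12.0, n)
    speed = rng.gamma(1.5, 0.8, n)
    if death_ts is not None:
        altitude[decline] = 45.0 - 40.0 * progress[decline] + rng.normal(0, 2.0, decline.sum())
        altitude[post] = 5.0 + rng.normal(0, 0.5, post.sum())
        speed[decline] = np.maximum(1.2 * (1 - progress[decline]) + rng.normal(0, 0.05, decline.sum()), 0.02)
        speed[post] = 0.0

    # positions: local jitter around a (possibly northward-moving) base point
    lon0, lat0 = site_lonlat
    base_lat = np.full(n, lat0)
    base_lon = np.full(n, lon0)
    if departure_ts is not None:
        days_out = np.maximum((ts - departure_ts).total_seconds().to_numpy() / 86400.0, 0.0)
        leg = np.minimum(days_out, 22.0)
        base_lat = base_lat + 1.1 * leg
        base_lon = base_lon + 0.15 * leg
    jit_m = 2500.0
    lat = base_lat + rng.normal(0, jit_m, n) / 111_320.0
    lon = base_lon + rng.normal(0, jit_m, n) / (111_320.0 * np.cos(np.radians(base_lat)))
    if death_ts is not None and (decline.any() or post.any()):
        k = int(np.argmax(decline | post))
        death_lat, death_lon = base_lat[k], base_lon[k]
        lat[decline] = death_lat + rng.normal(0, 800.0, decline.sum()) / 111_320.0
        lon[decline] = death_lon + rng.normal(0, 800.0, decline.sum()) / (
            111_320.0 * np.cos(np.radians(death_lat))
        )
        lat[post] = death_lat
        lon[post] = death_lon

    ambient = ambient_hourly(weather, ts).to_numpy()
    device_temp = ambient + 7.0 + rng.normal(0, 0.8, n)
    if death_ts is not None:
        device_temp[post] = ambient[post] + np.clip(rng.normal(0, 0.5, post.sum()), -1.5, 1.5)

    return pd.DataFrame(
        {
            "individual_id": ind,
            "timestamp": ts,
            "longitude": lon,
            "latitude": lat,
            "speed": speed,
            "heading": rng.uniform(0, 360, n),
            "altitude": altitude,
            "exercise_volume": counts.astype(np.int64),
            "device_temp": device_temp,
            "voltage": 4.1 + rng.normal(0, 0.03, n),
            "accuracy": "A",
        }
    )


# ---------------------------------------------------------------------------
# accuracy-class noise
# ---------------------------------------------------------------------------

def inject_accuracy_noise(fixes: pd.DataFrame, mixture: dict | None = None, rng=None) -> pd.DataFrame:
    """Assign accuracy classes from the mixture and jitter positions with the
    class's nominal error bound as per-axis sd; 'invalid' fixes lose their
    position. The input order is preserved; a fixed rng gives identical
    assignments on re-run.
    """
    mixture = mixture or NoiseSpec().accuracy_mix
    if set(mixture) - set(ACCURACY_LEVELS):
        raise ValueError("accuracy mixture has unknown class")
    if abs(sum(mixture.values()) - 1.0) > 1e-9:
        raise ValueError("accuracy mixture must sum to 1")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = fixes.copy()
    classes = list(mixture)
    probs = np.array([mixture[c] for c in classes], dtype=float)
    assigned = np.array(classes)[rng.choice(len(classes), size=len(out), p=probs)]
    out["accuracy"] = assigned
    sd = np.array([ACCURACY_BOUND_M.get(c, np.nan) for c in assigned])
    lat = out["latitude"].to_numpy(dtype=float)
    dlat = rng.normal(0, 1, len(out)) * sd / 111_320.0
    dlon = rng.normal(0, 1, len(out)) * sd / (111_320.0 * np.cos(np.radians(lat)))
    valid = assigned != "invalid"
    out.loc[valid, "latitude"] = lat[valid] + dlat[valid]
    out.loc[valid, "longitude"] = out.loc[valid, "longitude"].to_numpy() + dlon[valid]
    out.loc[~valid, ["latitude", "longitude"]] = np.nan
    return out


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _fate_counts(mix: dict, n: int) -> dict:
    """Largest-remainder apportionment of n individuals over fate classes."""
    raw = {f: mix.get(f, 0.0) * n for f in FATES}
    counts = {f: int(np.floor(v)) for f, v in raw.items()}
    rem = n - sum(counts.values())
    order = sorted(FATES, key=lambda f: raw[f] - counts[f], reverse=True)
    for f in order[:rem]:
        counts[f] += 1
    return counts


def simulate_cohort(config: ScenarioConfig | None = None) -> SimulatedCohort:
    """Generate a full cohort: fixes, weather, metadata and ground truth."""
    cfg = config or ScenarioConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    weather = _simulate_weather(cfg, rng)
    n = cfg.n_individuals

    design = reference_design()
    truth_cols = [
        "individual_id", "fate", "release_timestamp", "death_time", "departure_date",
        "survival_days_true", "actavg_true", "wdsp_window_mean", "z_actavg", "z_wdsp",
    ]
    if n == 0:
        empty_truth = GroundTruth(
            individuals=pd.DataFrame(columns=truth_cols),
            daily_activity=pd.DataFrame(columns=["individual_id", "date", "activity", "hours_observed"]),
            hazard=asdict(cfg.hazard_spec),
        )
        return SimulatedCohort(_empty_fixes(), weather,
                               pd.DataFrame(columns=list(META_COLUMNS)), empty_truth, cfg)

    ids = [f"G{i:03d}" for i in range(1, n + 1)]
    start = pd.Timestamp(cfg.start_date, tz="UTC") + pd.Timedelta(hours=12 - LOCAL_UTC_OFFSET_H)
    release = [start + pd.Timedelta(days=int(d)) for d in rng.integers(0, cfg.release_stagger_days + 1, n)]
    sampled = design.sample(n=n, replace=True, random_state=np.random.RandomState(cfg.seed + 1))
    meta = pd.DataFrame(
        {
            "individual_id": ids,
            "species": sampled["species"].to_numpy(),
            "release_site": sampled["release_site"].to_numpy(),
            "source": sampled["source"].to_numpy(),
            "tracker": sampled["tracker"].to_numpy(),
            "release_year": sampled["release_year"].to_numpy(),
            "release_timestamp": release,
            "weight": np.round(rng.normal(MEAN_BODY_MASS_KG, 0.3, n).clip(2.1, 4.2), 3),
        }
    )

    aspec = cfg.activity_spec
    a_day = rng.normal(aspec.day_mean, aspec.between_sd, n).clip(25.0, None)
    a_night = np.maximum(aspec.night_floor, a_day / 3.0)
    day_len = aspec.day_hours[1] - aspec.day_hours[0] + 1
    actavg_true = day_len * a_day + (24 - day_len) * a_night

    dep_offset = rng.uniform(*cfg.departure_offset_days, n)
    dep_offset = np.minimum(dep_offset, cfg.horizon_days - 40.0)
    departure_ts = [release[i] + pd.Timedelta(days=float(dep_offset[i])) for i in range(n)]
    wdsp_win = np.array(
        [
            _window_mean(weather, departure_ts[i], "WDSP", 14)
            for i in range(n)
        ]
    )
    z_act = _zscore(actavg_true)
    z_wd = _zscore(wdsp_win)
    hz = cfg.hazard_spec
    rate = hz.baseline_per_day * np.exp(hz.log_hr_actavg * z_act + hz.log_hr_wdsp * z_wd)

    if cfg.hazard_driven_fates:
        fates, death_day, loss_day = _hazard_driven_fates(cfg, rng, rate, dep_offset, n)
    else:
        counts_by_fate = _fate_counts(cfg.fate_mix, n)
        fate_vec = [f for f in FATES for _ in range(counts_by_fate[f])]
        fates = list(np.array(fate_vec, dtype=object)[rng.permutation(n)])
        death_day = np.full(n, np.nan)
        loss_day = np.full(n, np.nan)
        for i, f in enumerate(fates):
            b = min(float(dep_offset[i]) - 2.0, cfg.horizon_days - 5.0)
            a = min(15.0, b - 5.0)
            if f == "natural_death":
                # truncated-exponential death time in (a, b]
                u = rng.uniform()
                r = rate[i]
                death_day[i] = a - np.log(1.0 - u * (1.0 - np.exp(-r * (b - a)))) / r
            elif f == "hunting_loss":
                loss_day[i] = rng.uniform(a, b)

    tracks = []
    rows = []
    for i, ind in enumerate(ids):
        fate = fates[i]
        site = SITE_COORDS[meta["release_site"].iloc[i]]
        dts = release[i] + pd.Timedelta(hours=round(death_day[i] * 24)) if np.isfinite(death_day[i]) else None
        lts = release[i] + pd.Timedelta(hours=round(loss_day[i] * 24)) if np.isfinite(loss_day[i]) else None
        dep = departure_ts[i] if fate == "survivor_migrant" or (
            cfg.hazard_driven_fates and fate == "natural_death" and death_day[i] > dep_offset[i]
        ) else None
        track = _build_track(rng, ind, cfg, weather, release[i], site, float(a_day[i]),
                             fate, dts, lts, dep)
        tracks.append(track)
        if fate == "natural_death":
            surv = float(death_day[i])
        elif fate == "hunting_loss":
            surv = float(loss_day[i])
        else:
            surv = float(cfg.horizon_days)
        rows.append(
            {
                "individual_id": ind,
                "fate": fate,
                "release_timestamp": release[i],
                "death_time": dts,
                "departure_date": (dep + pd.Timedelta(hours=LOCAL_UTC_OFFSET_H)).date() if dep is not None else None,
                "survival_days_true": surv,
                "actavg_true": float(actavg_true[i]),
                "wdsp_window_mean": float(wdsp_win[i]),
                "z_actavg": float(z_act[i]),
                "z_wdsp": float(z_wd[i]),
            }
        )

    prenoise = pd.concat(tracks, ignore_index=True)
    truth_daily = daily_activity(prenoise)
    fixes = inject_accuracy_noise(prenoise, cfg.noise_spec.accuracy_mix, rng)
    truth = GroundTruth(
        individuals=pd.DataFrame(rows, columns=truth_cols),
        daily_activity=truth_daily,
        hazard=asdict(cfg.hazard_spec),
    )
    return SimulatedCohort(fixes=fixes, weather=weather, meta=meta, truth=truth, config=cfg)


def _window_mean(weather: pd.DataFrame, window_end: pd.Timestamp, var: str, span_days: int) -> float:
    end = pd.Timestamp(window_end).tz_localize(None).normalize()
    dates = pd.to_datetime(weather["date"])
    sel = weather[(dates >= end - pd.Timedelta(days=span_days)) & (dates < end)]
    return float(sel[var].mean())


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if len(v) < 2 or np.std(v) == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / v.std(ddof=0)


def _hazard_driven_fates(cfg, rng, rate, dep_offset, n):
    """Exponential death times competing with hunting truncation and the
    administrative horizon; survivors split migrant/resident by fate_mix."""
    T = rng.exponential(1.0 / rate)
    T = np.maximum(T, 4.0)  # room for the pre-death decline
    p_hunt = cfg.fate_mix.get("hunting_loss", 0.0)
    L = np.where(rng.random(n) < p_hunt, rng.uniform(15.0, cfg.horizon_days - 30.0, n), np.inf)
    mig = cfg.fate_mix.get("survivor_migrant", 0.0)
    res = cfg.fate_mix.get("censored_resident", 0.0)
    p_mig = mig / (mig + res) if (mig + res) > 0 else 0.5
    migrant_type = rng.random(n) < p_mig
    fates = []
    death_day = np.full(n, np.nan)
    loss_day = np.full(n, np.nan)
    limit = cfg.horizon_days - 5.0
    for i in range(n):
        if T[i] <= min(L[i], limit):
            fates.append("natural_death")
            death_day[i] = T[i]
        elif L[i] <= limit:
            fates.append("hunting_loss")
            loss_day[i] = L[i]
        else:
            fates.append("survivor_migrant" if migrant_type[i] else "censored_resident")
    return fates, death_day, loss_day


# ---------------------------------------------------------------------------
# covariate-level survival simulator (Cox coefficient recovery)
# ---------------------------------------------------------------------------

def simulate_survival_data(
    n: int,
    log_hrs: tuple[float, float] = (float(np.log(0.461)), float(np.log(2.311))),
    baseline_per_day: float = 0.0025,
    horizon_days: float = 365.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Standardized-covariate survival data from an exponential-baseline Cox
    model with the given log hazard ratios, right-censored at the horizon."""
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    rate = baseline_per_day * np.exp(log_hrs[0] * z1 + log_hrs[1] * z2)
    T = rng.exponential(1.0 / rate)
    event = (T <= horizon_days).astype(int)
    return pd.DataFrame(
        {
            "actavg_z": z1,
            "wdsp_z": z2,
            "survival_days": np.minimum(T, horizon_days),
            "event": event,
        }
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Write the cohort's tables in the dialects read by telemetry_io, plus
    ground truth as CSV and a JSON sidecar. Returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fixes": out / "fixes.csv",
        "weather": out / "weather.csv",
        "meta": out / "meta.csv",
        "truth_individuals": out / "truth_individuals.csv",
        "truth_daily_activity": out / "truth_daily_activity.csv",
        "truth": out / "truth.json",
    }
    write_fixes(cohort.fixes, paths["fixes"])
    write_weather(cohort.weather, paths["weather"])
    write_meta(cohort.meta, paths["meta"])
    ti = cohort.truth.individuals.copy()
    for col in ("release_timestamp", "death_time"):
        ti[col] = pd.to_datetime(ti[col], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    ti.to_csv(paths["truth_individuals"], index=False, float_format="%.6f")
    cohort.truth.daily_activity.to_csv(paths["truth_daily_activity"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump({"hazard": cohort.truth.hazard, "seed": cohort.config.seed,
                   "n_individuals": cohort.config.n_individuals}, fh, indent=2)
    return paths
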