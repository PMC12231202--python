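import numpy as np
import pandas as pd
import pytest

from goosurv import mortality
from goosurv._geo import LocalProjection

from conftest import make_fixes, make_weather


# ---------------------------------------------------------------------------
# independent exhaustive oracles
# ---------------------------------------------------------------------------

def brute_force_runs(ok: pd.Series, dur_h: float):
    """All maximal windows of an hourly boolean series that are True
    throughout and span >= dur_h, by checking every (i, j) pair."""
    idx = ok.index
    v = ok.to_numpy()
    n = len(v)
    dur = pd.Timedelta(hours=dur_h) - pd.Timedelta(seconds=1)
    out = []
    for i in range(n):
        for j in range(i, n):
            if not (v[i : j + 1].all() and (idx[j] - idx[i]) >= dur):
                continue
            # maximal iff the window cannot be extended on either side
            if (i == 0 or not v[i - 1]) and (j == n - 1 or not v[j + 1]):
                out.append((idx[i], idx[j]))
    return out


def brute_force_confinement(fixes: pd.DataFrame, radius_m: float, dur_h: float):
    """Every (start, end) fix pair whose window fits within radius of its own
    medoid and spans >= dur_h, reduced to maximal windows."""
    f = fixes.sort_values("timestamp").reset_index(drop=True)
    ts = pd.DatetimeIndex(pd.to_datetime(f["timestamp"], utc=True))
    proj = LocalProjection(float(f["longitude"].mean()), float(f["latitude"].mean()))
    x, y = proj.forward(f["longitude"].to_numpy(), f["latitude"].to_numpy())
    D = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
    n = len(f)
    dur = pd.Timedelta(hours=dur_h) - pd.Timedelta(seconds=1)
    qualifying = []
    for i in range(n):
        for j in range(i + 2, n):
            if (ts[j] - ts[i]) < dur:
                continue
            sub = D[i : j + 1, i : j + 1]
            med = int(np.argmin(sub.sum(axis=0)))
            if sub[med].max() <= radius_m:
                qualifying.append((i, j))
    # drop windows nested in another qualifying window: per start only the
    # largest end survives, then a sweep over increasing starts
    best_end: dict[int, int] = {}
    for i, j in qualifying:
        best_end[i] = max(best_end.get(i, -1), j)
    maximal = []
    prev = -1
    for i in sorted(best_end):
        if best_end[i] > prev:
            maximal.append((i, best_end[i]))
            prev = best_end[i]
    return [(ts[i], ts[j]) for i, j in maximal]


# ---------------------------------------------------------------------------
# interval machinery
# ---------------------------------------------------------------------------

def _bool_series(n, p_true, seed, start="2024-01-01T00:00:00Z"):
    rng = np.random.default_rng(seed)
    idx = pd.date_range(start, periods=n, freq="h", tz="UTC")
    return pd.Series(rng.random(n) < p_true, index=idx)


@pytest.mark.parametrize("seed,p", [(0, 0.9), (1, 0.97), (2, 0.5)])
def test_runs_to_intervals_matches_brute_force(seed, p):
    ok = _bool_series(300, p, seed)
    got = mortality._runs_to_intervals(ok, 24.0)
    assert got == brute_force_runs(ok, 24.0)


def test_fill_gaps_bridges_short_outages_only():
    idx = pd.date_range("2024-01-01", periods=30, freq="h", tz="UTC")
    ok = pd.Series(True, index=idx)
    short = ok.drop(idx[5:9])        # 4 h gap flanked by True -> bridged
    filled = mortality._fill_gaps(short, gap_fill_h=6)
    assert filled.all() and len(filled) == 30
    long = ok.drop(idx[5:13])        # 8 h gap -> breaks the run
    filled2 = mortality._fill_gaps(long, gap_fill_h=6)
    assert not filled2.iloc[5:13].any() and filled2.iloc[0:5].all() and filled2.iloc[13:].all()


def test_thermal_equilibration_inclusive_bound():
    idx = pd.date_range("2024-01-01", periods=100, freq="h", tz="UTC")
    ambient = pd.Series(10.0, index=idx)
    device = pd.Series(12.0, index=idx)  # exactly at the 2.0 degC tolerance
    ivs = mortality.thermal_equilibration(device, ambient, tol_c=2.0, dur_h=72.0)
    assert ivs == [(idx[0], idx[-1])]
    device2 = pd.Series(12.0001, index=idx)
    assert mortality.thermal_equilibration(device2, ambient, tol_c=2.0, dur_h=72.0) == []


def test_quiescence_strict_bound():
    idx = pd.date_range("2024-01-01", periods=48, freq="h", tz="UTC")
    at_threshold = pd.Series(10.0, index=idx)  # exactly 10 counts: not quiescent
    assert mortality.quiescence(at_threshold, max_count=10, dur_h=24.0) == []
    below = pd.Series(9.0, index=idx)
    assert mortality.quiescence(below, max_count=10, dur_h=24.0) == [(idx[0], idx[-1])]


# ---------------------------------------------------------------------------
# confinement
# ---------------------------------------------------------------------------

def _wandering_track(n, step_sd_m, seed, settle_at=None, settle_sd_m=30.0):
    """Random-walk track; optionally settles in place from index settle_at."""
    rng = np.random.default_rng(seed)
    dx = rng.normal(0, step_sd_m, n).cumsum()
    dy = rng.normal(0, step_sd_m, n).cumsum()
    if settle_at is not None:
        dx[settle_at:] = dx[settle_at] + rng.normal(0, settle_sd_m, n - settle_at)
        dy[settle_at:] = dy[settle_at] + rng.normal(0, settle_sd_m, n - settle_at)
    lat = 29.3 + dy / 111_320.0
    lon = 116.2 + dx / (111_320.0 * np.cos(np.radians(29.3)))
    return make_fixes(n, lon=lon, lat=lat, seed=seed + 100)


@pytest.mark.parametrize("seed", [0, 1])
def test_confinement_matches_exhaustive(seed):
    f = _wandering_track(140, step_sd_m=160.0, seed=seed, settle_at=60)
    got = mortality.confinement(f, radius_m=200.0, dur_h=24.0)
    assert got == brute_force_confinement(f, 200.0, 24.0)
    assert got, "a settled track must produce a confinement window"


def test_confinement_mobile_track_has_no_window():
    f = _wandering_track(120, step_sd_m=400.0, seed=3)
    assert mortality.confinement(f, radius_m=200.0, dur_h=24.0) == \
        brute_force_confinement(f, 200.0, 24.0)


# ---------------------------------------------------------------------------
# decline / abrupt loss
# ---------------------------------------------------------------------------

def _declining_fixes(n=80, seed=0):
    rng = np.random.default_rng(seed)
    ramp = np.linspace(1.0, 0.0, n)
    return make_fixes(
        n,
        counts=np.maximum((60 * ramp + rng.normal(0, 2, n)).round(), 0).astype(int),
        altitude=45 * ramp + rng.normal(0, 1, n),
        speed=np.maximum(1.5 * ramp + rng.normal(0, 0.03, n), 0.01),
        seed=seed,
    )


def test_decline_trend_detects_ramp_not_noise():
    assert mortality.decline_trend(_declining_fixes())
    noisy = make_fixes(80, counts=np.random.default_rng(1).poisson(50, 80),
                       altitude=np.random.default_rng(2).normal(45, 10, 80),
                       speed=np.random.default_rng(3).gamma(1.5, 0.8, 80))
    assert not mortality.decline_trend(noisy)
    flat = make_fixes(80, counts=50)
    assert not mortality.decline_trend(flat)     # constant series never declines
    assert not mortality.decline_trend(_declining_fixes(n=10))  # too few points


def test_detect_abrupt_loss_requires_normal_terminal_state():
    expected_end = pd.Timestamp("2024-06-01T00:00:00Z")
    active = make_fixes(200, counts=np.random.default_rng(4).poisson(50, 200))
    abrupt, diag = mortality.detect_abrupt_loss(active, expected_end)
    assert abrupt and diag["terminated_early"] and not diag["decline_before_end"]

    declining = _declining_fixes(n=80)
    abrupt2, diag2 = mortality.detect_abrupt_loss(declining, expected_end)
    assert not abrupt2 and diag2["decline_before_end"]

    quiet_tail = make_fixes(200, counts=np.r_[np.full(150, 50), np.full(50, 2)])
    abrupt3, diag3 = mortality.detect_abrupt_loss(quiet_tail, expected_end)
    assert not abrupt3 and diag3["final_24h_mean_count"] < 10

    # a track running to its expected end is not terminated early
    full = make_fixes(100, counts=50)
    last = pd.to_datetime(full["timestamp"], utc=True).iloc[-1]
    abrupt4, _ = mortality.detect_abrupt_loss(full, last + pd.Timedelta(hours=2))
    assert not abrupt4


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _death_track(death_at_h=240, post_h=84, seed=0):
    """Normal activity, 72 h decline into death, then a full death signature."""
    rng = np.random.default_rng(seed)
    n = death_at_h + post_h
    hours = np.arange(n)
    progress = np.clip((hours - (death_at_h - 72)) / 72.0, 0.0, 1.0)
    alive = hours < death_at_h
    counts = np.where(alive, np.maximum(rng.poisson(np.maximum(60 * (1 - progress), 11)), 0), 0)
    device = np.where(alive, 27.0, 20.0 + rng.normal(0, 0.3, n))  # ambient 20
    lat = np.where(alive, 29.3 + rng.normal(0, 0.0008, n), 29.3)
    lon = np.where(alive, 116.2 + rng.normal(0, 0.0008, n), 116.2)
    return make_fixes(n, counts=counts, device_temp=device, lat=lat, lon=lon,
                      altitude=np.where(alive, 45.0, 5.0),
                      speed=np.where(alive, 1.0, 0.0), seed=seed)


def test_classify_dead_confirmed_with_death_time():
    fixes = _death_track()
    weather = make_weather(start="2023-12-20", temp=20.0)
    rec = mortality.classify_mortality(fixes, weather, "2024-01-04T23:00:00Z")
    assert rec.fate == "dead_confirmed" and rec.event == 1
    true_death = pd.Timestamp("2024-01-05T00:00:00Z", tz="UTC") + pd.Timedelta(hours=240)
    assert abs((rec.death_time - true_death).total_seconds()) <= 3600 * 24
    assert rec.criteria_windows["thermal"] and rec.criteria_windows["quiescence"]
    assert rec.criteria_windows["confinement"]


def _jittered(n, seed, jitter_m=2500.0):
    """lat/lon arrays with GPS-scale scatter so a live bird never looks confined."""
    rng = np.random.default_rng(seed)
    lat = 29.3 + rng.normal(0, jitter_m, n) / 111_320.0
    lon = 116.2 + rng.normal(0, jitter_m, n) / (111_320.0 * np.cos(np.radians(29.3)))
    return lon, lat


def test_classify_survivor_censored_at_horizon():
    n = 24 * 400
    lon, lat = _jittered(n, seed=9)
    fixes = make_fixes(n, lon=lon, lat=lat, counts=np.random.default_rng(0).poisson(50, n))
    weather = make_weather(start="2023-12-20", days=450, temp=20.0)
    rec = mortality.classify_mortality(fixes, weather, "2024-01-04T23:00:00Z")
    assert rec.fate == "censored" and rec.event == 0
    assert rec.survival_days == pytest.approx(365.0)


def test_classify_hunting_loss_censored_at_last_fix():
    n = 24 * 30
    lon, lat = _jittered(n, seed=10)
    fixes = make_fixes(n, lon=lon, lat=lat, counts=np.random.default_rng(0).poisson(50, n))
    weather = make_weather(start="2023-12-20", temp=20.0)
    rec = mortality.classify_mortality(fixes, weather, "2024-01-04T23:00:00Z")
    assert rec.fate == "hunting_or_loss" and rec.event == 0
    assert rec.survival_days == pytest.approx(30.0, abs=0.1)


def test_classify_empty_track():
    rec = mortality.classify_mortality(make_fixes(0), make_weather(), "2024-01-04T23:00:00Z")
    assert rec.fate == "censored" and rec.flags.get("empty_track")


def test_ambient_hourly_interpolates_between_local_noons():
    w = make_weather(start="2024-01-01", days=3)
    w.loc[:, "TEMP"] = [10.0, 20.0, 30.0]
    # local noon on Jan 1 is 04:00 UTC; halfway to Jan 2's anchor is 16:00 UTC
    idx = pd.DatetimeIndex(pd.to_datetime(["2024-01-01T04:00:00Z", "2024-01-01T16:00:00Z",
                                           "2024-01-02T04:00:00Z"], utc=True))
    amb = mortality.ambient_hourly(w, idx)
    np.testing.assert_allclose(amb.to_numpy(), [10.0, 15.0, 20.0])
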