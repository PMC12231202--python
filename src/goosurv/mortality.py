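"""Rule-based mortality classification from telemetry signatures.

A death is *biologically confirmed* only when three criteria hold
simultaneously, each over its own sustained window:

1. **thermal equilibration** — the device temperature tracks ambient within
   +/-2 degC continuously for >= 72 h (a live goose keeps the housing well above
   ambient);
2. **behavioural quiescence** — fewer than 10 movement counts per hour for
   >= 24 consecutive hours (strict "<");
3. **spatial confinement** — every fix within a 200 m radius of the
   interval's medoid for >= 72 h.

Death time is the start of the earliest triple-overlap of the three interval
sets, and must precede transmitter signal termination. Tracks that terminate
abruptly from a normal-activity state (no preceding decline in counts,
altitude and speed; no death signature) are treated as hunting or tag loss
and right-censored at the last valid fix. Survivors past the study horizon
are right-censored with survival time truncated at 365 days.

Ambient temperature is the station daily TEMP linearly interpolated to
hourly, anchored at local noon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._geo import LocalProjection
from .activity import LOCAL_UTC_OFFSET_H, local_date

Interval = tuple[pd.Timestamp, pd.Timestamp]


@dataclass
class MortalityParams:
    thermal_tol_c: float = 2.0          # inclusive bound, +/-2 degC
    thermal_dur_h: float = 72.0
    quiescence_max_count: int = 10      # strict "<"
    quiescence_dur_h: float = 24.0
    confinement_radius_m: float = 200.0
    confinement_dur_h: float = 72.0
    decline_window_h: float = 72.0
    abrupt_gap_h: float = 72.0
    horizon_days: int = 365
    gap_fill_h: int = 6                 # tolerate short GSM transmission outages


@dataclass
class FateRecord:
    individual_id: str
    fate: str                   # dead_confirmed | hunting_or_loss | censored
    survival_days: float
    event: int                  # 1 iff dead_confirmed
    death_time: pd.Timestamp | None = None
    criteria_windows: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ambient temperature
# ---------------------------------------------------------------------------

def ambient_hourly(weather: pd.DataFrame, index: pd.DatetimeIndex) -> pd.Series:
    """Station daily TEMP interpolated linearly to the given hourly index.

    Daily values are anchored at local noon (UTC+8 study region); values
    outside the station record are held at the nearest day.
    """
    w = weather.dropna(subset=["TEMP"])
    if w.empty:
        raise ValueError("no non-missing TEMP in weather table")
    anchor = pd.to_datetime(w["date"]).dt.tz_localize("UTC") + pd.Timedelta(
        hours=12 - LOCAL_UTC_OFFSET_H
    )
    vals = np.interp(
        index.asi8.astype(float),
        pd.DatetimeIndex(anchor).asi8.astype(float),
        w["TEMP"].to_numpy(dtype=float),
    )
    return pd.Series(vals, index=index, name="ambient")


# ---------------------------------------------------------------------------
# run/interval machinery on hourly predicates
# ---------------------------------------------------------------------------

def _fill_gaps(ok: pd.Series, gap_fill_h: int) -> pd.Series:
    """Reindex a predicate series to hourly cadence, bridging short gaps.

    A missing stretch of <= gap_fill_h hours flanked by True hours counts as
    True (short transmission outage); anything longer breaks the run.
    """
    if ok.empty:
        return ok.astype(bool)
    full = pd.date_range(ok.index[0], ok.index[-1], freq="h")
    s = ok.astype("float64").reindex(full)
    vals = s.to_numpy()
    isnan = np.isnan(vals)
    if isnan.any():
        idx = np.flatnonzero(isnan)
        # contiguous NaN runs
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(idx) - 1]))
        for s0, e0 in zip(starts, ends):
            a, b = idx[s0], idx[e0]
            length = b - a + 1
            left_ok = a > 0 and vals[a - 1] == 1.0
            right_ok = b < len(vals) - 1 and vals[b + 1] == 1.0
            vals[a : b + 1] = 1.0 if (length <= gap_fill_h and left_ok and right_ok) else 0.0
    return pd.Series(vals.astype(bool), index=full)


def _runs_to_intervals(ok: pd.Series, dur_h: float) -> list[Interval]:
    """Maximal True runs with span (last - first) >= dur_h hours."""
    if ok.empty:
        return []
    v = ok.to_numpy()
    out: list[Interval] = []
    i = 0
    n = len(v)
    while i < n:
        if v[i]:
            j = i
            while j + 1 < n and v[j + 1]:
                j += 1
            if (ok.index[j] - ok.index[i]) >= pd.Timedelta(hours=dur_h) - pd.Timedelta(seconds=1):
                out.append((ok.index[i], ok.index[j]))
            i = j + 1
        else:
            i += 1
    return out


def thermal_equilibration(
    device_temp: pd.Series,
    ambient: pd.Series,
    tol_c: float = 2.0,
    dur_h: float = 72.0,
    gap_fill_h: int = 6,
) -> list[Interval]:
    """Maximal intervals with |device - ambient| <= tol_c continuously >= dur_h.

    The bound is inclusive (a difference of exactly 2.0 degC qualifies).
    """
    diff = (device_temp - ambient.reindex(device_temp.index)).dropna()
    ok = diff.abs() <= tol_c
    return _runs_to_intervals(_fill_gaps(ok, gap_fill_h), dur_h)


def quiescence(
    hourly_counts: pd.Series,
    max_count: int = 10,
    dur_h: float = 24.0,
    gap_fill_h: int = 6,
) -> list[Interval]:
    """Maximal intervals with counts strictly below max_count for >= dur_h."""
    ok = hourly_counts.dropna() < max_count
    return _runs_to_intervals(_fill_gaps(ok, gap_fill_h), dur_h)


# ---------------------------------------------------------------------------
# confinement
# ---------------------------------------------------------------------------

def _medoid_ok_windows(D: np.ndarray, radius_m: float) -> list[tuple[int, int]]:
    """For each start i, the largest end j with every point within radius of
    the window's medoid; reduced to maximal (non-nested) windows."""
    m = D.shape[0]
    best: list[tuple[int, int]] = []
    for i in range(m):
        S = D[:, i].copy()
        j_ok = -1
        for j in range(i, m):
            if j > i:
                S += D[:, j]
            sub = slice(i, j + 1)
            medoid = i + int(np.argmin(S[sub]))
            if D[medoid, sub].max() <= radius_m:
                j_ok = j
        if j_ok >= i:
            best.append((i, j_ok))
    out: list[tuple[int, int]] = []
    prev = -1
    for i, j in best:
        if j > prev:
            out.append((i, j))
            prev = j
    return out


def confinement(
    fixes: pd.DataFrame,
    radius_m: float = 200.0,
    dur_h: float = 72.0,
) -> list[Interval]:
    """Maximal intervals during which every fix lies within ``radius_m`` of
    the interval's geometric medoid (the fix minimizing total distance to the
    others), spanning >= dur_h.

    Any qualifying window has consecutive-fix steps <= 2*radius, so the exact
    medoid scan only runs inside movement-pruned segments; the result is
    identical to an exhaustive scan over all start/end pairs.
    """
    f = fixes.sort_values("timestamp").reset_index(drop=True)
    if len(f) < 3:
        return []
    ts = pd.DatetimeIndex(pd.to_datetime(f["timestamp"], utc=True))
    proj = LocalProjection(float(f["longitude"].mean()), float(f["latitude"].mean()))
    x, y = proj.forward(f["longitude"].to_numpy(), f["latitude"].to_numpy())
    step = np.hypot(np.diff(x), np.diff(y))
    cut = np.flatnonzero(step > 2.0 * radius_m)
    seg_starts = np.concatenate(([0], cut + 1))
    seg_ends = np.concatenate((cut, [len(f) - 1]))
    dur = pd.Timedelta(hours=dur_h) - pd.Timedelta(seconds=1)
    out: list[Interval] = []
    for a, b in zip(seg_starts, seg_ends):
        m = b - a + 1
        if m < 3 or (ts[b] - ts[a]) < dur:
            continue
        xs, ys = x[a : b + 1], y[a : b + 1]
        D = np.hypot(xs[:, None] - xs[None, :], ys[:, None] - ys[None, :])
        for i, j in _medoid_ok_windows(D, radius_m):
            if (ts[a + j] - ts[a + i]) >= dur:
                out.append((ts[a + i], ts[a + j]))
    return out


# ---------------------------------------------------------------------------
# decline / abrupt loss / classification
# ---------------------------------------------------------------------------

def decline_trend(
    fixes: pd.DataFrame,
    window_h: float = 72.0,
    at: pd.Timestamp | None = None,
    min_points: int = 24,
) -> bool:
    """True when hourly counts, altitude and speed all show a robustly
    negative trend over the window ending at ``at`` (default: last fix).

    The Theil-Sen slope is used with its 95% confidence band; a series
    counts as declining only when the whole band is below zero, so pure
    noise almost never qualifies while a genuine pre-death decline does.
    """
    f = fixes.sort_values("timestamp")
    ts = pd.DatetimeIndex(pd.to_datetime(f["timestamp"], utc=True))
    end = ts[-1] if at is None else pd.Timestamp(at)
    mask = (ts > end - pd.Timedelta(hours=window_h)) & (ts <= end)
    if int(mask.sum()) < min_points:
        return False
    hours = (ts[mask] - ts[mask][0]).total_seconds() / 3600.0
    for col in ("exercise_volume", "altitude", "speed"):
        series = f.loc[mask.to_numpy() if hasattr(mask, "to_numpy") else mask, col].to_numpy(dtype=float)
        if np.allclose(series, series[0]):
            return False
        res = stats.theilslopes(series, hours)
        if not (res[3] < 0):  # upper bound of the slope CI
            return False
    return True


def detect_abrupt_loss(
    fixes: pd.DataFrame,
    expected_end: pd.Timestamp | None = None,
    gap_h: float = 72.0,
    decline_window_h: float = 72.0,
    normal_activity_count: float = 10.0,
) -> tuple[bool, dict]:
    """True when the stream terminates >= gap_h before the expected end from a
    normal-activity state: no preceding decline trend and mean hourly counts
    over the final 24 h at or above the quiescence threshold.

    A track that goes quiet before terminating (a death signature) is not an
    abrupt loss; :func:`classify_mortality` additionally gives precedence to
    a criteria triple-overlap.
    """
    f = fixes.sort_values("timestamp")
    if f.empty:
        return False, {"empty": True}
    ts = pd.DatetimeIndex(pd.to_datetime(f["timestamp"], utc=True))
    last = ts[-1]
    terminated = expected_end is not None and last + pd.Timedelta(hours=gap_h) < pd.Timestamp(expected_end)
    declined = decline_trend(f, window_h=decline_window_h, at=last)
    tail = ts > last - pd.Timedelta(hours=24)
    tail_mean = float(f.loc[np.asarray(tail), "exercise_volume"].mean())
    normal = tail_mean >= normal_activity_count
    return bool(terminated and not declined and normal), {
        "terminated_early": bool(terminated),
        "last_fix": last,
        "decline_before_end": bool(declined),
        "final_24h_mean_count": tail_mean,
    }


def _hourly_series(fixes: pd.DataFrame, col: str) -> pd.Series:
    ts = pd.DatetimeIndex(pd.to_datetime(fixes["timestamp"], utc=True)).floor("h")
    return pd.Series(fixes[col].to_numpy(dtype=float), index=ts).groupby(level=0).mean()


def _triple_overlap(thermal, quiet, confined) -> Interval | None:
    """Earliest mutual overlap of one interval from each criterion."""
    best: Interval | None = None
    for t0, t1 in thermal:
        for q0, q1 in quiet:
            for c0, c1 in confined:
                s = max(t0, q0, c0)
                e = min(t1, q1, c1)
                if s <= e and (best is None or s < best[0]):
                    best = (s, e)
    return best


def classify_mortality(
    fixes: pd.DataFrame,
    weather: pd.DataFrame,
    release_timestamp,
    params: MortalityParams | None = None,
) -> FateRecord:
    """Classify one individual's fate from its accuracy-filtered track.

    dead_confirmed requires the three criteria's intervals to overlap
    mutually, with the overlap preceding signal termination; hunting/abrupt
    loss without a death signature is right-censored at the last valid fix;
    everything else is censored at min(tracked days, horizon).
    """
    p = params or MortalityParams()
    ind = str(fixes["individual_id"].iloc[0]) if len(fixes) else "<empty>"
    release = pd.Timestamp(release_timestamp)
    if release.tzinfo is None:
        release = release.tz_localize("UTC")
    if fixes.empty:
        return FateRecord(ind, "censored", 0.0, 0, flags={"empty_track": True})

    f = fixes.sort_values("timestamp").reset_index(drop=True)
    last_fix = pd.Timestamp(pd.to_datetime(f["timestamp"], utc=True).iloc[-1])
    counts = _hourly_series(f, "exercise_volume")
    device = _hourly_series(f, "device_temp")
    ambient = ambient_hourly(weather, pd.DatetimeIndex(device.index))

    thermal = thermal_equilibration(device, ambient, p.thermal_tol_c, p.thermal_dur_h, p.gap_fill_h)
    quiet = quiescence(counts, p.quiescence_max_count, p.quiescence_dur_h, p.gap_fill_h)
    confined = confinement(f, p.confinement_radius_m, p.confinement_dur_h)
    windows = {"thermal": thermal, "quiescence": quiet, "confinement": confined}

    expected_end = release + pd.Timedelta(days=p.horizon_days)
    abrupt, loss_diag = detect_abrupt_loss(f, expected_end, p.abrupt_gap_h, p.decline_window_h)
    overlap = _triple_overlap(thermal, quiet, confined)

    flags = {"abrupt_loss": loss_diag}
    horizon = float(p.horizon_days)
    if overlap is not None and overlap[0] <= last_fix:
        death_time = overlap[0]
        if abrupt and last_fix < death_time:
            flags["contradictory_signals"] = True  # earlier event takes precedence
        days = (death_time - release).total_seconds() / 86400.0
        if days > horizon:
            return FateRecord(ind, "censored", horizon, 0, None, windows,
                              {**flags, "death_after_horizon": True})
        return FateRecord(ind, "dead_confirmed", float(days), 1, death_time, windows, flags)
    if abrupt:
        days = min((last_fix - release).total_seconds() / 86400.0, horizon)
        return FateRecord(ind, "hunting_or_loss", float(days), 0, None, windows, flags)
    missing = [k for k, v in windows.items() if not v]
    if missing:
        flags["criteria_unmet"] = missing
    days = min((last_fix - release).total_seconds() / 86400.0, horizon)
    return FateRecord(ind, "censored", float(days), 0, None, windows, flags)


def fate_end_date(record: FateRecord, release_timestamp):
    """Local calendar date at which an individual's record ends."""
    release = pd.Timestamp(release_timestamp)
    if release.tzinfo is None:
        release = release.tz_localize("UTC")
    end = release + pd.Timedelta(days=record.survival_days)
    return local_date([end])[0]
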