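"""Activity metrics: ODBA, hourly movement counts, daily activity, ActAvg.

The trackers quantify body movement with overall dynamic body acceleration
(ODBA): the sum of absolute dynamic (gravity-removed) acceleration over the
three axes. Within each one-hour collection cycle the device increments a
movement counter whenever ODBA strictly exceeds 0.15 G; that hourly count is
shipped in the fix table as ``exercise_volume``. In the analysis pipeline the
device count is trusted as-is; :func:`odba` and :func:`count_movements`
reproduce the on-board computation for simulation and testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Manufacturer-calibrated movement threshold (G).
ODBA_THRESHOLD_G = 0.15
#: Local civil time of the study region (UTC+8); defines the day boundary.
LOCAL_UTC_OFFSET_H = 8
#: Days with fewer observed hours than this are excluded from ActAvg.
MIN_HOURS_PER_DAY = 20


def odba(dynamic_accel: np.ndarray) -> np.ndarray:
    """ODBA per sample from dynamic-acceleration triples (ax, ay, az) in G.

    ODBA_t = |ax_t| + |ay_t| + |az_t|. The static gravitational component must
    already have been removed (as the devices do on board).
    """
    a = np.asarray(dynamic_accel, dtype=float)
    if a.ndim == 1:
        a = a.reshape(1, -1)
    if a.shape[-1] != 3:
        raise ValueError("expected (n, 3) dynamic-acceleration triples")
    if not np.isfinite(a).all():
        raise ValueError("non-finite acceleration value")
    return np.abs(a).sum(axis=-1)


def count_movements(odba_series, timestamps=None, threshold: float = ODBA_THRESHOLD_G, cycle: str = "1h"):
    """Movement counts per collection cycle: samples with ODBA > threshold.

    With ``timestamps`` given, returns a Series of counts indexed by cycle
    start (cycles with no samples are absent; their count is 0 by
    convention). Without timestamps the whole input is a single cycle and an
    integer is returned. Exceedance is strict, matching the device rule that
    the counter increments only when ODBA *exceeds* the threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    vals = np.asarray(odba_series, dtype=float)
    hits = vals > threshold
    if timestamps is None:
        return int(hits.sum())
    idx = pd.DatetimeIndex(pd.to_datetime(timestamps, utc=True)).floor(cycle)
    return pd.Series(hits.astype(np.int64), index=idx).groupby(level=0).sum()


def local_date(timestamps, utc_offset_h: int = LOCAL_UTC_OFFSET_H):
    """Local civil date for UTC timestamps (study site is UTC+8)."""
    ts = pd.DatetimeIndex(pd.to_datetime(timestamps, utc=True))
    return (ts + pd.Timedelta(hours=utc_offset_h)).date


def daily_activity(fixes: pd.DataFrame, utc_offset_h: int = LOCAL_UTC_OFFSET_H) -> pd.DataFrame:
    """Daily activity per individual: the sum of the hourly counts over each
    local civil day, with the number of observed hours as bookkeeping.

    Input must already be accuracy-filtered. Dates with no fixes are absent.
    """
    if fixes.empty:
        return pd.DataFrame(columns=["individual_id", "date", "activity", "hours_observed"])
    df = fixes.loc[:, ["individual_id", "timestamp", "exercise_volume"]].copy()
    df["date"] = local_date(df["timestamp"], utc_offset_h)
    df["hour"] = pd.DatetimeIndex(pd.to_datetime(df["timestamp"], utc=True)).floor("h")
    out = (
        df.groupby(["individual_id", "date"], sort=True)
        .agg(activity=("exercise_volume", "sum"), hours_observed=("hour", "nunique"))
        .reset_index()
    )
    out["activity"] = out["activity"].astype(np.int64)
    out["hours_observed"] = out["hours_observed"].astype(np.int64)
    return out


class ActivityWindowError(ValueError):
    """No qualifying day in the requested ActAvg window."""


def activity_average(daily: pd.DataFrame, window, min_hours: int = MIN_HOURS_PER_DAY) -> float:
    """ActAvg: arithmetic mean of daily activity over a date window.

    ``window`` is a (start_date, end_date) pair, inclusive of the start and
    exclusive of the end. Days with fewer than ``min_hours`` observed hours
    are excluded to avoid downward bias from partial days.
    """
    start, end = (pd.Timestamp(w).date() for w in window)
    if end <= start:
        raise ValueError("empty ActAvg window")
    sel = daily[
        (daily["date"] >= start) & (daily["date"] < end) & (daily["hours_observed"] >= min_hours)
    ]
    if sel.empty:
        who = daily["individual_id"].iloc[0] if len(daily) else "<unknown>"
        raise ActivityWindowError(f"no day with >= {min_hours} observed hours in window for {who}")
    return float(sel["activity"].mean())
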