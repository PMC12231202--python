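"""First northward migration departure, StayDur, and pre-departure weather.

The departure detector is a rule the package defines (a net-displacement
threshold sustained without return, with a northward requirement): an
individual departs on the first date at which its great-circle displacement
from the wintering-region centroid exceeds ``min_displacement_km``, its
latitude has increased relative to the centroid, and the excursion is
sustained for at least ``min_sustain_h`` without the displacement dropping
back below the threshold.

StayDur is the number of whole days between release and that departure; for
individuals that die or are censored before migrating it is the days to fate
end, flagged as non-migrant.

The 14-day pre-departure weather covariates are per-variable arithmetic means
of the station daily values over the two weeks preceding the departure date
(missing station days skipped per variable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

from ._geo import haversine_m
from .activity import LOCAL_UTC_OFFSET_H, local_date
from .telemetry_io import WEATHER_VARS


@dataclass
class DepartureParams:
    min_displacement_km: float = 50.0
    min_sustain_h: float = 48.0
    ref_hours: float = 72.0  # fixes used to anchor the wintering-region centroid


@dataclass
class DepartureCall:
    individual_id: str
    departure_date: _date | None
    method_flags: dict = field(default_factory=dict)
    window_end: _date | None = None  # date anchoring the 14-day weather window


def detect_departure(fixes: pd.DataFrame, params: DepartureParams | None = None) -> DepartureCall:
    """Call the first northward migration departure from a filtered track.

    Fixes are sorted internally, so the call is invariant to input order.
    Returns a call with ``departure_date=None`` (and a diagnostic flag) for
    stationary tracks or tracks spanning < 24 h.
    """
    params = params or DepartureParams()
    ind = str(fixes["individual_id"].iloc[0]) if len(fixes) else "<empty>"
    if fixes.empty:
        return DepartureCall(ind, None, {"insufficient_data": True})
    f = fixes.sort_values("timestamp").reset_index(drop=True)
    ts = pd.DatetimeIndex(pd.to_datetime(f["timestamp"], utc=True))
    if (ts[-1] - ts[0]) < pd.Timedelta(hours=24):
        return DepartureCall(ind, None, {"insufficient_data": True})

    ref = ts[0] + pd.Timedelta(hours=params.ref_hours)
    ref_mask = ts <= ref
    lon0 = float(f.loc[ref_mask, "longitude"].mean())
    lat0 = float(f.loc[ref_mask, "latitude"].mean())
    dist_km = haversine_m(lon0, lat0, f["longitude"].to_numpy(), f["latitude"].to_numpy()) / 1000.0
    lat = f["latitude"].to_numpy()

    out_mask = (dist_km >= params.min_displacement_km) & (lat > lat0)
    sustain = pd.Timedelta(hours=params.min_sustain_h)
    candidates = np.flatnonzero(out_mask)
    for i in candidates:
        t0 = ts[i]
        win = np.flatnonzero((ts >= t0) & (ts <= t0 + sustain))
        if ts[win[-1]] - t0 < sustain:
            continue  # track ends before the excursion can be confirmed
        if (dist_km[win] >= params.min_displacement_km).all() and lat[win[-1]] > lat[win[0]]:
            dep = local_date([t0], LOCAL_UTC_OFFSET_H)[0]
            return DepartureCall(
                ind,
                dep,
                {"displacement_km": float(dist_km[i]), "ref_lon": lon0, "ref_lat": lat0},
                window_end=dep,
            )
    return DepartureCall(ind, None, {"no_sustained_departure": True})


@dataclass
class StayDuration:
    days: int
    migrated: bool


def stay_duration(release_timestamp, call: DepartureCall, fate_end_date: _date | None = None) -> StayDuration:
    """Whole days from release to migration onset (StayDur).

    Non-migrants get days from release to fate end (death/censor), flagged.
    """
    release_date = local_date([pd.Timestamp(release_timestamp)], LOCAL_UTC_OFFSET_H)[0]
    if call.departure_date is not None:
        days = (call.departure_date - release_date).days
        migrated = True
    else:
        if fate_end_date is None:
            raise ValueError("non-migrant StayDur requires a fate end date")
        days = (fate_end_date - release_date).days
        migrated = False
    if days < 0:
        raise ValueError(f"negative stay duration for {call.individual_id}")
    return StayDuration(days=int(days), migrated=migrated)


def premigration_weather(weather: pd.DataFrame, window_end, span_days: int = 14) -> pd.Series:
    """Per-variable means over the ``span_days`` days preceding ``window_end``.

    The window is [window_end - span_days, window_end), i.e. the departure
    date itself is excluded. Missing station days are skipped per variable; a
    variable missing on every day of the window yields NaN (flagged by the
    caller).
    """
    end = pd.Timestamp(window_end).normalize()
    start = end - pd.Timedelta(days=span_days)
    dates = pd.to_datetime(weather["date"])
    sel = weather[(dates >= start) & (dates < end)]
    if sel.empty:
        return pd.Series({v: np.nan for v in WEATHER_VARS}, dtype=float)
    return sel[list(WEATHER_VARS)].mean(skipna=True)
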