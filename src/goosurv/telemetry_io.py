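"""Readers, writers and QC filters for the three pipeline input tables.

The canonical on-disk formats are plain CSV:

* **fix tables** — one row per hourly GPS record with the tracker's ten
  variables plus an individual id;
* **weather tables** — one row per station-day in NCEI/GSOD style, with the
  dialect's sentinel codes mapped to missing values on read;
* **metadata tables** — one row per released individual.

All timestamps are ISO-8601 UTC.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """An input table is missing columns or contains unparseable values."""


#: GPS positioning-accuracy classes, best to worst, plus the no-fix code.
ACCURACY_LEVELS = ("A", "B", "C", "D", "E", "invalid")
#: Nominal positional error bound per class (metres); 'invalid' has no position.
ACCURACY_BOUND_M = {"A": 5.0, "B": 10.0, "C": 20.0, "D": 100.0, "E": 2000.0, "invalid": float("nan")}
_ACCURACY_RANK = {lvl: i for i, lvl in enumerate(ACCURACY_LEVELS)}

#: The ten tracker variables, in canonical column order, keyed by individual.
FIX_COLUMNS = (
    "individual_id",
    "timestamp",
    "longitude",
    "latitude",
    "speed",
    "heading",
    "altitude",
    "exercise_volume",
    "device_temp",
    "voltage",
    "accuracy",
)

WEATHER_VARS = ("TEMP", "DEWP", "SLP", "STP", "VISIB", "WDSP", "MXSPD", "MAX", "MIN", "PRCP")

#: GSOD-dialect sentinel codes for missing values, configurable per deployment.
GSOD_SENTINELS = {
    "TEMP": 9999.9,
    "DEWP": 9999.9,
    "SLP": 9999.9,
    "STP": 9999.9,
    "VISIB": 999.9,
    "WDSP": 999.9,
    "MXSPD": 999.9,
    "MAX": 9999.9,
    "MIN": 9999.9,
    "PRCP": 99.99,
}

META_COLUMNS = (
    "individual_id",
    "species",
    "release_site",
    "source",
    "tracker",
    "release_year",
    "release_timestamp",
    "weight",
)


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def _parse_timestamps(raw: pd.Series, what: str) -> pd.Series:
    ts = pd.to_datetime(raw, utc=True, format="ISO8601", errors="coerce")
    if ts.isna().any():
        bad = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise SchemaError(f"{what}: unparseable timestamp {raw.iloc[bad]!r} at row {bad}")
    return ts


def read_fixes(path) -> pd.DataFrame:
    """Read a fix CSV into a typed, per-individual time-sorted DataFrame.

    Duplicate (individual, timestamp) rows are collapsed keeping the best
    accuracy class (ties broken by original file order).
    """
    df = pd.read_csv(path)
    _require_columns(df, FIX_COLUMNS, "fix table")
    df = df.loc[:, list(FIX_COLUMNS)].copy()
    df["timestamp"] = _parse_timestamps(df["timestamp"], "fix table")
    bad_acc = ~df["accuracy"].isin(ACCURACY_LEVELS)
    if bad_acc.any():
        raise SchemaError(f"fix table: unknown accuracy class {df.loc[bad_acc, 'accuracy'].iloc[0]!r}")
    for col in ("longitude", "latitude", "speed", "heading", "altitude", "device_temp", "voltage"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    df["exercise_volume"] = pd.to_numeric(df["exercise_volume"], errors="raise").astype(np.int64)
    if (df["exercise_volume"] < 0).any():
        raise SchemaError("fix table: negative exercise_volume")
    if (df["latitude"].abs() > 90).any() or (df["longitude"].abs() > 180).any():
        raise SchemaError("fix table: coordinates outside WGS84 bounds")
    df["individual_id"] = df["individual_id"].astype(str)
    # Stable sort so the original ingestion order breaks accuracy-rank ties.
    df["_rank"] = df["accuracy"].map(_ACCURACY_RANK)
    df = df.sort_values(["individual_id", "timestamp", "_rank"], kind="stable")
    df = df.drop_duplicates(subset=["individual_id", "timestamp"], keep="first")
    return df.drop(columns="_rank").reset_index(drop=True)


def write_fixes(df: pd.DataFrame, path) -> None:
    """Write fixes in the canonical dialect read back by :func:`read_fixes`."""
    out = df.loc[:, list(FIX_COLUMNS)].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False, float_format="%.6f")


def filter_accuracy(fixes: pd.DataFrame, keep=("A", "B", "C")) -> pd.DataFrame:
    """Retain only fixes in the given accuracy classes (A-C by default).

    Idempotent; an empty result is allowed (logged as a warning).
    """
    out = fixes[fixes["accuracy"].isin(keep)].reset_index(drop=True)
    log.info("accuracy filter: retained %d of %d fixes", len(out), len(fixes))
    if len(fixes) and not len(out):
        log.warning("accuracy filter removed every fix")
    return out


def read_weather(path, sentinels: dict | None = None) -> pd.DataFrame:
    """Read a GSOD-style daily weather CSV.

    Sentinel codes are mapped to missing values; dates are sorted; duplicate
    dates are a hard error; interior gap dates are reported in
    ``df.attrs['gap_dates']``.
    """
    sentinels = GSOD_SENTINELS if sentinels is None else sentinels
    df = pd.read_csv(path)
    _require_columns(df, ("date",) + WEATHER_VARS, "weather table")
    df = df.loc[:, ["date", *WEATHER_VARS]].copy()
    df["date"] = pd.to_datetime(df["date"], errors="coerce")
    if df["date"].isna().any():
        raise SchemaError("weather table: unparseable date")
    if df["date"].duplicated().any():
        dup = df.loc[df["date"].duplicated(), "date"].iloc[0]
        raise SchemaError(f"weather table: duplicate date {dup.date()}")
    for var in WEATHER_VARS:
        col = pd.to_numeric(df[var], errors="raise").astype(float)
        code = sentinels.get(var)
        if code is not None:
            col = col.mask(np.isclose(col, code))
        df[var] = col
    df = df.sort_values("date").reset_index(drop=True)
    full = pd.date_range(df["date"].iloc[0], df["date"].iloc[-1], freq="D")
    gaps = full.difference(pd.DatetimeIndex(df["date"]))
    df.attrs["gap_dates"] = [d.date() for d in gaps]
    if len(gaps):
        log.warning("weather table has %d gap date(s)", len(gaps))
    bad = df[["MIN", "TEMP", "MAX"]].notna().all(axis=1) & ~(
        (df["MIN"] <= df["TEMP"]) & (df["TEMP"] <= df["MAX"])
    )
    if bad.any():
        log.warning("weather table: %d day(s) violate MIN <= TEMP <= MAX", int(bad.sum()))
    return df


def write_weather(df: pd.DataFrame, path) -> None:
    out = df.loc[:, ["date", *WEATHER_VARS]].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.2f")


def read_meta(path) -> pd.DataFrame:
    """Read the individual metadata table (release design attributes)."""
    df = pd.read_csv(path)
    _require_columns(df, META_COLUMNS, "metadata table")
    df = df.loc[:, list(META_COLUMNS)].copy()
    df["individual_id"] = df["individual_id"].astype(str)
    df["release_timestamp"] = _parse_timestamps(df["release_timestamp"], "metadata table")
    df["weight"] = pd.to_numeric(df["weight"], errors="raise")
    if (df["weight"] <= 0).any():
        raise SchemaError("metadata table: non-positive weight")
    df["release_year"] = pd.to_numeric(df["release_year"], errors="raise").astype(np.int64)
    return df.reset_index(drop=True)


def write_meta(df: pd.DataFrame, path) -> None:
    out = df.loc[:, list(META_COLUMNS)].copy()
    out["release_timestamp"] = pd.to_datetime(out["release_timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, index=False, float_format="%.3f")
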