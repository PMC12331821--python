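"""Reading sonde and meteorological files; station metadata; tidy outputs.

Timestamps are stored internally in UTC.  The station ``utc_offset`` is
applied only when solar geometry or display needs local time, which keeps
deployments that span daylight-saving transitions unambiguous.

Sonde CSV dialect (header required)::

    timestamp,temp_c,[cond_ms_cm|sal_psu],[pressure_dbar|depth_m],[do_mg_l|do_mmol_m3]

Meteorology is either the NDBC standard meteorological text format
(``#YY MM DD hh mm WDIR WSPD ... PRES ...``, UTC) or a simple CSV
``timestamp,wspd_ms,pres_hpa``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .seawater import O2_MOLAR_MASS

logger = logging.getLogger(__name__)

__all__ = [
    "StationMeta",
    "read_sonde",
    "read_met_csv",
    "read_ndbc_met",
    "write_daily_rates",
    "read_daily_rates",
    "load_config",
    "mg_per_l_to_mmol_per_m3",
]

#: NDBC missing-value sentinels, matched per column after float parsing
_NDBC_SENTINELS = (99.0, 999.0, 9999.0, 99.00, 999.0)


def mg_per_l_to_mmol_per_m3(value):
    """Convert dissolved oxygen from mg L^-1 to mmol m^-3 (M_O2 = 31.998)."""
    return np.asarray(value, dtype=float) * 1000.0 / O2_MOLAR_MASS


@dataclass(frozen=True)
class StationMeta:
    """Fixed per-station configuration.

    Parameters
    ----------
    station_id : short identifier, e.g. ``"BB2"``
    latitude : decimal degrees, +N; must satisfy |lat| < 66.5
    longitude : decimal degrees, +E (study-region sites are negative)
    utc_offset : station clock hours relative to UTC
    sensor_height_offset : m the sensor sits above the bottom, added to the
        measured depth (default 0.30)
    hobo_atm_pressure : hPa subtracted from fixed-reference absolute
        pressure readings before conversion to depth (default 1010)
    anemometer_height : m; when given, winds are log-profile corrected to
        10 m, otherwise treated as already 10-m referenced
    """

    station_id: str
    latitude: float
    longitude: float
    utc_offset: float
    sensor_height_offset: float = 0.30
    hobo_atm_pressure: float = 1010.0
    anemometer_height: Optional[float] = None

    def __post_init__(self):
        if abs(self.latitude) >= 66.5:
            raise ValueError("latitude must satisfy |lat| < 66.5 degrees")
        if not -12.0 <= self.utc_offset <= 14.0:
            raise ValueError("utc_offset must be in [-12, +14] hours")
        if self.sensor_height_offset < 0:
            raise ValueError("sensor_height_offset must be >= 0")


def _parse_timestamps(raw: pd.Series, utc_offset: float, path) -> pd.Series:
    ts = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    bad = ts.isna() & raw.notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header + 1-based
        raise ValueError(f"{path}: unparseable timestamp at line {line}: "
                         f"{raw[bad].iloc[0]!r}")
    if ts.dt.tz is None:
        # naive stamps are station-local clock time
        ts = ts - pd.Timedelta(hours=utc_offset)
        ts = ts.dt.tz_localize("UTC")
    else:
        ts = ts.dt.tz_convert("UTC")
    return ts


def _dedupe_sorted(df: pd.DataFrame, path) -> pd.DataFrame:
    df = df.sort_values("timestamp", kind="stable")
    dup = df["timestamp"].duplicated(keep="first")
    if dup.any():
        logger.warning("%s: dropped %d duplicate timestamps (kept first)",
                       path, int(dup.sum()))
        df = df[~dup]
    return df.reset_index(drop=True)


def read_sonde(path, meta: StationMeta) -> pd.DataFrame:
    """Read a sonde CSV into a tidy frame of instrument observations.

    Returns columns ``timestamp`` (UTC), ``temperature`` (degC) and
    whichever of ``conductivity`` (mS cm^-1), ``salinity`` (PSU),
    ``pressure`` (dbar), ``depth`` (m), ``oxygen`` (mmol m^-3, converted
    from mg L^-1 when the file declares ``do_mg_l``) are present.  Rows are
    time-sorted with duplicate timestamps dropped (first kept).
    """
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("%s: empty sonde file", path)
        return pd.DataFrame(columns=["timestamp", "temperature", "oxygen"])
    cols = set(df.columns)
    if "timestamp" not in cols or "temp_c" not in cols:
        raise ValueError(f"{path}: sonde CSV needs 'timestamp' and 'temp_c' columns")
    if not ({"do_mg_l", "do_mmol_m3"} & cols):
        raise ValueError(f"{path}: sonde CSV needs a 'do_mg_l' or 'do_mmol_m3' column")

    out = pd.DataFrame({
        "timestamp": _parse_timestamps(df["timestamp"], meta.utc_offset, path),
        "temperature": df["temp_c"].astype(float),
    })
    if "do_mmol_m3" in cols:
        out["oxygen"] = df["do_mmol_m3"].astype(float)
    else:
        out["oxygen"] = mg_per_l_to_mmol_per_m3(df["do_mg_l"].astype(float))
    for src, dst in [("cond_ms_cm", "conductivity"), ("sal_psu", "salinity"),
                     ("pressure_dbar", "pressure"), ("depth_m", "depth")]:
        if src in cols:
            out[dst] = df[src].astype(float)

    bad_t = ~out["temperature"].between(-2.0, 45.0)
    if bad_t.any():
        logger.warning("%s: %d temperature values outside [-2, 45] degC set "
                       "missing", path, int(bad_t.sum()))
        out.loc[bad_t, "temperature"] = np.nan
    out.loc[out["oxygen"] < 0, "oxygen"] = np.nan
    return _dedupe_sorted(out, path)


def read_met_csv(path, utc_offset: float = 0.0) -> pd.DataFrame:
    """Read the simple met CSV dialect: ``timestamp,wspd_ms,pres_hpa``."""
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("%s: empty met file", path)
        return pd.DataFrame(columns=["timestamp", "wind_speed", "baro_pressure"])
    for col in ("timestamp", "wspd_ms", "pres_hpa"):
        if col not in df.columns:
            raise ValueError(f"{path}: met CSV missing column {col!r}")
    out = pd.DataFrame({
        "timestamp": _parse_timestamps(df["timestamp"], utc_offset, path),
        "wind_speed": df["wspd_ms"].astype(float),
        "baro_pressure": df["pres_hpa"].astype(float),
    })
    out.loc[out["wind_speed"] < 0, "wind_speed"] = np.nan
    out.loc[~out["baro_pressure"].between(850.0, 1100.0), "baro_pressure"] = np.nan
    return _dedupe_sorted(out, path)


def read_ndbc_met(path) -> pd.DataFrame:
    """Read an NDBC standard meteorological text file.

    Timestamps in these files are UTC.  Missing-value sentinels (99.0,
    999.0, 9999.0) become NaN.  Requires WSPD and PRES columns; other
    columns are ignored.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ValueError(f"{path}: not an NDBC file (no '#YY ...' header)")
    names = header.lstrip("#").split()
    df = pd.read_csv(path, sep=r"\s+", comment="#", names=names, header=None)
    if df.empty:
        logger.warning("%s: empty NDBC file", path)
        return pd.DataFrame(columns=["timestamp", "wind_speed", "baro_pressure"])

    for col in ("WSPD", "PRES"):
        if col not in names:
            raise ValueError(f"{path}: NDBC file missing {col} column")
    year_col = "YY" if "YY" in names else "YYYY"
    year = df[year_col].astype(int)
    year = year.where(year > 100, year + 2000)
    minute = df["mm"].astype(int) if "mm" in names else 0
    ts = pd.to_datetime(dict(year=year, month=df["MM"].astype(int),
                             day=df["DD"].astype(int), hour=df["hh"].astype(int),
                             minute=minute), utc=True)

    def clean(col, sentinels):
        v = df[col].astype(float)
        return v.where(~v.isin(sentinels))

    out = pd.DataFrame({
        "timestamp": ts,
        "wind_speed": clean("WSPD", [99.0]),
        "baro_pressure": clean("PRES", [999.0, 9999.0]),
    })
    return _dedupe_sorted(out, path)


_RATE_COLUMNS = ["station", "date", "gpp", "er", "nep", "anomalous_gpp",
                 "anomalous_er", "n_day", "n_night"]


def write_daily_rates(rates: pd.DataFrame, path) -> None:
    """Write per-metabolic-day rates to CSV, one row per day.

    Numeric values use repr-precision floats so a read-back round-trips
    losslessly.
    """
    if rates.empty:
        raise ValueError("no daily rates to write")
    cols = [c for c in _RATE_COLUMNS if c in rates.columns]
    cols += [c for c in rates.columns if c not in cols]
    rates[cols].to_csv(path, index=False, float_format="%.12g")


def read_daily_rates(path) -> pd.DataFrame:
    """Read back a daily-rates CSV produced by :func:`write_daily_rates`."""
    df = pd.read_csv(path, parse_dates=["date"])
    for flag in ("anomalous_gpp", "anomalous_er"):
        if flag in df.columns:
            df[flag] = df[flag].astype(bool)
    return df


def load_config(path) -> dict:
    """Load a YAML run configuration.

    Expected layout::

        stations:
          - station_id: BB2
            latitude: 25.614028
            longitude: -80.241806
            utc_offset: -5
            sensor_height_offset: 0.30
            sonde: path/to/sonde.csv
            met: path/to/met.txt          # NDBC or CSV by extension

    Returns a dict with key ``stations`` mapping to a list of
    ``(StationMeta, {"sonde": ..., "met": ...})`` pairs.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not raw or "stations" not in raw:
        raise ValueError(f"{path}: config must contain a 'stations' list")
    stations = []
    meta_fields = {"station_id", "latitude", "longitude", "utc_offset",
                   "sensor_height_offset", "hobo_atm_pressure",
                   "anemometer_height"}
    for entry in raw["stations"]:
        meta = StationMeta(**{k: v for k, v in entry.items() if k in meta_fields})
        files = {k: v for k, v in entry.items() if k not in meta_fields}
        stations.append((meta, files))
    return {"stations": stations}
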