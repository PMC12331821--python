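"""Open-water diel oxygen metabolism estimator.

The estimator inverts the well-mixed oxygen mass balance

    H d[O2]/dt = GPP - ER + F,        F = k_w ([O2]sat - [O2])

per *metabolic day* (sunrise to next sunrise).  All inputs are averaged
into clock-aligned 30-min blocks first, which damps sensor noise and
short-term fluctuations around sunrise and sunset.  Ecosystem respiration
comes from the nighttime budget assuming zero GPP; GPP comes from the
daytime budget assuming the night's respiration rate also applies in
daylight; NEP = GPP - ER by construction.  Lateral advection is not
modelled: transport errors are assumed mean-zero over a deployment.

The module exposes the individual pipeline steps as functions and wraps
the whole fit in a model/results pair:

>>> model = OpenWaterMetabolism.from_records(sonde, met, station)
>>> res = model.fit()
>>> res.daily                     # per-metabolic-day GPP, ER, NEP
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import seawater
from .io_station import StationMeta
from .solar import MetabolicDay, assign_metabolic_days

__all__ = [
    "block_average",
    "correct_depth",
    "airsea_flux",
    "instantaneous_nep",
    "daily_rates",
    "stratification_check",
    "diel_range",
    "OpenWaterMetabolism",
    "MetabolismResults",
]

BLOCK = pd.Timedelta(minutes=30)

#: per-day time conversion used throughout (rates are areal, per day)
MIN_PER_DAY = 1440.0


# ---------------------------------------------------------------------------
# pipeline steps
# ---------------------------------------------------------------------------

def block_average(records: pd.DataFrame, width: str = "30min") -> pd.DataFrame:
    """Average observations into clock-aligned blocks.

    Each numeric column is averaged over all observations whose timestamps
    fall in ``[hh:00, hh:30)`` etc.; the returned frame is indexed by the
    block *midpoint*.  Blocks without observations are NaN rows (the grid
    is contiguous from first to last occupied block).
    """
    if records.empty:
        return pd.DataFrame()
    df = records.set_index("timestamp") if "timestamp" in records else records
    out = df.resample(width, label="left", closed="left").mean()
    out.index = out.index + pd.Timedelta(width) / 2
    out.index.name = "t"
    return out


def correct_depth(depth, offset: float):
    """Add the sensor-height-above-bottom offset to measured depth.

    Depths that remain non-positive after correction are unusable and
    become NaN.
    """
    if offset < 0:
        raise ValueError("sensor height offset must be >= 0")
    h = np.asarray(depth, dtype=float) + offset
    out = np.where(h > 0, h, np.nan)
    return float(out) if out.ndim == 0 else out


def airsea_flux(kw, o2_sat, o2):
    """Air-sea oxygen flux F = k_w ([O2]sat - [O2]), mmol m^-2 d^-1.

    Positive flux is invasion (into the water).  Any missing input makes
    the flux missing, which later excludes the interval from budgets.
    """
    return np.asarray(kw, float) * (np.asarray(o2_sat, float) - np.asarray(o2, float))


def instantaneous_nep(series: pd.DataFrame) -> pd.Series:
    """Per-interval biological rate GPP - ER, mmol O2 m^-2 d^-1.

    For each pair of consecutive 30-min blocks the oxygen tendency is
    converted to an areal rate and the air-sea flux removed:

        rate = Hbar * d[O2]/dt - Fbar

    with ``Hbar`` and ``Fbar`` the means of the bounding blocks and the
    rate assigned to the *later* block.  At most one missing block may be
    bridged; longer gaps break the difference chain.
    """
    need = {"oxygen", "depth", "flux"}
    missing = need - set(series.columns)
    if missing:
        raise ValueError(f"series lacks columns {sorted(missing)}")

    t = series.index
    o2 = series["oxygen"].to_numpy(float)
    h = series["depth"].to_numpy(float)
    f = series["flux"].to_numpy(float)

    rate = np.full(len(series), np.nan)
    if len(series) >= 2:
        dt_days = (t[1:] - t[:-1]).total_seconds() / 86400.0
        do2 = o2[1:] - o2[:-1]
        hbar = 0.5 * (h[1:] + h[:-1])
        fbar = 0.5 * (f[1:] + f[:-1])
        ok = dt_days <= (2 * BLOCK).total_seconds() / 86400.0 + 1e-9
        r = np.where(ok, hbar * do2 / dt_days - fbar, np.nan)
        rate[1:] = r
    return pd.Series(rate, index=t, name="inst_nep")


def daily_rates(day: MetabolicDay, rates: pd.Series) -> Optional[dict]:
    """Evaluate the day/night oxygen budgets for one metabolic day.

    ER is minus the mean nighttime rate extrapolated to 24 h (so it is
    already an areal daily rate); GPP corrects the mean daytime rate for
    that respiration and scales by the photoperiod fraction:

        ER  = -mean(night rates)
        GPP = (mean(day rates) + ER) * daylight_hours / 24
        NEP = GPP - ER

    Negative GPP or ER are physically anomalous; they are flagged, kept,
    and enter any later averaging.  Returns None when no usable night (or
    day) intervals exist.
    """
    vals = rates.to_numpy(float)
    day_r = vals[day.day_intervals]
    night_r = vals[day.night_intervals]
    day_r = day_r[~np.isnan(day_r)]
    night_r = night_r[~np.isnan(night_r)]
    if len(night_r) == 0 or len(day_r) == 0:
        return None

    er = -float(np.mean(night_r))
    gpp = (float(np.mean(day_r)) + er) * (day.daylight_hours / 24.0)
    nep = gpp - er
    return {
        "metabolic_day": day.index,
        "date": pd.Timestamp(day.date),
        "gpp": gpp,
        "er": er,
        "nep": nep,
        "anomalous_gpp": gpp < 0,
        "anomalous_er": er < 0,
        "n_day": int(len(day_r)),
        "n_night": int(len(night_r)),
        "daylight_hours": day.daylight_hours,
    }


def stratification_check(profile_o2: Sequence[float]) -> Optional[float]:
    """Sample standard deviation of a vertical O2 profile, mmol m^-3.

    Used to judge the well-mixed assumption: the profile spread should be
    small against the diel range (compare :func:`diel_range`).  A single
    point carries no spread information (returns None).
    """
    v = np.asarray(profile_o2, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        return None
    return float(np.std(v, ddof=1))


def diel_range(series: pd.DataFrame, days: Sequence[MetabolicDay]) -> float:
    """Mean over metabolic days of the daily O2 range (max - min)."""
    o2 = series["oxygen"].to_numpy(float)
    ranges = []
    for d in days:
        idx = np.concatenate([d.day_intervals, d.night_intervals])
        v = o2[idx]
        v = v[~np.isnan(v)]
        if len(v):
            ranges.append(v.max() - v.min())
    return float(np.mean(ranges)) if ranges else np.nan


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class OpenWaterMetabolism:
    """Diel-oxygen metabolism model for one station deployment.

    Parameters
    ----------
    series : DataFrame indexed by UTC 30-min block midpoints with columns
        ``temperature, salinity, depth, oxygen, wind_speed, baro_pressure``
        (depth already sensor-corrected).  Use :meth:`from_records` to
        build it from raw instrument observations.
    station : StationMeta

    Notes
    -----
    Construction derives the physics columns (``o2_sat``, ``kw``, ``flux``,
    ``o2_excess``); :meth:`fit` segments metabolic days and evaluates the
    budgets.
    """

    def __init__(self, series: pd.DataFrame, station: StationMeta):
        self.station = station
        self.series = self._derive_physics(series.copy())

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_records(cls, sonde: pd.DataFrame, met: pd.DataFrame,
                     station: StationMeta) -> "OpenWaterMetabolism":
        """Build the model from raw sonde and met observation frames.

        Both inputs are block-averaged to the same clock-aligned 30-min
        grid (no observation ever crosses a block boundary), salinity is
        derived from conductivity and depth from absolute pressure where
        needed, the sensor height offset is applied, and winds are
        referenced to 10 m.
        """
        s30 = block_average(sonde)
        m30 = block_average(met)

        if "salinity" not in s30.columns:
            if "conductivity" not in s30.columns:
                raise ValueError(
                    "metabolism blocked: no salinity or conductivity recorded")
            p = s30["pressure"] if "pressure" in s30.columns else 0.0
            s30["salinity"] = seawater.practical_salinity(
                s30["conductivity"], s30["temperature"], p)
        bad_s = ~s30["salinity"].between(0.0, 50.0)
        s30.loc[bad_s, "salinity"] = np.nan

        if "depth" not in s30.columns:
            if "pressure" not in s30.columns:
                raise ValueError("metabolism blocked: no depth or pressure recorded")
            s30["depth"] = seawater.depth_from_pressure(
                s30["pressure"], station.hobo_atm_pressure,
                s30["salinity"], s30["temperature"])
        s30["depth"] = correct_depth(s30["depth"], station.sensor_height_offset)

        m30 = m30.reindex(s30.index)
        s30["wind_speed"] = seawater.wind_at_10m(
            m30["wind_speed"], station.anemometer_height)
        s30["baro_pressure"] = m30["baro_pressure"]
        return cls(s30, station)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, station: StationMeta,
                       ) -> "OpenWaterMetabolism":
        """Build from an already-merged frame with a ``timestamp`` column."""
        df = data.set_index("timestamp") if "timestamp" in data else data
        return cls(df, station)

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _derive_physics(df: pd.DataFrame) -> pd.DataFrame:
        df["o2_sat"] = seawater.oxygen_saturation(
            df["temperature"], df["salinity"], df["baro_pressure"])
        df["kw"] = seawater.gas_transfer_velocity(
            df["wind_speed"], df["temperature"], df["salinity"])
        df["flux"] = airsea_flux(df["kw"], df["o2_sat"], df["oxygen"])
        df["o2_excess"] = df["oxygen"] - df["o2_sat"]
        return df

    # -- fitting -----------------------------------------------------------

    def fit(self, completeness: float = 0.8) -> "MetabolismResults":
        """Segment metabolic days and evaluate the daily oxygen budgets.

        Parameters
        ----------
        completeness : minimum present fraction of both day and night
            intervals for a metabolic day to produce rates.
        """
        days = assign_metabolic_days(
            self.series.index, self.station.latitude, self.station.longitude,
            self.station.utc_offset, completeness=completeness)
        inst = instantaneous_nep(self.series)
        rows = []
        for d in days:
            row = daily_rates(d, inst)
            if row is not None:
                row["station"] = self.station.station_id
                rows.append(row)
        cols = ["station", "metabolic_day", "date", "gpp", "er", "nep",
                "anomalous_gpp", "anomalous_er", "n_day", "n_night",
                "daylight_hours"]
        daily = pd.DataFrame(rows, columns=cols)
        return MetabolismResults(self, daily, days, inst)


@dataclass
class MetabolismResults:
    """Fit output: per-metabolic-day rates plus diagnostics.

    Attributes
    ----------
    daily : DataFrame, one row per complete metabolic day with ``gpp``,
        ``er``, ``nep`` (mmol O2 m^-2 d^-1), anomaly flags and interval
        counts
    days : the MetabolicDay windows used
    instantaneous : per-interval biological rate series (diagnostic)
    """

    model: OpenWaterMetabolism
    daily: pd.DataFrame
    days: list = field(default_factory=list)
    instantaneous: Optional[pd.Series] = None

    @property
    def n_days(self) -> int:
        return len(self.daily)

    def mean_rates(self) -> pd.Series:
        """Deployment means of GPP, ER, NEP over all metabolic days."""
        return self.daily[["gpp", "er", "nep"]].mean()

    def standard_errors(self) -> pd.Series:
        """SE of the deployment means: sd over days / sqrt(n_days)."""
        n = self.n_days
        sd = self.daily[["gpp", "er", "nep"]].std(ddof=1)
        return sd / np.sqrt(n) if n > 1 else sd * np.nan

    def diel_range(self) -> float:
        """Mean daily O2 range, mmol m^-3 (well-mixedness context)."""
        return diel_range(self.model.series, self.days)

    def diagnostics(self) -> pd.DataFrame:
        """Per-interval table: physics fields, instantaneous rate, labels."""
        df = self.model.series.copy()
        df["inst_nep"] = self.instantaneous
        df["metabolic_day"] = -1
        df["is_day"] = False
        for d in self.days:
            df.iloc[d.day_intervals, df.columns.get_loc("metabolic_day")] = d.index
            df.iloc[d.night_intervals, df.columns.get_loc("metabolic_day")] = d.index
            df.iloc[d.day_intervals, df.columns.get_loc("is_day")] = True
        return df

    def summary(self) -> str:
        """Plain-text deployment summary (means +/- 2 SE)."""
        from .reporting import to_carbon, annualize

        mean = self.mean_rates()
        se = self.standard_errors()
        n_anom = int(self.daily["anomalous_gpp"].sum()
                     + self.daily["anomalous_er"].sum())
        lines = [
            "Open-water diel oxygen metabolism",
            "=" * 49,
            f"Station:            {self.model.station.station_id}",
            f"Metabolic days:     {self.n_days}",
            f"Anomalous rates:    {n_anom}",
            f"Mean diel O2 range: {self.diel_range():8.1f} mmol m-3",
            "-" * 49,
            f"{'':6}{'mmol O2 m-2 d-1':>20}{'g C m-2 d-1':>14}",
        ]
        for k in ("gpp", "er", "nep"):
            pm = f"{mean[k]:8.1f} (+/- {2 * se[k]:5.1f})" if self.n_days > 1 \
                else f"{mean[k]:8.1f}  (n=1)     "
            lines.append(f"{k.upper():6}{pm:>20}{to_carbon(mean[k]):>14.2f}")
        lines.append("-" * 49)
        lines.append(
            f"Annual GPP: {annualize(to_carbon(mean['gpp'])):6.0f} g C m-2 y-1")
        return "\n".join(lines)
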