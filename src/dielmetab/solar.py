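"""Sunrise/sunset computation and metabolic-day segmentation.

A *metabolic day* is the window between sunrises on two adjacent calendar
days; the daily oxygen budget is integrated over it, with the daytime part
ending at sunset.  Sun times come from the standard NOAA solar-position
equations (zenith 90.833 deg: refraction plus the solar radius), accurate
to about a minute at mid latitudes — far finer than the 30-min series they
segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd

__all__ = ["MetabolicDay", "sun_times", "assign_metabolic_days", "SUN_ZENITH_DEG"]

#: zenith angle of the sun centre at rise/set, degrees
SUN_ZENITH_DEG = 90.833

#: maximum |latitude| supported (sun must rise and set every day)
MAX_LATITUDE = 66.5


@dataclass
class MetabolicDay:
    """One sunrise-to-sunrise window with day/night interval membership.

    ``day_intervals`` and ``night_intervals`` hold integer positions into
    the regular 30-min series this day was cut from; membership is decided
    by interval midpoint.
    """

    index: int
    start: pd.Timestamp           # sunrise, UTC
    sunset: pd.Timestamp          # UTC
    end: pd.Timestamp             # next sunrise, UTC
    day_intervals: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    night_intervals: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def daylight_hours(self) -> float:
        return (self.sunset - self.start).total_seconds() / 3600.0

    @property
    def date(self) -> date:
        """Calendar date of the starting sunrise (UTC)."""
        return self.start.date()


def _noaa_sun_hour_angles(latitude: float, longitude: float, day: date):
    """Return (sunrise_utc_minutes, sunset_utc_minutes) past UTC midnight.

    Standard NOAA general-solar-position algorithm: fractional year ->
    equation of time and declination -> hour angle at the rise/set zenith.
    """
    doy = day.timetuple().tm_yday
    # fractional year, radians (midday anchor)
    gamma = 2.0 * math.pi / 365.0 * (doy - 1 + 0.5)

    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )

    lat = math.radians(latitude)
    zen = math.radians(SUN_ZENITH_DEG)
    cos_ha = (math.cos(zen) - math.sin(lat) * math.sin(decl)) / (
        math.cos(lat) * math.cos(decl)
    )
    if not -1.0 < cos_ha < 1.0:
        raise ValueError(
            f"sun does not rise and set on {day} at latitude {latitude}"
        )
    ha_deg = math.degrees(math.acos(cos_ha))

    sunrise = 720.0 - 4.0 * (longitude + ha_deg) - eqtime
    sunset = 720.0 - 4.0 * (longitude - ha_deg) - eqtime
    return sunrise, sunset


def sun_times(latitude: float, longitude: float, day: date, utc_offset: float = 0.0):
    """Sunrise and sunset for the local calendar day.

    Parameters
    ----------
    latitude : decimal degrees, positive north; |lat| must be < 66.5
    longitude : decimal degrees, positive east (western hemisphere negative)
    day : the *local* calendar date
    utc_offset : hours of the station clock relative to UTC (e.g. -5)

    Returns
    -------
    (sunrise, sunset) : timezone-aware UTC ``pd.Timestamp`` pair, chosen so
    that the sunrise falls on the requested local date.
    """
    if abs(latitude) >= MAX_LATITUDE:
        raise ValueError(
            f"latitude {latitude} not supported: polar day/night possible"
        )
    rise_min, set_min = _noaa_sun_hour_angles(latitude, longitude, day)

    midnight_utc = datetime(day.year, day.month, day.day, tzinfo=timezone.utc)
    sunrise = midnight_utc + timedelta(minutes=rise_min)
    sunset = midnight_utc + timedelta(minutes=set_min)

    # shift whole solar day so the *local* sunrise lands on the requested date
    local_rise = sunrise + timedelta(hours=utc_offset)
    shift = (day - local_rise.date()).days
    if shift:
        delta = timedelta(days=shift)
        sunrise, sunset = sunrise + delta, sunset + delta
    return pd.Timestamp(sunrise), pd.Timestamp(sunset)


def assign_metabolic_days(times: pd.DatetimeIndex, latitude: float,
                          longitude: float, utc_offset: float = 0.0,
                          completeness: float = 0.8) -> list[MetabolicDay]:
    """Cut a regular 30-min series into complete metabolic days.

    Parameters
    ----------
    times : interval *midpoints* of the regular series, tz-aware UTC
    latitude, longitude, utc_offset : station geometry
    completeness : minimum fraction of expected day intervals AND night
        intervals that must be present for the day to be kept (days failing
        the threshold yield no rates)

    Returns
    -------
    list of :class:`MetabolicDay`, one per complete sunrise-to-sunrise
    window fully inside the series.  Empty (with no error) if the series is
    shorter than one window.
    """
    if len(times) == 0:
        return []
    if times.tz is None:
        raise ValueError("series timestamps must be timezone-aware (UTC)")

    t0, t1 = times[0], times[-1]
    local_first = (t0 + pd.Timedelta(hours=utc_offset)).date()
    local_last = (t1 + pd.Timedelta(hours=utc_offset)).date()

    dates = pd.date_range(local_first - pd.Timedelta(days=1),
                          local_last + pd.Timedelta(days=1), freq="D").date
    suns = [sun_times(latitude, longitude, d, utc_offset) for d in dates]

    days: list[MetabolicDay] = []
    idx = 0
    for k in range(len(suns) - 1):
        start, sunset = suns[k]
        end = suns[k + 1][0]
        if start < t0 or end > t1:
            continue  # partial leading/trailing window
        in_window = (times >= start) & (times < end)
        is_day = in_window & (times < sunset)
        is_night = in_window & (times >= sunset)

        n_day_expected = max(1, round((sunset - start) / pd.Timedelta(minutes=30)))
        n_night_expected = max(1, round((end - sunset) / pd.Timedelta(minutes=30)))
        day_idx = np.flatnonzero(is_day)
        night_idx = np.flatnonzero(is_night)
        if (len(day_idx) < completeness * n_day_expected
                or len(night_idx) < completeness * n_night_expected):
            continue
        days.append(MetabolicDay(index=idx, start=start, sunset=sunset, end=end,
                                 day_intervals=day_idx, night_intervals=night_idx))
        idx += 1
    return days
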