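"""Forward simulation of a sonde deployment with known metabolic truth.

The simulator integrates the same well-mixed oxygen mass balance the
estimator inverts,

    d[O2]/dt = (gpp(t) - er(t) + F(t)) / H(t) + advection,

by explicit Euler at the sampling interval.  Photosynthesis is a
half-sinusoid over daylight whose integral over each metabolic day equals
the prescribed daily GPP; respiration follows an optional Q10 temperature
response (Q10 = 1 keeps it constant).  Depth and salinity follow a
semidiurnal tidal harmonic, temperature a diel cycle peaking
mid-afternoon, wind an AR(1) process truncated at zero.  Two transport
error modes are available: a seeded Gaussian random walk in concentration
(mean-zero, the estimator's operating assumption) and a tidal-harmonic
mode for probing tidally correlated advection, the method's known failure
mode.  Observation noise is iid Gaussian on the emitted oxygen only.

Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd

from . import seawater
from .io_station import StationMeta
from .solar import sun_times

__all__ = ["SimulationConfig", "SimulatedTruth", "simulate_deployment",
           "truth_daily_integrals", "DEFAULT_STATION"]

#: a subtropical estuarine station (central-bay geometry, UTC-5 clock)
DEFAULT_STATION = StationMeta(
    station_id="SIM1", latitude=25.614028, longitude=-80.241806,
    utc_offset=-5.0, sensor_height_offset=0.30)


@dataclass(frozen=True)
class SimulationConfig:
    """Deployment scenario: prescribed rates, environment and noise.

    Rates are areal (mmol O2 m^-2 d^-1).  ``true_er_ref`` applies at
    ``temp_mean``; with ``q10`` = 1 respiration is constant.  Defaults
    describe a shallow subtropical deployment whose diel oxygen swing is
    of order 45 mmol m^-3.
    """

    station: StationMeta = DEFAULT_STATION
    start: date = date(2021, 6, 1)
    n_days: int = 10
    true_gpp: float = 200.0
    true_er_ref: float = 185.0
    q10: float = 1.0
    mean_depth: float = 2.5            # m
    tidal_amplitude: float = 0.5       # m
    tidal_period: float = 12.42        # h (principal lunar semidiurnal)
    temp_mean: float = 28.0            # degC
    temp_diel_amplitude: float = 1.5   # degC
    salinity_mean: float = 35.0        # PSU
    salinity_tidal_amplitude: float = 0.5
    wind_mean: float = 4.0             # m s^-1
    wind_ar1: float = 0.9
    wind_sd: float = 1.0               # AR(1) innovation s.d., m s^-1
    baro: float = 1015.0               # hPa
    advection_noise_sd: float = 0.0    # mmol m^-3 per step (random walk)
    advection_harmonic_amplitude: float = 0.0  # mmol m^-3 per step, tidal
    obs_noise_sd: float = 2.0          # mmol m^-3, iid on emitted O2
    o2_initial: float | None = None    # mmol m^-3; None = start at saturation
    sample_interval: float = 10.0      # min
    seed: int = 0

    def __post_init__(self):
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2")
        if self.mean_depth <= self.tidal_amplitude:
            raise ValueError("mean_depth must exceed tidal_amplitude")
        for name in ("tidal_amplitude", "temp_diel_amplitude",
                     "salinity_tidal_amplitude", "advection_noise_sd",
                     "advection_harmonic_amplitude", "obs_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.wind_ar1 < 1.0:
            raise ValueError("wind_ar1 must be in [0, 1)")

    def with_(self, **kw) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


@dataclass
class SimulatedTruth:
    """Prescribed per-interval rates paired with the generated series.

    ``gpp``, ``er``, ``flux`` are areal rates (mmol O2 m^-2 d^-1) on the
    simulation grid ``times``; ``o2`` is the noise-free state.  ``windows``
    holds the (sunrise, sunset, next-sunrise) triple per metabolic day
    fully covered by the simulation.
    """

    config: SimulationConfig
    times: pd.DatetimeIndex
    gpp: np.ndarray
    er: np.ndarray
    flux: np.ndarray
    o2: np.ndarray
    windows: list = field(default_factory=list)


def _daylight_shape(times_days: np.ndarray, rise: float, setting: float,
                    total: float) -> np.ndarray:
    """Half-sinusoid in [rise, setting] (times in fractional days since t0)
    integrating to ``total``."""
    L = setting - rise
    amp = total * np.pi / (2.0 * L)
    x = (times_days - rise) / L
    out = np.where((x >= 0) & (x <= 1), amp * np.sin(np.pi * np.clip(x, 0, 1)), 0.0)
    return out


def simulate_deployment(config: SimulationConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame, SimulatedTruth]:
    """Run the forward model.

    Returns
    -------
    sonde : DataFrame in the sonde observation layout (``timestamp`` UTC,
        ``temperature``, ``salinity``, ``depth`` (sensor-referenced, i.e.
        true depth minus the sensor height offset), ``oxygen`` with
        observation noise)
    met : DataFrame (``timestamp``, ``wind_speed``, ``baro_pressure``)
    truth : :class:`SimulatedTruth`

    Raises
    ------
    RuntimeError if the prescribed forcing drives oxygen negative.
    """
    cfg = config
    st = cfg.station
    rng = np.random.default_rng(cfg.seed)

    dt_min = cfg.sample_interval
    n = int(round(cfg.n_days * 1440.0 / dt_min))
    start_local = pd.Timestamp(cfg.start)
    start_utc = (start_local - pd.Timedelta(hours=st.utc_offset)).tz_localize("UTC")
    times = start_utc + pd.to_timedelta(np.arange(n) * dt_min, unit="min")
    t_days = np.arange(n) * dt_min / 1440.0  # fractional days since start

    # solar windows, expressed in fractional days since start_utc
    suns = [sun_times(st.latitude, st.longitude,
                      cfg.start + pd.Timedelta(days=k).to_pytimedelta(), st.utc_offset)
            for k in range(cfg.n_days + 1)]
    to_frac = lambda ts: (ts - start_utc).total_seconds() / 86400.0

    gpp_t = np.zeros(n)
    for rise_ts, set_ts in suns:
        rise, setting = to_frac(rise_ts), to_frac(set_ts)
        if setting < 0 or rise > t_days[-1]:
            continue
        gpp_t += _daylight_shape(t_days, rise, setting, cfg.true_gpp)

    # environmental harmonics
    h_local = ((times + pd.Timedelta(hours=st.utc_offset)).hour
               + (times + pd.Timedelta(hours=st.utc_offset)).minute / 60.0)
    temp = cfg.temp_mean + cfg.temp_diel_amplitude * np.sin(
        2 * np.pi * (h_local.to_numpy() - 9.0) / 24.0)  # peak 15:00 local
    tide_phase = 2 * np.pi * t_days * 24.0 / cfg.tidal_period
    depth = cfg.mean_depth + cfg.tidal_amplitude * np.sin(tide_phase)
    sal = cfg.salinity_mean + cfg.salinity_tidal_amplitude * np.sin(tide_phase)

    # AR(1) wind, stationary innovations, truncated at zero
    wind = np.empty(n)
    wind[0] = cfg.wind_mean
    innov = rng.standard_normal(n) * cfg.wind_sd * np.sqrt(1 - cfg.wind_ar1**2)
    for k in range(1, n):
        wind[k] = cfg.wind_mean + cfg.wind_ar1 * (wind[k - 1] - cfg.wind_mean) \
            + innov[k]
    np.clip(wind, 0.0, None, out=wind)

    er_t = cfg.true_er_ref * cfg.q10 ** ((temp - cfg.temp_mean) / 10.0)
    o2_sat = seawater.oxygen_saturation(temp, sal, cfg.baro)
    kw = seawater.gas_transfer_velocity(wind, temp, sal)

    adv = rng.standard_normal(n) * cfg.advection_noise_sd
    if cfg.advection_harmonic_amplitude > 0:
        adv = adv + cfg.advection_harmonic_amplitude * np.sin(tide_phase)

    dt_d = dt_min / 1440.0
    o2 = np.empty(n)
    flux = np.empty(n)
    o2[0] = float(np.asarray(o2_sat)[0]) if cfg.o2_initial is None \
        else cfg.o2_initial
    for k in range(n):
        flux[k] = kw[k] * (o2_sat[k] - o2[k])
        if k + 1 < n:
            o2[k + 1] = o2[k] + dt_d * (gpp_t[k] - er_t[k] + flux[k]) / depth[k] \
                + adv[k]
            if o2[k + 1] < 0:
                raise RuntimeError(
                    f"simulated oxygen went negative at step {k + 1}; "
                    "the configuration is unrealistic")

    windows = []
    end_frac = t_days[-1]
    for k in range(len(suns) - 1):
        rise, setting = suns[k]
        nxt = suns[k + 1][0]
        if to_frac(rise) >= 0 and to_frac(nxt) <= end_frac:
            windows.append((rise, setting, nxt))

    sonde = pd.DataFrame({
        "timestamp": times,
        "temperature": temp,
        "salinity": sal,
        "depth": depth - st.sensor_height_offset,
        "oxygen": o2 + rng.standard_normal(n) * cfg.obs_noise_sd,
    })
    met = pd.DataFrame({
        "timestamp": times,
        "wind_speed": wind,
        "baro_pressure": np.full(n, cfg.baro),
    })
    truth = SimulatedTruth(config=cfg, times=times, gpp=gpp_t, er=er_t,
                           flux=flux, o2=o2, windows=windows)
    return sonde, met, truth


def truth_daily_integrals(truth: SimulatedTruth) -> pd.DataFrame:
    """Trapezoidal integrals of the prescribed rates per metabolic day.

    The acceptance oracle for the estimator: columns ``gpp``, ``er`` and
    ``nep = gpp - er`` (exact), one row per sunrise-to-sunrise window.
    """
    t = (truth.times - truth.times[0]).total_seconds().to_numpy() / 86400.0

    def integral(y, a, b):
        # exact window endpoints enter by linear interpolation
        m = (t > a) & (t < b)
        tt = np.concatenate(([a], t[m], [b]))
        yy = np.concatenate(([np.interp(a, t, y)], y[m], [np.interp(b, t, y)]))
        return float(np.trapezoid(yy, tt))

    rows = []
    for i, (rise, _sunset, nxt) in enumerate(truth.windows):
        a = (rise - truth.times[0]).total_seconds() / 86400.0
        b = (nxt - truth.times[0]).total_seconds() / 86400.0
        gpp = integral(truth.gpp, a, b)
        er = integral(truth.er, a, b)
        rows.append({"metabolic_day": i, "gpp": gpp, "er": er, "nep": gpp - er})
    return pd.DataFrame(rows, columns=["metabolic_day", "gpp", "er", "nep"])


def records_to_csv(sonde: pd.DataFrame, met: pd.DataFrame, sonde_path, met_path
                   ) -> None:
    """Write simulated records in the CSV dialects the readers consume."""
    out = pd.DataFrame({
        "timestamp": sonde["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "temp_c": sonde["temperature"],
        "sal_psu": sonde["salinity"],
        "depth_m": sonde["depth"],
        "do_mmol_m3": sonde["oxygen"],
    })
    out.to_csv(sonde_path, index=False, float_format="%.6f")
    outm = pd.DataFrame({
        "timestamp": met["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "wspd_ms": met["wind_speed"],
        "pres_hpa": met["baro_pressure"],
    })
    outm.to_csv(met_path, index=False, float_format="%.6f")
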