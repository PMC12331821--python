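"""Physical chemistry of seawater needed for the oxygen mass balance.

All functions are vectorised over numpy arrays and accept scalars.

Contents
--------
practical_salinity      PSS-78 practical salinity from conductivity
oxygen_saturation       Benson & Krause equilibrium O2 at ambient pressure
schmidt_number          O2 Schmidt number (Wanninkhof 2014 polynomials)
gas_transfer_velocity   wind-speed-squared piston velocity, m d^-1
depth_from_pressure     hydrostatic depth from total pressure
wind_at_10m             neutral log-profile height correction
surface_density         EOS-80 one-atmosphere seawater density

Constants are collected in ``CONSTANTS`` for reference.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CONSTANTS",
    "practical_salinity",
    "oxygen_saturation",
    "schmidt_number",
    "gas_transfer_velocity",
    "depth_from_pressure",
    "wind_at_10m",
    "surface_density",
    "O2_MOLAR_MASS",
]

#: molar mass of O2, g mol^-1 (used for mg/L <-> mmol/m^3)
O2_MOLAR_MASS = 31.998

#: conductivity of standard seawater (S=35, T=15 degC, p=0), mS cm^-1
C35_15_0 = 42.914

#: gravitational acceleration, m s^-2
GRAVITY = 9.81

#: Wanninkhof (2014) quadratic wind-speed coefficient, cm h^-1 per (m/s)^2
KW_COEFF_CM_PER_H = 0.251

#: cm h^-1 -> m d^-1
CM_PER_H_TO_M_PER_D = 0.24

#: roughness length for the neutral log wind profile, m
ROUGHNESS_LENGTH = 1.0e-4

CONSTANTS = {
    "O2_MOLAR_MASS_G_MOL": O2_MOLAR_MASS,
    "C35_15_0_MS_CM": C35_15_0,
    "GRAVITY_M_S2": GRAVITY,
    "KW_COEFF_CM_H": KW_COEFF_CM_PER_H,
    "KW_SCHMIDT_REF": 660.0,
    "ROUGHNESS_LENGTH_M": ROUGHNESS_LENGTH,
}


# ---------------------------------------------------------------------------
# PSS-78 practical salinity (Fofonoff & Millard / UNESCO TR 44 polynomials)
# ---------------------------------------------------------------------------

_PSS_A = (0.0080, -0.1692, 25.3851, 14.0941, -7.0261, 2.7081)
_PSS_B = (0.0005, -0.0056, -0.0066, -0.0375, 0.0636, -0.0144)
_PSS_K = 0.0162

_RT_C = (0.6766097, 2.00564e-2, 1.104259e-4, -6.9698e-7, 1.0031e-9)

_RP_E = (2.070e-5, -6.370e-10, 3.989e-15)
_RP_D = (3.426e-2, 4.464e-4, 4.215e-1, -3.107e-3)


def _sal_poly(rt_sqrt: np.ndarray, temperature: np.ndarray) -> np.ndarray:
    """S(Rt, T): the defining PSS-78 polynomial pair."""
    s0 = sum(a * rt_sqrt**i for i, a in enumerate(_PSS_A))
    ds = sum(b * rt_sqrt**i for i, b in enumerate(_PSS_B))
    dt = temperature - 15.0
    return s0 + dt / (1.0 + _PSS_K * dt) * ds


def practical_salinity(conductivity, temperature, pressure=0.0):
    """PSS-78 practical salinity from in-situ conductivity.

    Parameters
    ----------
    conductivity : mS cm^-1
    temperature : degC (ITS-68 assumed; the ITS-90 difference is far below
        sensor accuracy for this application)
    pressure : dbar (sea pressure; 0 at the surface)

    Returns
    -------
    salinity : PSU (dimensionless, practical salinity scale)

    Notes
    -----
    The conductivity ratio R = C / C(35,15,0) is split into the pressure
    factor Rp, the temperature factor rt and the salinity-carrying ratio
    Rt = R / (Rp * rt); salinity is the standard two-polynomial expansion
    in sqrt(Rt).  Nominal validity 2 <= S <= 42; values outside [0, 50]
    should be flagged by callers (``np.nan`` is returned only for
    non-positive conductivity).
    """
    c = np.asarray(conductivity, dtype=float)
    t = np.asarray(temperature, dtype=float)
    p = np.asarray(pressure, dtype=float)

    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(c > 0, c / C35_15_0, np.nan)
        rt_t = sum(ci * t**i for i, ci in enumerate(_RT_C))
        e1, e2, e3 = _RP_E
        d1, d2, d3, d4 = _RP_D
        rp = 1.0 + p * (e1 + e2 * p + e3 * p**2) / (
            1.0 + d1 * t + d2 * t**2 + (d3 + d4 * t) * r
        )
        rt = r / (rp * rt_t)
        sal = _sal_poly(np.sqrt(rt), t)
    if sal.ndim == 0:
        return float(sal)
    return sal


# ---------------------------------------------------------------------------
# Oxygen solubility (Benson & Krause, USGS/DOTABLES formulation)
# ---------------------------------------------------------------------------


def _o2_sat_one_atm_mg_l(t_kelvin, salinity):
    """Unit standard-atmosphere equilibrium O2, mg L^-1."""
    ln_c = (
        -139.34411
        + 1.575701e5 / t_kelvin
        - 6.642308e7 / t_kelvin**2
        + 1.243800e10 / t_kelvin**3
        - 8.621949e11 / t_kelvin**4
    )
    f_sal = -salinity * (0.017674 - 10.754 / t_kelvin + 2140.7 / t_kelvin**2)
    return np.exp(ln_c + f_sal)


def oxygen_saturation(temperature, salinity, baro_pressure=1013.25):
    """Equilibrium dissolved-oxygen concentration, mmol m^-3.

    Parameters
    ----------
    temperature : degC, valid 0-40
    salinity : PSU, valid 0-42
    baro_pressure : ambient (total) barometric pressure, hPa

    Returns
    -------
    o2_sat : mmol m^-3

    Notes
    -----
    Standard-atmosphere solubility times the total-pressure correction

        Fp = (P - u) (1 - theta P) / [(1 - u)(1 - theta)]

    with P in atm, u the water vapour pressure and theta the second
    pressure coefficient, both functions of temperature.
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    tk = t + 273.15
    c_star = _o2_sat_one_atm_mg_l(tk, s)

    p_atm = np.asarray(baro_pressure, dtype=float) / 1013.25
    ln_u = 11.8571 - 3840.70 / tk - 216961.0 / tk**2
    u = np.exp(ln_u)
    theta = 0.000975 - 1.426e-5 * t + 6.436e-8 * t**2
    f_p = (p_atm - u) * (1.0 - theta * p_atm) / ((1.0 - u) * (1.0 - theta))

    mg_l = c_star * f_p
    out = mg_l * 1000.0 / O2_MOLAR_MASS
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Schmidt number and gas transfer velocity (Wanninkhof 2014)
# ---------------------------------------------------------------------------

# O2 Schmidt polynomials Sc = A + Bt + Ct^2 + Dt^3 + Et^4, t in degC
_SC_O2_SEA = (1920.4, -135.6, 5.2122, -0.10939, 0.00093777)   # S = 35
_SC_O2_FRESH = (1745.1, -124.34, 4.8055, -0.10115, 0.00086842)  # S = 0


def _sc_poly(coeffs, t):
    return sum(c * t**i for i, c in enumerate(coeffs))


def schmidt_number(temperature, salinity=35.0):
    """Schmidt number of O2, linearly interpolated in salinity.

    Interpolates between the freshwater and seawater (S = 35) fourth-order
    polynomials; salinities above 35 extrapolate linearly.
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    sc_sea = _sc_poly(_SC_O2_SEA, t)
    sc_fresh = _sc_poly(_SC_O2_FRESH, t)
    out = sc_fresh + (sc_sea - sc_fresh) * s / 35.0
    if out.ndim == 0:
        return float(out)
    return out


def gas_transfer_velocity(wind10, temperature, salinity=35.0):
    """Gas transfer (piston) velocity k_w for O2, m d^-1.

    k_w = 0.251 U10^2 (Sc/660)^(-1/2) in cm h^-1, converted to m d^-1.
    Exactly zero at zero wind; scales quadratically with wind speed.
    """
    u = np.asarray(wind10, dtype=float)
    sc = schmidt_number(temperature, salinity)
    kw_cm_h = KW_COEFF_CM_PER_H * u**2 * (sc / 660.0) ** -0.5
    out = kw_cm_h * CM_PER_H_TO_M_PER_D
    if out.ndim == 0:
        return float(out)
    return out


def wind_at_10m(wind_speed, anemometer_height=None):
    """Refer a measured wind speed to 10 m by the neutral log profile.

    U10 = Uz * ln(10/z0) / ln(z/z0) with z0 = 1e-4 m.  When no anemometer
    height is given the measurement is taken as already 10-m referenced.
    """
    u = np.asarray(wind_speed, dtype=float)
    if anemometer_height is None:
        return u if u.ndim else float(u)
    z = float(anemometer_height)
    if z <= ROUGHNESS_LENGTH:
        raise ValueError(f"anemometer height {z} m must exceed z0={ROUGHNESS_LENGTH} m")
    factor = np.log(10.0 / ROUGHNESS_LENGTH) / np.log(z / ROUGHNESS_LENGTH)
    out = u * factor
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Depth from pressure
# ---------------------------------------------------------------------------

# EOS-80 one-atmosphere density of seawater, kg m^-3
_RHO_W = (999.842594, 6.793952e-2, -9.095290e-3, 1.001685e-4, -1.120083e-6, 6.536332e-9)
_RHO_A = (0.824493, -4.0899e-3, 7.6438e-5, -8.2467e-7, 5.3875e-9)
_RHO_B = (-5.72466e-3, 1.0227e-4, -1.6546e-6)
_RHO_C = 4.8314e-4


def surface_density(salinity, temperature):
    """Density of seawater at atmospheric pressure, kg m^-3 (EOS-80)."""
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    rho_w = sum(c * t**i for i, c in enumerate(_RHO_W))
    a = sum(c * t**i for i, c in enumerate(_RHO_A))
    b = sum(c * t**i for i, c in enumerate(_RHO_B))
    out = rho_w + a * s + b * s**1.5 + _RHO_C * s**2
    if out.ndim == 0:
        return float(out)
    return out


def depth_from_pressure(total_pressure, atm_pressure=1010.0, salinity=35.0,
                        temperature=20.0):
    """Water depth from a total (absolute) pressure reading.

    Parameters
    ----------
    total_pressure : dbar (absolute pressure measured by the sensor)
    atm_pressure : hPa subtracted as the atmospheric contribution
        (fixed-reference logger convention; default 1010 hPa)
    salinity, temperature : used for the water density

    Returns
    -------
    depth : m; ``nan`` where the hydrostatic pressure would be negative
    """
    p_tot = np.asarray(total_pressure, dtype=float)
    p_hydro_dbar = p_tot - np.asarray(atm_pressure, dtype=float) / 100.0
    rho = surface_density(salinity, temperature)
    depth = p_hydro_dbar * 1.0e4 / (rho * GRAVITY)
    out = np.where(p_hydro_dbar < 0, np.nan, depth)
    if out.ndim == 0:
        return float(out)
    return out
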