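"""Aggregation of daily metabolic rates and standard statistical summaries.

Rates aggregate by unweighted means over *metabolic days* (bay-level means
pool every day across stations and deployments, i.e. they are day-weighted,
not means of deployment means).  Uncertainty is the standard error of the
mean, sd / sqrt(n_days), conventionally displayed as +/- 2 SE.  Oxygen
converts to carbon with the organic-matter remineralisation stoichiometry
C:O2 = 106:154.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "C_TO_O2_RATIO",
    "CARBON_MOLAR_MASS",
    "to_carbon",
    "annualize",
    "gpp_npp_ratio",
    "summarize",
    "correlate",
    "kruskal_wallis",
]

#: mol C produced (consumed) per mol O2 consumed (produced), 106:154
C_TO_O2_RATIO = 106.0 / 154.0

#: g mol^-1
CARBON_MOLAR_MASS = 12.011

#: days per year used for annual rates
DAYS_PER_YEAR = 365.0


def to_carbon(rate):
    """Convert an O2 rate (mmol O2 m^-2 d^-1) to carbon (g C m^-2 d^-1).

    rate * (106/154) * 12.011 / 1000.  Linear; display rounding is left to
    the caller/formatter.
    """
    return np.multiply(rate, C_TO_O2_RATIO * CARBON_MOLAR_MASS / 1000.0)


def annualize(rate):
    """Scale a daily carbon rate to g C m^-2 y^-1 (365 d)."""
    return np.multiply(rate, DAYS_PER_YEAR)


def gpp_npp_ratio(gpp, npp):
    """Ratio of gross production to (planktonic) net primary production."""
    if np.any(np.asarray(npp) <= 0):
        raise ValueError("NPP must be positive for a GPP:NPP ratio")
    return np.divide(gpp, npp)


def summarize(rates: pd.DataFrame, by: str | Sequence[str] = "station",
              ) -> pd.DataFrame:
    """Group daily rates and report means, SEs and carbon conversions.

    Parameters
    ----------
    rates : daily-rates frame (one row per metabolic day) with columns
        ``gpp, er, nep`` and whatever grouping keys are requested
    by : column name(s) to group on — e.g. ``"station"``, ``["station",
        "deployment"]`` — or ``"all"`` to pool everything

    Returns
    -------
    DataFrame with per-group ``gpp/er/nep`` means, ``se_*`` standard
    errors (NaN when n_days == 1), ``n_days``, carbon-unit columns
    ``gpp_c/er_c/nep_c`` (g C m^-2 d^-1) and ``gpp_c_annual``
    (g C m^-2 y^-1).  Groups are day-weighted: pooled groups average all
    constituent days directly.
    """
    if rates.empty:
        raise ValueError("no daily rates to summarize")
    df = rates.copy()
    if by == "all":
        df["_all"] = "all"
        by = "_all"
    grouped = df.groupby(by, sort=True)

    out = grouped[["gpp", "er", "nep"]].mean()
    n = grouped.size().rename("n_days")
    sd = grouped[["gpp", "er", "nep"]].std(ddof=1)
    se = sd.div(np.sqrt(n), axis=0)
    se[n == 1] = np.nan
    se.columns = [f"se_{c}" for c in se.columns]

    out = pd.concat([out, se, n], axis=1)
    for c in ("gpp", "er", "nep"):
        out[f"{c}_c"] = to_carbon(out[c])
    out["gpp_c_annual"] = annualize(out["gpp_c"])
    out.index.name = "group" if by == "_all" else None
    return out


def correlate(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    Intended for per-station-per-deployment mean rates against covariate
    means.  Requires at least 3 pairs; zero variance in either variable
    makes r undefined (returns (nan, nan)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("correlate needs >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test across groups of daily rates.

    Tie-corrected H with a chi-square (k-1 df) p-value.  Identical values
    across all groups give H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
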