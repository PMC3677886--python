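"""Fick's-law layer fluxes, surface efflux extrapolation and annual totals.

The flux-gradient method estimates soil respiration from in-profile CO2
concentrations: Fick's first law gives the flux across each depth interval,

    F = Ds * (C_deep - C_shallow) / (z_deep - z_shallow),

with depth positive downward and flux positive upward (toward the
atmosphere).  With sensors at 10 and 30 cm plus atmospheric CO2, the
interval fluxes F5 (0-10 cm pair, midpoint 5 cm) and F20 (10-30 cm pair,
midpoint 20 cm) are extrapolated linearly in depth to the surface:

    F0 = F5 + (F5 - F20) * 5 / 15.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from soilflux import preprocessing as prep
from soilflux.diffusivity import DiffusivityModel, eval_ds

# Depth geometry (m): sensors and flux evaluation midpoints.
Z_SENSOR_SHALLOW = 0.10
Z_SENSOR_DEEP = 0.30
Z_FLUX_SHALLOW = 0.05
Z_FLUX_DEEP = 0.20

GRAMS_C_PER_UMOL = 12.011e-6
SECONDS_PER_DAY = 86400.0


def layer_flux(c_shallow, c_deep, z_shallow, z_deep, ds):
    """Fick's-law CO2 flux across a depth interval (umol m-2 s-1).

    Concentrations are mole concentrations (umol m-3), depths in m positive
    downward; a positive result is an upward flux.
    """
    if np.any(np.asarray(z_deep) <= np.asarray(z_shallow)) or np.any(
            np.asarray(z_shallow) < 0):
        raise ValueError("require z_deep > z_shallow >= 0")
    ds = np.asarray(ds, dtype=float)
    if np.any(ds <= 0):
        raise ValueError("diffusivity must be positive")
    out = ds * (np.asarray(c_deep, float) - np.asarray(c_shallow, float)) / (
        np.asarray(z_deep, float) - np.asarray(z_shallow, float))
    return out if np.ndim(out) else float(out)


def surface_efflux(f5, f20, z5: float = Z_FLUX_SHALLOW, z20: float = Z_FLUX_DEEP):
    """Linear extrapolation of the in-profile fluxes to the soil surface.

    With evaluation depths 5 and 20 cm: F0 = F5 + (F5 - F20)/3.
    """
    f5 = np.asarray(f5, dtype=float)
    f20 = np.asarray(f20, dtype=float)
    out = f5 + (f5 - f20) * z5 / (z20 - z5)
    return out if out.shape else float(out)


def compute_fluxes(df: pd.DataFrame, model_10cm: DiffusivityModel,
                   model_30cm: DiffusivityModel) -> pd.DataFrame:
    """Half-hourly F5/F20/F0 from a preprocessed profile record.

    Ds for F5 is evaluated with the 10 cm model at theta(10 cm); Ds for F20
    with the 30 cm model at the mean of theta(10 cm) and theta(30 cm).
    Timesteps whose CO2 input was gap-filled at the sensor ceiling carry a
    ``saturated_input`` QC flag so totals can be reported with and without
    them.
    """
    theta10 = df["theta_10cm"].to_numpy()
    theta30 = df["theta_30cm"].to_numpy()
    with np.errstate(invalid="ignore"):
        ds5 = eval_ds(model_10cm, theta10)
        ds20 = eval_ds(model_30cm, 0.5 * (theta10 + theta30))

    c_air = df["c_air_umol_m3"].to_numpy()
    c10 = df["co2_umol_m3_10cm"].to_numpy()
    c30 = df["co2_umol_m3_30cm"].to_numpy()

    f5 = layer_flux(c_air, c10, 0.0, Z_SENSOR_SHALLOW, ds5)
    f20 = layer_flux(c10, c30, Z_SENSOR_SHALLOW, Z_SENSOR_DEEP, ds20)
    f0 = surface_efflux(f5, f20)

    saturated = np.zeros(len(df), dtype=bool)
    missing = np.zeros(len(df), dtype=bool)
    for d in prep.DEPTH_LABELS:
        col = f"co2_flag_{d}"
        if col in df:
            flags = df[col].to_numpy()
            saturated |= flags == prep.FLAG_GAPFILLED_RANGE
            missing |= flags == prep.FLAG_MISSING
    qc = np.where(missing, prep.FLAG_MISSING,
                  np.where(saturated, "saturated_input", prep.FLAG_OK))

    return pd.DataFrame(
        {"f5": f5, "f20": f20, "f0": f0, "qc": qc}, index=df.index)


def annual_respiration(f0: pd.Series) -> float:
    """Annual soil respiration (g C m-2 y-1) from a >= 1 y half-hourly record.

    Day-of-year values that occur more than once in the record are averaged
    first (to avoid seasonal bias in a record longer than a year), then the
    365 daily means are integrated: sum(daily mean flux) * 86400 s *
    12.011e-6 g C per umol CO2.  Feb 29 is folded into day 59.
    """
    if not isinstance(f0.index, pd.DatetimeIndex):
        raise TypeError("f0 must be indexed by timestamp")
    doy = f0.index.dayofyear.to_numpy().copy()
    leap = f0.index.is_leap_year
    after_feb29 = leap & (doy >= 60)
    doy[after_feb29] -= 1  # align leap-year DOY with a 365-day calendar
    doy = np.minimum(doy, 365)
    by_doy = f0.groupby(doy).mean()
    if by_doy.index.nunique() < 365:
        raise ValueError(
            f"need all 365 days of year covered, have {by_doy.index.nunique()}")
    return float(by_doy.sum() * SECONDS_PER_DAY * GRAMS_C_PER_UMOL)


def chamber_comparison(gradient_f0, chamber_f0):
    """OLS regression of chamber-measured efflux on gradient-method efflux.

    Returns (slope, intercept, r_squared, p_value) of the slope test.
    """
    x = np.asarray(gradient_f0, dtype=float)
    y = np.asarray(chamber_f0, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples required")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)
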