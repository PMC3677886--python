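"""Sensor corrections, range gap-fill, unit conversions and the pF transform.

The in-profile CO2 sensors report a volume fraction (ppm) whose output
depends on temperature and pressure through the ideal gas law; readings are
corrected to a common reference state (25 degC, 101.325 kPa), converted to
mole concentrations for Fick's-law flux computation, and over-range samples
are gap-filled at the sensor ceiling so the record stays continuous for
time-series analysis.  Soil water potential (tension, kPa <= 0) is also
expressed on the logarithmic pF scale (log10 of head in cm of water).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# Reference state for the sensor correction.
T_REF_K = 298.15
P_REF_KPA = 101.325
R_GAS = 8.3145  # J mol-1 K-1
KPA_TO_CM_HEAD = 10.19716  # 1 kPa of tension == 10.19716 cm of water head
PSI_FLOOR_KPA = -0.001  # tensions in (-0.001, 0] are floored before the log
SENSOR_MAX_PPM = 115_000.0

# QC flag values used across the pipeline.
FLAG_OK = "ok"
FLAG_GAPFILLED_RANGE = "gapfilled_range"
FLAG_MISSING = "missing"

DEPTH_LABELS = ("10cm", "30cm")


def _validate_tp(t_k, p_kpa) -> None:
    t_k = np.asarray(t_k, dtype=float)
    p_kpa = np.asarray(p_kpa, dtype=float)
    if np.any(t_k <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    if np.any(p_kpa <= 0):
        raise ValueError("pressure must be positive (kPa)")


def correct_co2_reading(raw_ppm, t_soil_k, pressure_kpa):
    """Ideal-gas temperature/pressure correction of a raw CO2 reading.

    chi_corr = chi_raw * (P_ref / P) * (T / T_ref), with the reference state
    25 degC and 101.325 kPa.  At the reference state the correction is the
    identity.

    Parameters
    ----------
    raw_ppm : array_like
        Raw sensor output, ppm (volume fraction * 1e6).
    t_soil_k : array_like
        Soil temperature at the sensor, kelvin.
    pressure_kpa : array_like
        Barometric pressure, kPa.
    """
    _validate_tp(t_soil_k, pressure_kpa)
    raw_ppm = np.asarray(raw_ppm, dtype=float)
    out = raw_ppm * (P_REF_KPA / np.asarray(pressure_kpa, float)) * (
        np.asarray(t_soil_k, float) / T_REF_K
    )
    return out if out.shape else float(out)


def uncorrect_co2_reading(true_ppm, t_soil_k, pressure_kpa):
    """Inverse of :func:`correct_co2_reading` (used by the sensor simulator)."""
    _validate_tp(t_soil_k, pressure_kpa)
    true_ppm = np.asarray(true_ppm, dtype=float)
    out = true_ppm * (np.asarray(pressure_kpa, float) / P_REF_KPA) * (
        T_REF_K / np.asarray(t_soil_k, float)
    )
    return out if out.shape else float(out)


def ppm_to_mole_concentration(chi_ppm, t_k, pressure_kpa):
    """Convert a CO2 volume fraction (ppm) to mole concentration (umol m-3).

    C = chi * P / (R T); with chi in ppm and P in Pa the result is directly
    in umol m-3 (386 ppm at 25 degC / 101.325 kPa -> 1.578e4 umol m-3).
    """
    _validate_tp(t_k, pressure_kpa)
    chi_ppm = np.asarray(chi_ppm, dtype=float)
    p_pa = np.asarray(pressure_kpa, dtype=float) * 1000.0
    out = chi_ppm * p_pa / (R_GAS * np.asarray(t_k, dtype=float))
    return out if out.shape else float(out)


def mole_concentration_to_ppm(c_umol_m3, t_k, pressure_kpa):
    """Inverse of :func:`ppm_to_mole_concentration`."""
    _validate_tp(t_k, pressure_kpa)
    c = np.asarray(c_umol_m3, dtype=float)
    p_pa = np.asarray(pressure_kpa, dtype=float) * 1000.0
    out = c * R_GAS * np.asarray(t_k, dtype=float) / p_pa
    return out if out.shape else float(out)


def kpa_to_pF(psi_kpa):
    """Soil water potential (tension, kPa <= 0) to pF = log10(head in cm).

    Tensions in (-0.001, 0] kPa are floored to -0.001 kPa before taking the
    log so that saturation does not map to -inf.  Positive potentials are
    rejected.
    """
    psi = np.asarray(psi_kpa, dtype=float)
    if np.any(psi > 0):
        raise ValueError("soil water potential must be a tension (psi <= 0 kPa)")
    psi = np.minimum(psi, PSI_FLOOR_KPA)
    out = np.log10(-psi * KPA_TO_CM_HEAD)
    return out if out.shape else float(out)


def clip_and_gapfill(co2_ppm, over_range=None, range_max: float = SENSOR_MAX_PPM):
    """Apply the over-range gap-fill rule to a CO2 series.

    Samples flagged over-range (or exceeding ``range_max``) are set to exactly
    ``range_max`` so the record stays continuous; the number and fraction of
    gap-filled samples are reported alongside per-sample flags.

    Parameters
    ----------
    co2_ppm : array_like
        CO2 readings, ppm.  NaN marks a missing (not over-range) sample.
    over_range : array_like of bool, optional
        Saturation flags from the sensor; defaults to ``co2 >= range_max``.

    Returns
    -------
    filled : ndarray
    flags : ndarray of str  (``ok`` / ``gapfilled_range`` / ``missing``)
    count : int
    fraction : float
    """
    co2 = np.asarray(co2_ppm, dtype=float).copy()
    if over_range is None:
        over_range = co2 >= range_max
    over_range = np.asarray(over_range, dtype=bool) | (co2 >= range_max)
    flags = np.full(co2.shape, FLAG_OK, dtype=object)
    co2[over_range] = range_max
    flags[over_range] = FLAG_GAPFILLED_RANGE
    flags[np.isnan(co2)] = FLAG_MISSING
    count = int(over_range.sum())
    fraction = count / co2.size if co2.size else 0.0
    return co2, flags, count, fraction


def interpolate_short_gaps(series: pd.Series, max_gap_steps: int = 4):
    """Linearly interpolate missing samples across gaps of <= ``max_gap_steps``.

    Longer gaps stay NaN (flagged missing and excluded from statistics).
    Returns the filled series and a boolean mask of samples that remain
    missing.
    """
    filled = series.interpolate(method="linear", limit=max_gap_steps,
                                limit_area="inside")
    # interpolate(limit=...) fills the first max_gap_steps samples of longer
    # gaps too; undo that so long gaps are left entirely missing.
    isna = series.isna().to_numpy()
    if isna.any():
        run_id = np.cumsum(~isna)
        for rid in np.unique(run_id[isna]):
            idx = np.where(isna & (run_id == rid))[0]
            if idx.size > max_gap_steps:
                filled.iloc[idx] = np.nan
    return filled, filled.isna().to_numpy()


def preprocess(raw: pd.DataFrame, range_max: float = SENSOR_MAX_PPM,
               max_gap_steps: int = 4) -> tuple[pd.DataFrame, dict]:
    """Produce an analysis-ready profile record from raw sensor output.

    Steps, per depth: temperature/pressure correction of the CO2 reading,
    over-range gap-fill at ``range_max``, short-gap interpolation, conversion
    to mole concentration, and the pF transform of tension.  Returns the
    augmented frame plus a QC summary (counts by flag per channel).

    The input frame follows the canonical profile schema (see
    :func:`soilflux.io.read_profile_csv`).
    """
    df = raw.copy()
    qc: dict[str, dict] = {}
    t_k = {d: df[f"tsoil_{d}"].to_numpy() + 273.15 for d in DEPTH_LABELS}
    p = df["pressure_kpa"].to_numpy()

    for d in DEPTH_LABELS:
        raw_col = df[f"co2_ppm_{d}"]
        sat_col = f"co2_sat_{d}"
        over = df[sat_col].to_numpy(dtype=bool) if sat_col in df else None
        corrected = correct_co2_reading(raw_col.to_numpy(), t_k[d], p)
        filled, flags, count, frac = clip_and_gapfill(corrected, over, range_max)
        ser, still_missing = interpolate_short_gaps(
            pd.Series(filled, index=df.index), max_gap_steps)
        flags[still_missing] = FLAG_MISSING
        df[f"co2_ppm_{d}"] = ser.to_numpy()
        df[f"co2_flag_{d}"] = flags
        df[f"co2_umol_m3_{d}"] = ppm_to_mole_concentration(ser.to_numpy(), t_k[d], p)
        df[f"pF_{d}"] = kpa_to_pF(np.minimum(df[f"psi_kpa_{d}"].to_numpy(), 0.0))
        qc[f"co2_{d}"] = {
            "gapfilled_range": count,
            "gapfilled_fraction": frac,
            "missing": int(still_missing.sum()),
        }

    df["c_air_umol_m3"] = ppm_to_mole_concentration(
        df["c_air_ppm"].to_numpy(), df["tsoil_10cm"].to_numpy() + 273.15, p)
    return df, qc
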