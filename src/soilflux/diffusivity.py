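"""Steady-state chamber diffusivity and the Ds(theta) calibration models.

Soil CO2 diffusivity Ds is measured in the lab on undisturbed cores: a
CO2-enriched gas is fed to the base of a chamber, the core equilibrates to
steady state, and Ds follows from Fick's law across the core,

    Ds = (F0 - Fs) * L / (C_L - C_0),

where F0 is the steady surface efflux, Fs the core's own background CO2
production, L the core length and C_0/C_L the concentrations at its top and
bottom.  Repeating the measurement as the core dries yields (theta, Ds)
pairs, fitted here with the standard log-linear soil-gas form
ln Ds = a + b*theta, one model per sensor depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

THETA_RANGE = (0.04, 0.38)  # validity range of the lab calibration, cm3 cm-3


@dataclass(frozen=True)
class ChamberRun:
    """One steady-state chamber diffusivity measurement.

    All concentrations are mole concentrations (umol m-3), fluxes umol m-2
    s-1, length m.  ``theta`` is the core's volumetric water content during
    the run.
    """

    L: float
    c0: float
    cL: float
    f0: float
    fs: float
    theta: float

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError("core length L must be positive")
        if self.cL <= self.c0:
            raise ValueError("feed is at the base: cL must exceed c0")
        if not (self.f0 >= self.fs >= 0):
            raise ValueError("require f0 >= fs >= 0")


@dataclass
class DiffusivityModel:
    """Fitted exponential Ds(theta) model for one sensor depth.

    Ds(theta) = exp(a + b*theta); theta outside ``theta_range`` is clamped to
    the calibrated range on evaluation.
    """

    depth_label: str
    a: float
    b: float
    theta_range: tuple[float, float] = THETA_RANGE
    r_squared: float | None = None
    residuals: np.ndarray | None = field(default=None, repr=False)


def ds_from_chamber(run: ChamberRun) -> float:
    """Diffusivity from one steady-state chamber run.

    The through-core flux is F_L = F0 - Fs, so Ds = F_L * L / (cL - c0).
    """
    dc = run.cL - run.c0
    if dc == 0:
        raise ValueError("zero concentration difference across the core")
    return (run.f0 - run.fs) * run.L / dc


def fit_ds_theta(points, depth_label: str) -> DiffusivityModel:
    """Least-squares fit of ln Ds = a + b*theta from (theta, Ds) pairs.

    Parameters
    ----------
    points : sequence of (theta, ds) pairs, or tuple of two arrays
    depth_label : "10cm" or "30cm"
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 2 and arr.shape[0] == 2 and arr.shape[1] != 2:
        theta, ds = arr
    else:
        theta, ds = arr[:, 0], arr[:, 1]
    if theta.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.any(ds <= 0):
        raise ValueError("diffusivities must be positive")
    b, a = np.polyfit(theta, np.log(ds), 1)
    resid = np.log(ds) - (a + b * theta)
    ss_tot = np.sum((np.log(ds) - np.log(ds).mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    return DiffusivityModel(depth_label=depth_label, a=float(a), b=float(b),
                            r_squared=r2, residuals=resid)


def eval_ds(model: DiffusivityModel, theta, return_clamp_flags: bool = False):
    """Evaluate a fitted Ds(theta) model.

    theta outside the calibrated range is clamped to the range boundary and a
    warning is raised (flags returned with ``return_clamp_flags=True``).
    """
    if model.a is None or model.b is None:
        raise ValueError("model is not fitted")
    theta = np.asarray(theta, dtype=float)
    lo, hi = model.theta_range
    clamped = (theta < lo) | (theta > hi)
    if np.any(clamped):
        warnings.warn(
            f"theta outside calibrated range {model.theta_range}; clamped",
            stacklevel=2)
    th = np.clip(theta, lo, hi)
    ds = np.exp(model.a + model.b * th)
    ds = ds if ds.shape else float(ds)
    if return_clamp_flags:
        return ds, (clamped if np.ndim(clamped) else bool(clamped))
    return ds


def calibrate_from_runs(runs, depth_label: str) -> DiffusivityModel:
    """Fit a Ds(theta) model from a sequence of :class:`ChamberRun`."""
    pts = [(r.theta, ds_from_chamber(r)) for r in runs]
    return fit_ds_theta(pts, depth_label)
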