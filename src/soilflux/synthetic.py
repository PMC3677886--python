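"""Synthetic hyperseasonal soil CO2 simulator with known ground truth.

Emulates a seasonally flooded tropical wetland tree-island profile: a wet
season (roughly October-April) with frequent convective rain wetting the
soil from above, an annual flood pulse raising the water table and
saturating the profile from below, and a long dry season.  Soil CO2
production responds to temperature (Q10), water potential (linear in pF
with a cutoff) and rewetting (Birch-effect pulses); CO2 moves by vertical
diffusion with a moisture-dependent diffusivity, and in-profile sensors
report temperature/pressure-dependent readings that saturate at 115,000
ppm.  Every stochastic element is driven by an explicit seed and the full
ground truth (production, true surface efflux, true diffusivity) is
returned for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from soilflux import preprocessing as prep
from soilflux.diffusivity import ChamberRun, DiffusivityModel

STEPS_PER_DAY = 48
DT_SECONDS = 1800.0

# Ground-truth Ds(theta) = exp(a + b*theta) coefficients per sensor depth,
# giving ~2-4e-6 m2/s in dry sand and ~5e-8-1.5e-7 m2/s near saturation
# (diffusion-limited enough that the 30 cm sensor saturates under flood).
TRUTH_DS_COEFFS = {"10cm": (-12.0, -11.0), "30cm": (-12.3, -12.0)}


def truth_ds_model(depth_label: str) -> DiffusivityModel:
    """The simulator's ground-truth diffusivity model for one depth."""
    a, b = TRUTH_DS_COEFFS[depth_label]
    return DiffusivityModel(depth_label=depth_label, a=a, b=b)


# ---------------------------------------------------------------------------
# climate forcing
# ---------------------------------------------------------------------------

@dataclass
class SeasonParams:
    """Hyperseasonal climate: rain regime, temperature and air CO2.

    Rain is a marked Poisson process (per-step Bernoulli arrivals with
    exponential depths); the wet-season window is a day-of-year interval
    that may wrap the year end.  Defaults give an expected annual total of
    ~1250 mm, nearly all of it in the wet season.
    """

    wet_start_doy: int = 274      # Oct 1
    wet_end_doy: int = 120        # Apr 30
    wet_rate_per_day: float = 0.683
    dry_rate_per_day: float = 0.10
    wet_mean_mm: float = 8.0
    dry_mean_mm: float = 6.0
    t_mean: float = 25.5          # degC; annual + semiannual harmonics
    t_annual_amp: float = 1.5
    t_annual_peak_doy: float = 15.0
    t_semiannual_amp: float = 1.5
    t_semiannual_peak_doy: float = 75.5
    t_diurnal_amp: float = 5.0    # air, peak 14:30
    t_daily_anom_sd: float = 1.0  # synoptic day-to-day anomaly
    t_step_noise_sd: float = 0.2
    c_air_mean_ppm: float = 386.0
    c_air_diurnal_amp: float = 8.0
    pressure_mean_kpa: float = 99.0


@dataclass
class ClimateForcing:
    """Half-hourly surface forcing over the simulated period."""

    time: pd.DatetimeIndex
    precip: np.ndarray        # mm per step
    t_air: np.ndarray         # degC
    c_air: np.ndarray         # ppm
    pressure: np.ndarray      # kPa
    t_daily_anom: np.ndarray  # degC, synoptic anomaly shared with the soil

    def __post_init__(self):
        if np.any(self.precip < 0):
            raise ValueError("precipitation must be nonnegative")


def in_wet_season(doy, season: SeasonParams):
    """Boolean mask: day-of-year inside the (possibly wrapping) wet window."""
    doy = np.asarray(doy)
    if season.wet_start_doy > season.wet_end_doy:  # wraps new year
        return (doy >= season.wet_start_doy) | (doy <= season.wet_end_doy)
    return (doy >= season.wet_start_doy) & (doy <= season.wet_end_doy)


def seasonal_air_temperature(doy, season: SeasonParams):
    """Smooth seasonal mean air temperature (degC) for a day of year."""
    doy = np.asarray(doy, dtype=float)
    w = 2 * np.pi / 365.0
    return (season.t_mean
            + season.t_annual_amp * np.cos(w * (doy - season.t_annual_peak_doy))
            + season.t_semiannual_amp
            * np.cos(2 * w * (doy - season.t_semiannual_peak_doy)))


def gen_climate(days: int, season: SeasonParams | None = None, seed: int = 0,
                start: str = "2009-01-01") -> ClimateForcing:
    """Generate half-hourly climate forcing for ``days`` days.

    Deterministic for a fixed seed.  Rain arrivals are per-step Bernoulli
    with a seasonally varying rate; depths are exponential.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    season = season or SeasonParams()
    if not (1 <= season.wet_start_doy <= 366 and 1 <= season.wet_end_doy <= 366):
        raise ValueError("malformed wet-season window")
    rng = np.random.default_rng(seed)
    n = days * STEPS_PER_DAY
    time = pd.date_range(start, periods=n, freq="30min")
    doy = time.dayofyear.to_numpy()
    hour = time.hour.to_numpy() + time.minute.to_numpy() / 60.0

    wet = in_wet_season(doy, season)
    rate = np.where(wet, season.wet_rate_per_day, season.dry_rate_per_day)
    mean_mm = np.where(wet, season.wet_mean_mm, season.dry_mean_mm)
    events = rng.random(n) < rate / STEPS_PER_DAY
    precip = np.where(events, rng.exponential(1.0, n) * mean_mm, 0.0)

    anom_daily = np.repeat(rng.normal(0.0, season.t_daily_anom_sd, days),
                           STEPS_PER_DAY)
    t_air = (seasonal_air_temperature(doy, season)
             + season.t_diurnal_amp * np.cos(2 * np.pi * (hour - 14.5) / 24.0)
             + anom_daily
             + rng.normal(0.0, season.t_step_noise_sd, n))

    c_air = (season.c_air_mean_ppm
             + season.c_air_diurnal_amp * np.cos(2 * np.pi * (hour - 4.0) / 24.0)
             + rng.normal(0.0, 2.0, n))
    pressure = (season.pressure_mean_kpa
                + 0.4 * np.cos(2 * np.pi * (doy - 180) / 365.0)
                + 0.15 * np.cos(2 * np.pi * (hour - 10.0) / 12.0)
                + rng.normal(0.0, 0.05, n))
    return ClimateForcing(time=time, precip=precip, t_air=t_air, c_air=c_air,
                          pressure=pressure, t_daily_anom=anom_daily)


def expected_annual_rain(season: SeasonParams) -> tuple[float, float]:
    """Analytic mean and variance of the annual rain total (mm).

    The marked process has per-day arrival rate r and exponential depths of
    mean m, thinned to per-step Bernoulli arrivals: over d days the total has
    mean d*r*m (exactly, for p = r/steps) and variance n*p*E[D^2]*(1-p*...)
    ~= n*p*2m^2 for small p.
    """
    wet_days = (366 - season.wet_start_doy) + season.wet_end_doy \
        if season.wet_start_doy > season.wet_end_doy \
        else season.wet_end_doy - season.wet_start_doy + 1
    dry_days = 365 - wet_days
    mean = (wet_days * season.wet_rate_per_day * season.wet_mean_mm
            + dry_days * season.dry_rate_per_day * season.dry_mean_mm)
    var = (wet_days * season.wet_rate_per_day * 2 * season.wet_mean_mm**2
           + dry_days * season.dry_rate_per_day * 2 * season.dry_mean_mm**2)
    return mean, var


# ---------------------------------------------------------------------------
# soil temperature
# ---------------------------------------------------------------------------

DIURNAL_DAMPING_M = 0.15   # damping depth of the diurnal wave
SEASONAL_DAMPING_M = 2.0   # seasonal wave barely damped at sensor depths


def soil_temperature(time: pd.DatetimeIndex, depth_m, season: SeasonParams,
                     daily_anom: np.ndarray | None = None):
    """Soil temperature at depth: damped, phase-lagged surface wave.

    Diurnal and synoptic components damp as exp(-z/d) with the diurnal
    damping depth; the seasonal harmonic is essentially undamped at sensor
    depths but lagged slightly.
    """
    depth_m = float(depth_m)
    doy = time.dayofyear.to_numpy().astype(float)
    hour = time.hour.to_numpy() + time.minute.to_numpy() / 60.0
    zd = depth_m / DIURNAL_DAMPING_M
    zs = depth_m / SEASONAL_DAMPING_M
    w = 2 * np.pi / 365.0
    seas = (season.t_mean
            + season.t_annual_amp * np.exp(-zs)
            * np.cos(w * (doy - season.t_annual_peak_doy) - zs)
            + season.t_semiannual_amp * np.exp(-np.sqrt(2) * zs)
            * np.cos(2 * w * (doy - season.t_semiannual_peak_doy) - np.sqrt(2) * zs))
    diur = (season.t_diurnal_amp * np.exp(-zd)
            * np.cos(2 * np.pi * (hour - 14.5) / 24.0 - zd))
    out = seas + diur
    if daily_anom is not None:
        out = out + np.exp(-zd) * daily_anom
    return out


# ---------------------------------------------------------------------------
# retention curve (van Genuchten with wetting/drying hysteresis)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VanGenuchten:
    """van Genuchten retention parameters for a loamy-sand wetland soil.

    ``alpha_kpa`` is the inverse air-entry scale in kPa^-1 for the drying
    branch; the wetting branch uses ``alpha_kpa * wetting_alpha_factor``
    (Kool-Parker convention), so at equal theta the wetting branch holds
    less tension.
    """

    theta_r: float = 0.04
    theta_s: float = 0.38
    alpha_kpa: float = 0.5
    n: float = 1.5
    wetting_alpha_factor: float = 2.0

    def __post_init__(self):
        if self.n <= 1:
            raise ValueError("van Genuchten n must exceed 1")
        if self.theta_s <= self.theta_r:
            raise ValueError("theta_s must exceed theta_r")


_SE_FLOOR = 1e-9


def retention(theta, vg: VanGenuchten = VanGenuchten(), branch: str = "drying"):
    """Matric potential psi (kPa <= 0) from water content on one branch.

    Strictly increasing in theta with psi(theta_s) = 0.
    """
    if branch not in ("wetting", "drying"):
        raise ValueError("branch must be 'wetting' or 'drying'")
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < vg.theta_r - 1e-12) or np.any(theta > vg.theta_s + 1e-12):
        raise ValueError("theta outside [theta_r, theta_s]")
    alpha = vg.alpha_kpa * (vg.wetting_alpha_factor if branch == "wetting" else 1.0)
    m = 1.0 - 1.0 / vg.n
    se = np.clip((theta - vg.theta_r) / (vg.theta_s - vg.theta_r), _SE_FLOOR, 1.0)
    psi = -(se ** (-1.0 / m) - 1.0) ** (1.0 / vg.n) / alpha
    return psi if psi.shape else float(psi)


def theta_from_psi(psi_kpa, vg: VanGenuchten = VanGenuchten(),
                   branch: str = "drying"):
    """Inverse retention: water content from tension on the same branch."""
    if branch not in ("wetting", "drying"):
        raise ValueError("branch must be 'wetting' or 'drying'")
    psi = np.asarray(psi_kpa, dtype=float)
    if np.any(psi > 0):
        raise ValueError("psi must be a tension (<= 0 kPa)")
    alpha = vg.alpha_kpa * (vg.wetting_alpha_factor if branch == "wetting" else 1.0)
    m = 1.0 - 1.0 / vg.n
    se = (1.0 + (-alpha * psi) ** vg.n) ** (-m)
    theta = vg.theta_r + se * (vg.theta_s - vg.theta_r)
    return theta if theta.shape else float(theta)


def retention_series(theta: np.ndarray, vg: VanGenuchten) -> np.ndarray:
    """Per-step hysteretic psi: wetting branch where theta rose, else drying."""
    dtheta = np.diff(theta, prepend=theta[0])
    psi = np.empty_like(theta)
    rising = dtheta > 0
    if rising.any():
        psi[rising] = retention(theta[rising], vg, "wetting")
    if (~rising).any():
        psi[~rising] = retention(theta[~rising], vg, "drying")
    return psi


# ---------------------------------------------------------------------------
# bucket soil-water model (wet-from-above) + flood water table (wet-from-below)
# ---------------------------------------------------------------------------

@dataclass
class WaterParams:
    """Two-layer nonlinear bucket constants.

    Layer 1 spans 0-0.2 m (10 cm sensor), layer 2 spans 0.2-0.4 m (30 cm
    sensor).  Infiltrating event water is split between layer 1 (sharp
    rise) and a percolation store that releases into layer 2 with time
    constant ``perc_tau_days`` (lagged, damped rise); between events both
    layers recede toward theta_r through gravity drainage k * Se^3 *
    (theta - theta_r) per day (strongly nonlinear: post-event drawdown is
    fast, the dry-season tail slow) and layer 1 additionally loses
    Se^2-scaled evaporation.  The flood is a prescribed water-table ramp;
    saturation from below is imposed through an exponential capillary
    fringe above the table.
    """

    theta_r: float = 0.04
    theta_s: float = 0.38
    d1: float = 0.2               # layer thicknesses, m
    d2: float = 0.2
    k1_per_day: float = 0.30      # recession constants at saturation
    k2_per_day: float = 0.15
    infiltration_fraction: float = 0.85
    route_fraction: float = 0.4   # share of infiltration routed to layer 2
    perc_tau_days: float = 1.5
    evap_mm_day: float = 5.0
    wt_base_m: float = 3.0        # water-table depth outside the flood
    wt_min_m: float = 0.12        # peak flood stage (below surface)
    ramp_in_days: float = 12.0
    ramp_out_days: float = 20.0
    fringe_m: float = 0.15        # capillary fringe e-folding height
    theta_init: tuple = (0.20, 0.22)

    def __post_init__(self):
        if self.theta_s <= self.theta_r:
            raise ValueError("theta_s must exceed theta_r")
        if self.k1_per_day < 0 or self.k2_per_day < 0:
            raise ValueError("recession constants must be nonnegative")
        if not (0.0 <= self.route_fraction <= 1.0):
            raise ValueError("route_fraction must be in [0, 1]")


@dataclass
class SoilState:
    """Layer water states and water-balance diagnostics (all water in m)."""

    time: pd.DatetimeIndex
    theta: dict                   # depth label -> theta series
    psi: dict                     # depth label -> psi series (kPa)
    t_soil: dict                  # depth label -> temperature series (degC)
    water_table: np.ndarray       # m below surface
    balance: dict = field(default_factory=dict)


def water_table_depth(doy, flood_window, wp: WaterParams):
    """Prescribed water-table depth (m) for a day-of-year flood window."""
    doy = np.asarray(doy, dtype=float)
    wt = np.full(doy.shape, wp.wt_base_m)
    if flood_window is None:
        return wt
    start, end = flood_window
    if end <= start:
        raise ValueError("flood window end must follow start (no wrap)")
    t = doy
    rise = (t >= start) & (t < start + wp.ramp_in_days)
    frac = (t[rise] - start) / wp.ramp_in_days
    wt[rise] = wp.wt_base_m + frac * (wp.wt_min_m - wp.wt_base_m)
    hold = (t >= start + wp.ramp_in_days) & (t <= end)
    wt[hold] = wp.wt_min_m
    fall = (t > end) & (t <= end + wp.ramp_out_days)
    frac = (t[fall] - end) / wp.ramp_out_days
    wt[fall] = wp.wt_min_m + frac * (wp.wt_base_m - wp.wt_min_m)
    return wt


def soil_water_forward(forcing: ClimateForcing, flood_window=None,
                       params: WaterParams | None = None,
                       vg: VanGenuchten | None = None,
                       season: SeasonParams | None = None) -> SoilState:
    """Step the two-layer bucket forward under rain, drainage and flood.

    Rain wets layer 1 sharply and layer 2 with a damped lag (percolation
    routing); with no rain both layers recede monotonically toward theta_r;
    the flood window ramps the water table up so the 30 cm depth saturates
    before 10 cm.  The per-step water balance (storage change, including
    the percolation store, = infiltration - excess - deep drainage -
    evaporation + flood supply) closes to roundoff and is returned in
    ``balance``.
    """
    wp = params or WaterParams()
    vg = vg or VanGenuchten(theta_r=wp.theta_r, theta_s=wp.theta_s)
    season = season or SeasonParams()
    n = len(forcing.time)
    doy_f = (forcing.time.dayofyear.to_numpy().astype(float)
             + (forcing.time.hour.to_numpy() * 60
                + forcing.time.minute.to_numpy()) / 1440.0)
    wt = water_table_depth(doy_f, flood_window, wp)
    dt_d = 1.0 / STEPS_PER_DAY

    th1 = np.empty(n)
    th2 = np.empty(n)
    store_arr = np.zeros(n)
    infil = np.zeros(n)
    excess = np.zeros(n)
    drain2 = np.zeros(n)
    evap = np.zeros(n)
    flood_supply = np.zeros(n)

    t1, t2 = wp.theta_init
    store = 0.0  # percolation routing store, m of water
    release_frac = 1.0 - np.exp(-dt_d / wp.perc_tau_days)
    span = wp.theta_s - wp.theta_r
    for i in range(n):
        # wet from above: direct share to layer 1, routed share to the store
        fin = wp.infiltration_fraction * forcing.precip[i] / 1000.0
        store += wp.route_fraction * fin
        t1 += (1.0 - wp.route_fraction) * fin / wp.d1
        ex = 0.0
        if t1 > wp.theta_s:
            ex += (t1 - wp.theta_s) * wp.d1
            t1 = wp.theta_s
        rel = store * release_frac
        store -= rel
        t2 += rel / wp.d2
        if t2 > wp.theta_s:
            ex += (t2 - wp.theta_s) * wp.d2
            t2 = wp.theta_s
        # gravity drainage (to deep) and evaporation
        se1 = (t1 - wp.theta_r) / span
        d1_out = wp.k1_per_day * se1**3 * (t1 - wp.theta_r) * wp.d1 * dt_d
        t1 -= d1_out / wp.d1
        ev = min(wp.evap_mm_day / 1000.0 * se1**2 * dt_d,
                 (t1 - wp.theta_r) * wp.d1)
        t1 -= ev / wp.d1
        se2 = (t2 - wp.theta_r) / span
        d2_out = wp.k2_per_day * se2**3 * (t2 - wp.theta_r) * wp.d2 * dt_d
        t2 -= d2_out / wp.d2
        d2_out += d1_out  # both layers drain to depth
        # wet from below: capillary fringe above the prescribed water table
        fl = 0.0
        if wt[i] < wp.wt_base_m:
            for depth, th, d in ((0.10, t1, wp.d1), (0.30, t2, wp.d2)):
                cap = wp.theta_r + span * np.exp(-max(wt[i] - depth, 0.0)
                                                 / wp.fringe_m)
                if cap > th:
                    fl += (cap - th) * d
                    if depth == 0.10:
                        t1 = cap
                    else:
                        t2 = cap
        th1[i], th2[i], store_arr[i] = t1, t2, store
        infil[i], excess[i], drain2[i] = fin, ex, d2_out
        evap[i], flood_supply[i] = ev, fl

    psi1 = retention_series(th1, vg)
    psi2 = retention_series(th2, vg)
    ts10 = soil_temperature(forcing.time, 0.10, season, forcing.t_daily_anom)
    ts30 = soil_temperature(forcing.time, 0.30, season, forcing.t_daily_anom)
    storage = th1 * wp.d1 + th2 * wp.d2 + store_arr
    balance = {
        "storage": storage,
        "infiltration": infil,
        "excess": excess,
        "deep_drainage": drain2,
        "evaporation": evap,
        "flood_supply": flood_supply,
        "initial_storage": wp.theta_init[0] * wp.d1 + wp.theta_init[1] * wp.d2,
    }
    return SoilState(time=forcing.time,
                     theta={"10cm": th1, "30cm": th2},
                     psi={"10cm": psi1, "30cm": psi2},
                     t_soil={"10cm": ts10, "30cm": ts30},
                     water_table=wt, balance=balance)


# ---------------------------------------------------------------------------
# CO2 production
# ---------------------------------------------------------------------------

@dataclass
class ProductionParams:
    """Depth-resolved CO2 production response.

    R(z,t) = R0 exp(-z/z_e) * Q10^((T-25)/10) * max(0, 1 - pF/pF_max)
             + Birch pulse,
    where the Birch pulse fires when theta rises by >= ``rewet_dtheta``
    after at least ``antecedent_dry_steps`` consecutive steps with
    pF > ``dry_pf``, then decays exponentially with ``birch_tau_days``.
    """

    r0_surface: float = 30.0      # umol m-3 s-1 at z=0, 25 degC, pF 0
    efold_m: float = 0.2
    q10: float = 2.0
    t_ref_c: float = 25.0
    pf_max: float = 4.2
    birch_gain: float = 1.5       # pulse amplitude as multiple of local base R0
    birch_tau_days: float = 2.0
    antecedent_dry_steps: int = 480   # 10 days
    dry_pf: float = 2.5
    rewet_dtheta: float = 0.005

    def __post_init__(self):
        if self.r0_surface < 0:
            raise ValueError("R0 must be nonnegative")
        if self.q10 <= 0 or self.pf_max <= 0:
            raise ValueError("Q10 and pF_max must be positive")


def moisture_factor(psi_kpa, pf_max: float):
    """Log-linear moisture limitation: 1 at pF<=0, 0 at pF>=pF_max."""
    pf = np.maximum(kpa_to_pf_clipped(psi_kpa), 0.0)
    return np.clip(1.0 - pf / pf_max, 0.0, 1.0)


def kpa_to_pf_clipped(psi_kpa):
    """pF of a tension, with psi floored near saturation (vectorized)."""
    return prep.kpa_to_pF(np.minimum(np.asarray(psi_kpa, float), 0.0))


def birch_pulse_state(theta: np.ndarray, psi_kpa: np.ndarray,
                      params: ProductionParams) -> np.ndarray:
    """Dimensionless rewetting-pulse state (0 when no pulse is active)."""
    pf = kpa_to_pf_clipped(psi_kpa)
    decay = np.exp(-1.0 / (params.birch_tau_days * STEPS_PER_DAY))
    state = np.zeros(theta.size)
    dry_count = 0
    level = 0.0
    prev = theta[0]
    for i in range(theta.size):
        level *= decay
        if theta[i] - prev >= params.rewet_dtheta and \
                dry_count >= params.antecedent_dry_steps:
            level += 1.0
            dry_count = 0
        if pf[i] > params.dry_pf:
            dry_count += 1
        else:
            dry_count = 0
        state[i] = level
        prev = theta[i]
    return state


def production_rate(t_soil_c, psi_kpa, depth_m: float,
                    params: ProductionParams | None = None,
                    theta: np.ndarray | None = None):
    """Volumetric CO2 production (umol m-3 s-1) at one depth.

    ``theta`` is only needed for the Birch rewetting pulse; without it the
    base temperature-moisture response is returned.
    """
    params = params or ProductionParams()
    t = np.asarray(t_soil_c, dtype=float)
    r0 = params.r0_surface * np.exp(-float(depth_m) / params.efold_m)
    q10f = params.q10 ** ((t - params.t_ref_c) / 10.0)
    base = r0 * q10f * moisture_factor(psi_kpa, params.pf_max)
    if theta is not None:
        pulse = birch_pulse_state(np.asarray(theta, float),
                                  np.asarray(psi_kpa, float), params)
        base = base + params.birch_gain * r0 * q10f * pulse
    return base if np.ndim(base) else float(base)


# ---------------------------------------------------------------------------
# diffusion solver
# ---------------------------------------------------------------------------

def _steady_state(c_air, ds_face, r, dz):
    """Direct steady solve: div(Ds grad C) + R = 0, Dirichlet top, no-flux bottom.

    ``ds_face`` holds the nz-1 face diffusivities; ``r`` the production at
    the unknown nodes 1..N.  The bottom node is a half cell.
    """
    nu = r.size
    dminus = ds_face                      # D_{i-1/2} for node i = 1..N
    dplus = np.append(ds_face[1:], 0.0)   # D_{i+1/2}; none below the bottom
    diag = dminus + dplus
    rhs = r * dz * dz
    rhs[-1] *= 0.5                        # half-volume bottom cell
    rhs[0] += dminus[0] * c_air
    ab = np.zeros((3, nu))
    ab[0, 1:] = -dplus[:-1]
    ab[1, :] = diag
    ab[2, :-1] = -dminus[1:]
    return solve_banded((1, 1), ab, rhs)


def diffuse_profile(production: np.ndarray, ds: np.ndarray, grid: np.ndarray,
                    c_air: np.ndarray | float, dt_s: float = DT_SECONDS,
                    c_init="steady"):
    """Crank-Nicolson solution of dC/dt = d/dz(Ds dC/dz) + R on a 1-D profile.

    Top boundary is held at the atmospheric mole concentration, the bottom
    is zero-flux.  Unconditionally stable and second-order in space; at
    steady state with uniform production and constant Ds the discrete
    solution equals the closed-form parabola to roundoff.

    Parameters
    ----------
    production : (nz, nt) or (nz,) array, umol m-3 s-1 on the grid
    ds : (nz, nt) or (nz,) array, m2 s-1 on the grid (positive)
    grid : (nz,) strictly increasing depths from 0, uniform spacing <= 2 cm
    c_air : scalar or (nt,) top-boundary mole concentration, umol m-3

    Returns
    -------
    c : (nz, nt) mole concentrations
    f0 : (nt,) true surface efflux, umol m-2 s-1 positive upward
        (second-order one-sided gradient at z=0)
    diagnostics : dict with 'storage', 'cum_production', 'cum_surface'
        (CN-consistent bookkeeping for mass-conservation checks)
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 3 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with >= 3 nodes")
    dz = np.diff(grid)
    if not np.allclose(dz, dz[0]):
        raise ValueError("grid must be uniform")
    if dz[0] > 0.02 + 1e-12:
        raise ValueError("grid spacing must be <= 2 cm")
    dz = float(dz[0])
    nz = grid.size

    production = np.asarray(production, dtype=float)
    ds = np.asarray(ds, dtype=float)
    if production.ndim == 1:
        production = production[:, None]
    nt = production.shape[1]
    if ds.ndim == 1:
        ds = np.broadcast_to(ds[:, None], (nz, nt))
    if np.any(~np.isfinite(ds)) or np.any(ds <= 0):
        raise ValueError("Ds must be finite and positive")
    c_air = np.broadcast_to(np.asarray(c_air, dtype=float), (nt,))

    c = np.empty((nz, nt))
    nu = nz - 1  # unknowns: nodes 1..nz-1
    lam = dt_s / (2.0 * dz * dz)

    def faces(col):
        return 0.5 * (ds[:-1, col] + ds[1:, col])  # nz-1 faces

    dsf0 = faces(0)
    if isinstance(c_init, str) and c_init == "steady":
        c0 = np.empty(nz)
        c0[0] = c_air[0]
        c0[1:] = _steady_state(c_air[0], dsf0, production[1:, 0], dz)
    else:
        c0 = np.broadcast_to(np.asarray(c_init, dtype=float), (nz,)).copy()
    c[:, 0] = c0

    storage = np.empty(nt)
    cum_prod = np.zeros(nt)
    cum_surf = np.zeros(nt)
    vol = np.full(nz, dz)
    vol[-1] = dz / 2.0  # bottom half cell; node 0 is the boundary
    storage[0] = float(np.dot(c0[1:], vol[1:]))

    ab = np.zeros((3, nu))
    wbot = np.ones(nu)
    wbot[-1] = 2.0  # half-volume bottom cell
    for t in range(1, nt):
        dsf = faces(t)
        dlo = dsf                            # D_{i-1/2} for node i = 1..N
        dup = np.append(dsf[1:], 0.0)        # D_{i+1/2}; none at bottom
        expl = (dlo * c[:-1, t - 1]
                - (dlo + dup) * c[1:, t - 1]
                + dup * np.append(c[2:, t - 1], 0.0))
        rhs = (c[1:, t - 1] + lam * wbot * expl
               + dt_s * 0.5 * (production[1:, t - 1] + production[1:, t]))
        rhs[0] += lam * dlo[0] * c_air[t]    # implicit Dirichlet contribution
        ab[0, 1:] = -lam * wbot[:-1] * dup[:-1]
        ab[1, :] = 1.0 + lam * wbot * (dlo + dup)
        ab[2, :-1] = -lam * wbot[1:] * dlo[1:]
        c[1:, t] = solve_banded((1, 1), ab, rhs)
        c[0, t] = c_air[t]
        storage[t] = float(np.dot(c[1:, t], vol[1:]))
        cum_prod[t] = cum_prod[t - 1] + dt_s * float(
            np.dot(0.5 * (production[1:, t - 1] + production[1:, t]), vol[1:]))
        # CN-consistent flux through the face at dz/2 (positive upward); the
        # operator freezes Ds per step, so both half-steps use dsf[0]
        cum_surf[t] = cum_surf[t - 1] + dt_s * 0.5 * dsf[0] * (
            (c[1, t - 1] - c[0, t - 1]) + (c[1, t] - c[0, t])) / dz

    # surface efflux from a second-order one-sided derivative at z = 0
    ds0 = ds[0, :]
    f0 = ds0 * (-3.0 * c[0, :] + 4.0 * c[1, :] - c[2, :]) / (2.0 * dz)
    diagnostics = {"storage": storage, "cum_production": cum_prod,
                   "cum_surface": cum_surf}
    return c, f0, diagnostics


# ---------------------------------------------------------------------------
# chamber and sensor simulators
# ---------------------------------------------------------------------------

def chamber_sim(ds_true: float, L: float = 0.1, c_feed_ppm: float = 50_000.0,
                fs: float = 1.0, theta: float = 0.2, noise_sd: float = 0.0,
                seed: int | None = None, t_k: float = prep.T_REF_K,
                p_kpa: float = prep.P_REF_KPA,
                c_top_ppm: float = 600.0) -> ChamberRun:
    """Simulate one steady-state chamber diffusivity run.

    A CO2-rich gas is fed at the core base (concentration ``c_feed_ppm``)
    while the top sits in lab air; at steady state the through-core flux is
    F_L = Ds (C_L - C_0) / L and the measured surface efflux is
    F_0 = F_L + Fs, with Fs the core's own production.  ``noise_sd`` is the
    relative (fractional) Gaussian error applied to each measured quantity.
    """
    if ds_true <= 0:
        raise ValueError("ds_true must be positive")
    if L <= 0:
        raise ValueError("core length must be positive")
    c0 = prep.ppm_to_mole_concentration(c_top_ppm, t_k, p_kpa)
    cL = prep.ppm_to_mole_concentration(c_feed_ppm, t_k, p_kpa)
    fL = ds_true * (cL - c0) / L
    f0 = fL + fs
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        c0 = c0 * (1.0 + rng.normal(0.0, noise_sd))
        cL = cL * (1.0 + rng.normal(0.0, noise_sd))
        f0 = f0 * (1.0 + rng.normal(0.0, noise_sd))
        fs = fs * (1.0 + rng.normal(0.0, noise_sd)) if fs > 0 else fs
    return ChamberRun(L=L, c0=c0, cL=cL, f0=f0, fs=fs, theta=theta)


def chamber_series(depth_label: str, thetas=None, fs: float = 1.0,
                   noise_sd: float = 0.0, seed: int | None = None):
    """Chamber runs across a moisture range using the ground-truth Ds model."""
    model = truth_ds_model(depth_label)
    if thetas is None:
        thetas = np.linspace(0.04, 0.38, 8)
    rng = np.random.default_rng(seed)
    runs = []
    for th in np.asarray(thetas, dtype=float):
        ds = float(np.exp(model.a + model.b * th))
        sub = int(rng.integers(0, 2**31 - 1)) if noise_sd > 0 else None
        runs.append(chamber_sim(ds, fs=fs, theta=float(th),
                                noise_sd=noise_sd, seed=sub))
    return runs


def sensorize(conc_umol_m3: np.ndarray, t_soil_c: np.ndarray,
              pressure_kpa: np.ndarray, noise_sd_ppm: float = 0.0,
              range_max: float = prep.SENSOR_MAX_PPM,
              seed: int | None = None, n_readings: int = 4):
    """Simulate the in-profile CO2 sensor: raw ppm readings + saturation flags.

    The true mole concentration is converted to a volume fraction at the in
    situ temperature and pressure, the inverse of the ideal-gas sensor
    correction is applied (so preprocessing recovers the truth exactly in
    the noise-free in-range case), Gaussian noise is added per 30-s
    sub-reading, each sub-reading clips at ``range_max``, and the
    ``n_readings`` sub-readings of the duty-cycled measurement window are
    averaged.  A sample is flagged saturated when every sub-reading clipped.
    """
    t_k = np.asarray(t_soil_c, dtype=float) + 273.15
    p = np.asarray(pressure_kpa, dtype=float)
    true_ppm = prep.mole_concentration_to_ppm(
        np.asarray(conc_umol_m3, dtype=float), t_k, p)
    raw = prep.uncorrect_co2_reading(true_ppm, t_k, p)
    if noise_sd_ppm > 0:
        rng = np.random.default_rng(seed)
        reads = raw[None, :] + rng.normal(0.0, noise_sd_ppm,
                                          (n_readings, raw.size))
    else:
        reads = np.broadcast_to(raw, (n_readings, raw.size))
    clipped = np.minimum(reads, range_max)
    reading = clipped.mean(axis=0)
    saturated = np.all(reads >= range_max, axis=0)
    return reading, saturated


# ---------------------------------------------------------------------------
# end-to-end simulation
# ---------------------------------------------------------------------------

GRID_DZ = 0.01
GRID_DEPTH = 1.0
LAYER1_BOTTOM = 0.2  # grid levels at or above use layer-1 water state


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated sensor record."""

    grid: np.ndarray
    production: np.ndarray      # (nz, nt) umol m-3 s-1
    f0_true: np.ndarray         # (nt,) umol m-2 s-1
    ds_true: dict               # depth label -> Ds series at the sensor
    c_true: dict                # depth label -> true mole concentration
    diagnostics: dict
    seed: int


def _layer_to_grid(grid, series_1, series_2):
    """Broadcast the two layer states onto the solver grid."""
    out = np.empty((grid.size, series_1.size))
    top = grid <= LAYER1_BOTTOM + 1e-12
    out[top, :] = series_1
    out[~top, :] = series_2
    return out


def simulate(days: int = 270, seed: int = 0, start: str = "2009-01-01",
             season: SeasonParams | None = None,
             water: WaterParams | None = None,
             vg: VanGenuchten | None = None,
             production_params: ProductionParams | None = None,
             flood_window=(121, 165), co2_noise_sd_ppm: float = 50.0):
    """Run the full hyperseasonal simulation.

    Returns ``(profile, truth)`` where ``profile`` is a raw sensor record in
    the canonical column schema (plus ``co2_sat_*`` saturation flags) and
    ``truth`` is a :class:`SimulationTruth`.
    """
    season = season or SeasonParams()
    water = water or WaterParams()
    vg = vg or VanGenuchten(theta_r=water.theta_r, theta_s=water.theta_s)
    pp = production_params or ProductionParams()
    rng = np.random.default_rng(seed)
    sub = [int(rng.integers(0, 2**31 - 1)) for _ in range(4)]

    forcing = gen_climate(days, season, seed=sub[0], start=start)
    soil = soil_water_forward(forcing, flood_window, water, vg, season)
    time = forcing.time
    nt = len(time)

    grid = np.round(np.arange(0.0, GRID_DEPTH + GRID_DZ / 2, GRID_DZ), 6)
    th_g = _layer_to_grid(grid, soil.theta["10cm"], soil.theta["30cm"])
    psi_g = _layer_to_grid(grid, soil.psi["10cm"], soil.psi["30cm"])

    # temperature on the grid (vectorized over depth)
    t_g = np.empty((grid.size, nt))
    for i, z in enumerate(grid):
        t_g[i] = soil_temperature(time, z, season, forcing.t_daily_anom)

    # production: base response on the grid + per-layer Birch pulse
    r0 = pp.r0_surface * np.exp(-grid / pp.efold_m)
    q10f = pp.q10 ** ((t_g - pp.t_ref_c) / 10.0)
    moist = moisture_factor(psi_g, pp.pf_max)
    pulse1 = birch_pulse_state(soil.theta["10cm"], soil.psi["10cm"], pp)
    pulse2 = birch_pulse_state(soil.theta["30cm"], soil.psi["30cm"], pp)
    pulse_g = _layer_to_grid(grid, pulse1, pulse2)
    production = r0[:, None] * q10f * (moist + pp.birch_gain * pulse_g)

    # diffusivity on the grid from the ground-truth models
    m10, m30 = truth_ds_model("10cm"), truth_ds_model("30cm")
    ds_g = np.where((grid <= LAYER1_BOTTOM + 1e-12)[:, None],
                    np.exp(m10.a + m10.b * th_g),
                    np.exp(m30.a + m30.b * th_g))

    t_air_k = forcing.t_air + 273.15
    c_air_conc = prep.ppm_to_mole_concentration(forcing.c_air, t_air_k,
                                                forcing.pressure)
    c, f0_true, diag = diffuse_profile(production, ds_g, grid, c_air_conc)

    i10 = int(np.argmin(np.abs(grid - 0.10)))
    i30 = int(np.argmin(np.abs(grid - 0.30)))
    c10, c30 = c[i10], c[i30]

    ppm10, sat10 = sensorize(c10, soil.t_soil["10cm"], forcing.pressure,
                             co2_noise_sd_ppm, seed=sub[1])
    ppm30, sat30 = sensorize(c30, soil.t_soil["30cm"], forcing.pressure,
                             co2_noise_sd_ppm, seed=sub[2])

    profile = pd.DataFrame({
        "co2_ppm_10cm": ppm10,
        "co2_ppm_30cm": ppm30,
        "co2_sat_10cm": sat10,
        "co2_sat_30cm": sat30,
        "theta_10cm": soil.theta["10cm"],
        "theta_30cm": soil.theta["30cm"],
        "psi_kpa_10cm": soil.psi["10cm"],
        "psi_kpa_30cm": soil.psi["30cm"],
        "tsoil_10cm": soil.t_soil["10cm"],
        "tsoil_30cm": soil.t_soil["30cm"],
        "pressure_kpa": forcing.pressure,
        "precip_mm": forcing.precip,
        "c_air_ppm": forcing.c_air,
    }, index=pd.Index(time, name="timestamp"))

    truth = SimulationTruth(
        grid=grid, production=production, f0_true=f0_true,
        ds_true={"10cm": ds_g[i10], "30cm": ds_g[i30]},
        c_true={"10cm": c10, "30cm": c30},
        diagnostics={**diag, "water_balance": soil.balance,
                     "water_table": soil.water_table,
                     "production_integral": np.sum(
                         production[1:] * GRID_DZ, axis=0)},
        seed=seed)
    return profile, truth
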