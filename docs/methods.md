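# Methods

This note documents the models, parameter choices and numerical decisions
behind `soilflux`, and what the synthetic validation does and does not
demonstrate about field data.

## 1. Gradient-method soil respiration

CO₂ produced by roots and microbes diffuses to the surface through the
air-filled pore space. With mole concentrations C (µmol m⁻³) at two depths
and an effective diffusivity Dₛ (m² s⁻¹), Fick's first law gives the flux
across the interval; depth is positive downward and flux positive upward.
The package evaluates F₅ from the atmospheric concentration and the 10 cm
sensor (interval midpoint 5 cm) and F₂₀ from the 10 and 30 cm sensors
(midpoint 20 cm), then extrapolates the flux profile linearly in depth to
the surface: F₀ = F₅ + (F₅ − F₂₀)·5/15. Linear extrapolation from two
points is exact when flux varies linearly with depth (uniform production)
and is biased low when production is concentrated near the surface — the
dominant term in the ~4 % low bias seen in the dynamic recovery study
(§6).

Sensor ppm readings are first corrected to a reference state (25 °C,
101.325 kPa) with the multiplicative ideal-gas form
χ_corr = χ_raw·(P_ref/P)·(T/T_ref). The instrument manual's exact
correction polynomial is proprietary; the ideal-gas form captures its
physical content and the reference constants are isolated in
`RunConfig` so an instrument-specific form can be substituted. Conversion
to mole concentration is C = χ·P/(R·T) with R = 8.3145 J mol⁻¹ K⁻¹.

Readings above the 115,000 ppm ceiling are *gap-filled at the ceiling* and
flagged, keeping the record continuous for spectral analysis; flux rows
built from gap-filled inputs carry a `saturated_input` flag and summary
statistics are reported with and without them. Missing (non-saturated)
samples are linearly interpolated across gaps of ≤ 2 h; longer gaps stay
flagged and are excluded from statistics.

Annual respiration averages F₀ by day of year first (a record longer than
one year would otherwise overweight the twice-sampled season), then
integrates: Σ(365 daily means)·86400 s·12.011×10⁻⁶ g C µmol⁻¹. Feb 29 is
folded into day 59.

## 2. Diffusivity calibration

A steady-state chamber feeds CO₂-rich gas (default 5 % CO₂) to the base of
an undisturbed core of length L while the top sits in lab air. At steady
state the through-core flux is the surface efflux minus the core's own
production, F_L = F₀ − Fₛ, so Dₛ = (F₀ − Fₛ)·L/(C_L − C₀). Repeating as
the core dries yields (θ, Dₛ) pairs fitted with the standard soil-gas
log-linear form ln Dₛ = a + b·θ, one model per sensor depth, valid on the
calibrated moisture range 0.04–0.38 cm³ cm⁻³; evaluation outside the range
clamps to it and raises a flag. For F₅ the 10 cm model is evaluated at
θ(10 cm); for F₂₀ the 30 cm model is evaluated at the mean of θ(10 cm) and
θ(30 cm) — the interval straddles both layers and the deeper model's
calibration cores bracket its midpoint.

## 3. The synthetic hyperseasonal simulator

The simulator produces half-hourly records with the statistical structure
the analysis assumes — hyperseasonal wet/dry forcing, wetting from above
and below, moisture- and temperature-driven production, diffusive
transport, and imperfect sensors — with full ground truth. Defaults (all
configurable dataclasses in `soilflux.synthetic`):

* **Rain** — marked Poisson: Bernoulli arrivals per half-hour with rate
  0.683 d⁻¹ (wet season, day-of-year 274–120) or 0.10 d⁻¹ (dry), and
  exponential depths of mean 8 mm (wet) / 6 mm (dry). Expected annual
  total 1250 mm with an extensive May–September dry season, the regime of
  the northern Pantanal.
* **Temperature** — annual (±1.5 °C) plus semiannual (±1.5 °C) harmonics
  around 25.5 °C, a ±5 °C diurnal wave, and a 1 °C-sd synoptic daily
  anomaly. Soil temperature damps the diurnal/synoptic components as
  exp(−z/0.15 m) with matching phase lag; the seasonal wave is essentially
  undamped at sensor depths.
* **Soil water** — two 0.2 m layers (sensors at their 10 and 30 cm
  midpoints). Infiltration (85 % of rain) splits 60/40 between layer 1
  (sharp rise) and a percolation store releasing into layer 2 with
  τ = 1.5 d (lagged, damped rise). Both layers drain to depth at
  k·Se³·(θ−θ_r) per day (k₁ = 0.30, k₂ = 0.15 d⁻¹): post-event drawdown is
  fast, the dry-season tail slow. Layer 1 additionally evaporates at
  5 mm d⁻¹·Se². With no rain both layers recede monotonically toward
  θ_r = 0.04. The annual flood is a prescribed water-table ramp (base 3 m,
  peak stage 0.12 m below the surface, day-of-year 121–165 with 12/20-day
  ramps); saturation is imposed from below through an exponential
  capillary fringe (e-fold 0.15 m), so the 30 cm depth saturates while
  10 cm stays just short of saturation. The paper-style flood stage record
  does not exist, so the ramp parameters are free choices; per-step water
  balance closes to round-off.
* **Retention** — van Genuchten (θ_r = 0.04, θ_s = 0.38, α = 0.5 kPa⁻¹,
  n = 1.5; a loamy-sand planosol A-horizon) with Kool–Parker hysteresis:
  the wetting branch doubles α, so at equal θ the wetting branch holds
  less tension. The branch is selected per step from the sign of Δθ. The
  parameters give a hyperseasonal pF swing from ~0 (flood) to ~3
  (late dry season).
* **Production** — R(z,t) = R₀·e^(−z/0.2 m) · Q10^((T−25)/10) ·
  max(0, 1 − pF/4.2) + Birch pulse, with R₀ = 30 µmol m⁻³ s⁻¹ at the
  surface and Q10 = 2. The moisture factor is the field's log-linear
  pF–respiration relationship with a cutoff at pF 4.2 (wilting) and is
  capped at 1 near saturation. The Birch (rewetting) pulse fires when θ
  rises by ≥ 0.005 after ≥ 10 days with pF > 2.5, adds 1.5× the local
  base rate, and decays with τ = 2 d. R₀ was chosen so the simulated mean
  efflux sits near the few-µmol m⁻² s⁻¹ magnitude typical of tropical
  soils.
* **Transport** — ∂C/∂t = ∂/∂z(Dₛ ∂C/∂z) + R on a 1 cm grid to 1 m depth,
  Crank–Nicolson (unconditionally stable, second order in space), top
  boundary fixed at the atmospheric mole concentration, zero-flux bottom.
  The ground-truth diffusivity uses the same exponential form as the
  calibration models with (a, b) = (−12.0, −11.0) at 10 cm and
  (−12.3, −12.0) at 30 cm: ~2–4×10⁻⁶ m² s⁻¹ in dry sand (≈0.2× the
  free-air value) falling to ~5×10⁻⁸–1.5×10⁻⁷ near saturation, so the
  flooded profile is diffusion-limited and the 30 cm sensor saturates —
  a few percent of its readings gap-fill at the ceiling, as observed in
  seasonally flooded records. The initial condition is the steady state of
  the first timestep's forcing, avoiding spin-up transients.
* **Sensors** — the true concentration is converted to in-situ ppm, the
  inverse of the ideal-gas correction applied, Gaussian noise (50 ppm sd)
  added per 30-s sub-reading, each sub-reading clipped at 115,000 ppm, and
  four sub-readings averaged per half hour (duty-cycled operation). A
  sample is flagged saturated when all sub-readings clip.

What the simulator does *not* emulate: lateral flow, plant CO₂ uptake,
advective or ebullitive gas transport, methane, sensor drift, and the
soil-specific shape of the true Dₛ(θ) (assumed exactly log-linear, so the
calibration fit is correctly specified by construction). Passing the
recovery tests therefore demonstrates the *chain's* correctness — units,
gradients, extrapolation, calibration, bookkeeping — not that the gradient
method is unbiased on soils whose diffusivity law deviates from the fitted
form.

## 4. Seasonal statistics

Factor analysis standardizes the eight half-hourly channels (CO₂, soil
temperature, θ, and tension at both depths), extracts two principal
components of the correlation matrix, and applies Kaiser varimax
(SVD-based iteration, convergence 10⁻⁶). Tension enters as pF: the kPa
series is so skewed in a hyperseasonal record that linear loadings become
uninterpretable. Both rotated and extraction (eigenvalue) variance shares
are reported; the extraction share is the null-structure diagnostic, since
varimax is degenerate on a single-factor solution and may split it across
columns. Factor signs are fixed so each factor's largest-magnitude loading
is positive. Monthly mean factor scores are clustered with k-means
(k = 3, 50 restarts, seeded); the highest-factor-1 (wettest) centroid is
labelled warm-wet and the remaining two split on factor 2 into warm-dry
and cool-dry.

Correlation tables are computed on half-hourly data by default (a flag
aggregates first), with tension in both kPa and pF as separate variables.

Hysteresis loops: daily-mean (x, y) trajectories are z-scored (so areas
are comparable across variable pairs) and the shoelace signed area of the
closed polygon is reported; positive = counterclockwise, |area| <
10⁻¹² = degenerate. Note the standardization makes the area unit
σ_x·σ_y-based, not the raw product unit.

## 5. Spectral analysis

**Wavelet coherence.** Morlet (ω₀ = 6) CWT via FFT, dyadic scales at 12
voices per octave from 2Δt. Cross- and auto-spectra are smoothed in time
with a scale-matched Gaussian (sd = s) and over scale with a 0.6-octave
boxcar before forming R² = |⟨W_xy/s⟩|²/(⟨|W_x|²/s⟩⟨|W_y|²/s⟩); without
smoothing, coherence is identically 1. Significance at α = 0.05 is
Monte Carlo: AR(1) surrogates fitted to each input (lag-1 autocorrelation
and variance), per-scale 95th percentile of in-cone coherence pooled over
time (thinned by one scale length to reduce autocorrelation in the null
pool). The reported mask is restricted to the cone of influence (e-folding
time √2·s). 300 surrogates by default; the pipeline uses 100, which
stabilizes the threshold to the second decimal.

**Nonparametric Granger causality.** Cross-spectral matrices are
multitaper estimates (DPSS, NW = 3, K = 5) averaged over 50 %-overlapping
segments (default length 1024 at half-hourly sampling ≈ 21 d). Wilson's
iterative factorization (tolerance 10⁻⁹, cap 500 iterations; the causal
projection halves the zero lag and truncates negative lags) yields
S = HΣH* with H minimum-phase; Σ is returned in variance units. Geweke's
pairwise causality onto target t from driver d uses the standard
partialization H̃_tt = H_tt + (Σ_td/Σ_tt)·H_td,
f_{d→t}(ω) = ln S_tt/(|H̃_tt|²Σ_tt). The conditional spectrum embeds the
reduced (target, conditioner) factorization G in the full 3-variable
system (identity row/column for the driver), forms Q = G⁻¹H per frequency,
decorrelates the remaining innovations from the target's, and evaluates
f_{d→t|c}(ω) = ln Σʳ_tt/(|Q̃_tt|²Σ_tt). On a chain x→z→y the conditional
spectrum suppresses the spurious pairwise x→y causality by >90 % while
direct couplings are preserved — the defining property of the method.
Frequencies are reported in cycles per day (daily = 1, 12 h = 2, 8 h = 3).

Factorization accuracy: on smooth (analytic) spectra the reconstruction
error is < 10⁻⁶; on estimated spectra the sampling ripple occupies all
representable lags and the error floor is ~10⁻³, which cancels in the
causality ratios because the reconstructed spectrum is used consistently.

**Significance for causality spectra.** The driver is circularly shifted
by a uniform random offset of at least one day (preserving its
autocorrelation, destroying cross-dependence) and the per-frequency
threshold is the order statistic of rank ⌈0.95(n+1)⌉ of n surrogate
spectra — with n = 39 the null rejection probability is exactly 5 % by
exchangeability. Magnitudes of causality spectra depend on estimator
settings (taper bandwidth, segment length) and are not comparable across
toolboxes; comparisons should stay within one configuration.

**Windows.** Seasonal causality runs on up-to-90-day windows taken from
the longest run of consecutively labelled months per cluster. Windows are
detrended and standardized; gaps ≤ 2 h are interpolated upstream, longer
gaps disqualify a window.

## 6. Validation summary

The test suite and `scripts/acceptance.py` verify, among others: exact
steady-state agreement of the diffusion solver with the closed-form
parabola and of pipeline F₀ with ∫R dz (two-point extrapolation is exact
for uniform production); daily-mean recovery of true F₀ on the 270-day
simulation with r ≈ 0.99 and ≈ −4 % bias; exact noise-free chamber
inversion and < 1 % Monte Carlo bias at 2 % measurement noise;
nonparametric causality within a few percent of the parametric value on a
VAR(1) oracle with > 90 % mediation suppression and a 5 ± 2.5 % null
rejection rate; and daily-band coherence detection with ≤ 10 % false-alarm
area on independent noise. Problem sizes (270–366-day simulations, n =
4096–8192 spectral series, 100–200 Monte Carlo replicates) were chosen so
the whole suite runs in minutes on one CPU while leaving the Monte Carlo
tolerances comfortably resolvable.

## 7. Known limitations

* The two-point surface extrapolation is systematically biased for
  strongly depth-concentrated production; a storage-term or multi-depth
  fit would reduce this.
* Gap-filling saturated readings at the ceiling biases the 30 cm
  concentration (hence F₂₀) low during floods; totals are reported with
  and without flagged rows.
* The retention model is unimodal van Genuchten with a two-branch
  hysteresis approximation, not a full scanning-curve model.
* Conditional causality spectra are estimates of different population
  quantities than pairwise ones and need not be smaller at every
  frequency.
* k-means season labels operationalize what is, in the field, a
  descriptive clustering; month-to-cluster assignments near boundaries
  are sensitive to the simulated year.
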