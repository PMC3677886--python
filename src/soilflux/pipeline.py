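"""End-to-end orchestration: simulate -> preprocess -> calibrate -> flux ->
seasonal statistics -> spectral causality, with a reproducible manifest."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from soilflux import io as sfio
from soilflux import preprocessing as prep
from soilflux import seasonal, spectral, synthetic
from soilflux.config import RunConfig
from soilflux.diffusivity import calibrate_from_runs
from soilflux.flux import annual_respiration, compute_fluxes

FACTOR_CHANNELS = [
    "co2_ppm_10cm", "co2_ppm_30cm",
    "tsoil_10cm", "tsoil_30cm",
    "theta_10cm", "theta_30cm",
    "pF_10cm", "pF_30cm",
]


def calibrate_models(seed: int, noise_sd: float = 0.02, n_points: int = 8):
    """Fit the per-depth Ds(theta) models from simulated chamber runs."""
    models = {}
    for i, depth in enumerate(("10cm", "30cm")):
        runs = synthetic.chamber_series(depth, fs=1.0, noise_sd=noise_sd,
                                        seed=seed + i,
                                        thetas=np.linspace(0.04, 0.38, n_points))
        models[depth] = calibrate_from_runs(runs, depth)
    return models


def table1_channels(pre: pd.DataFrame, fluxes: pd.DataFrame) -> pd.DataFrame:
    """Channel layout of the full correlation table (tension in kPa and pF)."""
    ok = fluxes["qc"] != prep.FLAG_MISSING
    return pd.DataFrame({
        "F0": fluxes.loc[ok, "f0"],
        "CO2_10cm": pre.loc[ok, "co2_ppm_10cm"],
        "CO2_30cm": pre.loc[ok, "co2_ppm_30cm"],
        "Tsoil_10cm": pre.loc[ok, "tsoil_10cm"],
        "Tsoil_30cm": pre.loc[ok, "tsoil_30cm"],
        "theta_10cm": pre.loc[ok, "theta_10cm"],
        "theta_30cm": pre.loc[ok, "theta_30cm"],
        "psi_kPa_10cm": pre.loc[ok, "psi_kpa_10cm"],
        "psi_kPa_30cm": pre.loc[ok, "psi_kpa_30cm"],
        "pF_10cm": pre.loc[ok, "pF_10cm"],
        "pF_30cm": pre.loc[ok, "pF_30cm"],
    })


def season_windows(labels: dict, index: pd.DatetimeIndex,
                   window_days: int = 90) -> dict:
    """Contiguous analysis window per season label from monthly clusters.

    For each label, the longest run of consecutively labelled months is
    found and at most ``window_days`` days from its start are returned.
    """
    months = sorted(labels)
    out = {}
    for lab in set(labels.values()):
        runs, cur = [], []
        for m in months:
            if labels[m] == lab:
                cur.append(m)
            elif cur:
                runs.append(cur)
                cur = []
        if cur:
            runs.append(cur)
        best = max(runs, key=len)
        start = best[0].to_timestamp()
        end = min(best[-1].to_timestamp(how="end"),
                  start + pd.Timedelta(days=window_days))
        sel = index[(index >= start) & (index < end)]
        out[lab] = (sel[0], sel[-1])
    return out


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full analysis and write artifacts under ``out_dir``.

    Stages: simulate, preprocess, calibrate-ds, flux, seasons, spectral.
    Any stage failure raises with a stage-labelled message.  Returns the
    summary dictionary (also written as ``summary.json``).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    subseeds = {k: int(rng.integers(0, 2**31 - 1))
                for k in ("simulate", "calibrate", "cluster", "wavelet", "gc")}
    summary: dict = {"seed": config.seed, "config_hash":
                     sfio.config_hash(config.to_dict())}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") \
                        from exc
        return _Ctx()

    with stage("simulate"):
        profile, truth = synthetic.simulate(
            days=config.days, seed=subseeds["simulate"], start=config.start,
            flood_window=config.flood_window_doy)
        sfio.write_profile_csv(profile, out / "profile.csv")
        truth_df = pd.DataFrame(
            {"f0_true": truth.f0_true,
             "production_integral": truth.diagnostics["production_integral"]},
            index=profile.index)
        sfio.write_profile_csv(truth_df, out / "truth.csv")

    with stage("preprocess"):
        pre, qc = prep.preprocess(profile, range_max=config.co2_ceiling_ppm)
        sfio.write_profile_csv(pre, out / "preprocessed.csv")
        summary["qc"] = qc

    with stage("calibrate-ds"):
        models = calibrate_models(subseeds["calibrate"])
        sfio.write_json({d: {"a": m.a, "b": m.b, "r_squared": m.r_squared,
                             "theta_range": list(m.theta_range)}
                         for d, m in models.items()}, out / "ds_models.json")

    with stage("flux"):
        fluxes = compute_fluxes(pre, models["10cm"], models["30cm"])
        sfio.write_profile_csv(fluxes, out / "flux.csv")
        ok = fluxes["qc"] != prep.FLAG_MISSING
        summary["mean_f0_umol_m2_s"] = float(fluxes.loc[ok, "f0"].mean())
        summary["saturated_input_fraction"] = float(
            (fluxes["qc"] == "saturated_input").mean())
        try:
            summary["annual_respiration_gC_m2_y"] = annual_respiration(
                fluxes.loc[ok, "f0"])
        except ValueError:
            summary["annual_respiration_gC_m2_y"] = None  # < 1 y of coverage

    with stage("seasons"):
        channels = table1_channels(pre, fluxes)
        r, p = seasonal.correlation_matrix(channels)
        r.to_csv(out / "correlations.csv", float_format="%.3f")
        fac = seasonal.factor_varimax(pre[FACTOR_CHANNELS], n_factors=2)
        fac.loadings.to_csv(out / "factor_loadings.csv", float_format="%.4f")
        monthly = seasonal.monthly_scores(fac)
        labels = seasonal.cluster_months(monthly, k=3, seed=subseeds["cluster"])
        sfio.write_json({str(m): lab for m, lab in labels.items()},
                        out / "clusters.json")
        summary["factor_variance_pct"] = [
            round(100 * v, 2) for v in fac.variance_explained]
        summary["cluster_labels"] = {str(m): lab for m, lab in labels.items()}

    with stage("spectral"):
        ok_idx = fluxes.index[fluxes["qc"] != prep.FLAG_MISSING]
        f0 = fluxes.loc[ok_idx, "f0"].to_numpy()
        pf = pre.loc[ok_idx, "pF_10cm"].to_numpy()
        ts = pre.loc[ok_idx, "tsoil_10cm"].to_numpy()
        wc_t = spectral.wavelet_coherence(
            f0, ts, dt=0.5, n_surrogates=config.wavelet_surrogates,
            seed=subseeds["wavelet"])
        wc_p = spectral.wavelet_coherence(
            f0, pf, dt=0.5, n_surrogates=config.wavelet_surrogates,
            seed=subseeds["wavelet"] + 1)
        for name, wc in (("coherence_f0_tsoil", wc_t), ("coherence_f0_pf", wc_p)):
            _write_coherence_csv(wc, out / f"{name}.csv")
        summary["daily_band_significant_fraction_f0_tsoil"] = \
            daily_band_significant_fraction(wc_t)
        summary["daily_band_significant_fraction_f0_pf"] = \
            daily_band_significant_fraction(wc_p)

        windows = season_windows(labels, ok_idx,
                                 window_days=config.season_window_days)
        gc_rows = []
        for lab, (t0, t1) in sorted(windows.items()):
            sel = (ok_idx >= t0) & (ok_idx <= t1)
            if sel.sum() < 2 * config.gc_segment:
                continue
            args = dict(dt_hours=0.5, nperseg=config.gc_segment)
            g_pf = spectral.granger_spectrum(f0[sel], pf[sel], ts[sel],
                                             window_label=lab, **args)
            g_ts = spectral.granger_spectrum(f0[sel], ts[sel], pf[sel],
                                             window_label=lab, **args)
            for drv, g in (("pF", g_pf), ("Tsoil", g_ts)):
                gc_rows.append(pd.DataFrame({
                    "season": lab, "driver": drv,
                    "freq_cpd": g.frequencies,
                    "gc_pairwise": g.gc_pairwise["driver->target"],
                    "gc_conditional":
                        g.gc_conditional["driver->target|conditioner"],
                }))
            summary[f"gc_daily_{lab}"] = {
                "pF->F0|Ts": _band_value(g_pf, 1.0),
                "Ts->F0|pF": _band_value(g_ts, 1.0),
            }
        if gc_rows:  # windows long enough for spectral estimation
            pd.concat(gc_rows).to_csv(out / "granger_spectra.csv", index=False)

    sfio.write_json(summary, out / "summary.json")
    sfio.write_json({"seed": config.seed, "subseeds": subseeds,
                     "config": config.to_dict()}, out / "manifest.json")
    return summary


def _write_coherence_csv(wc, path) -> None:
    """Long-format coherence map: one row per (period, time) cell."""
    sc, t = np.meshgrid(wc.periods, wc.times, indexing="ij")
    pd.DataFrame({
        "period_h": sc.ravel(), "time_h": t.ravel(),
        "coherence": wc.coherence.ravel(),
        "phase": wc.phase.ravel(),
        "significant": wc.significance_mask.ravel(),
    }).to_csv(path, index=False, float_format="%.4g")


def daily_band_significant_fraction(wc, period_h: float = 24.0) -> float:
    """Fraction of in-COI time significant at the scale nearest ``period_h``."""
    i = int(np.argmin(np.abs(wc.periods - period_h)))
    in_coi = wc.periods[i] <= wc.coi
    if not in_coi.any():
        return float("nan")
    return float(wc.significance_mask[i, in_coi].mean())


def _band_value(g, freq_cpd: float) -> float:
    spec = g.gc_conditional["driver->target|conditioner"]
    i = int(np.argmin(np.abs(g.frequencies - freq_cpd)))
    return float(spec[i])
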