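"""Climate generator, bucket hydrology, retention, production and diffusion."""

import numpy as np
import pandas as pd
import pytest

from soilflux import preprocessing as prep
from soilflux import synthetic as syn


class TestGenClimate:
    def test_deterministic_under_seed(self):
        a = syn.gen_climate(10, seed=42)
        b = syn.gen_climate(10, seed=42)
        assert np.array_equal(a.precip, b.precip)
        assert np.array_equal(a.t_air, b.t_air)
        assert np.array_equal(a.pressure, b.pressure)

    def test_zero_intensity_gives_zero_rain(self):
        season = syn.SeasonParams(wet_rate_per_day=0.0, dry_rate_per_day=0.0)
        f = syn.gen_climate(30, season, seed=0)
        assert np.all(f.precip == 0.0)

    def test_annual_total_within_3_sigma_of_analytic_mean(self):
        season = syn.SeasonParams()
        mean, var = syn.expected_annual_rain(season)
        assert mean == pytest.approx(1250, rel=0.01)
        totals = [syn.gen_climate(365, season, seed=s).precip.sum()
                  for s in range(5)]
        sd = np.sqrt(var)
        for tot in totals:
            assert abs(tot - mean) < 3 * sd

    def test_invariants(self):
        f = syn.gen_climate(5, seed=3)
        assert np.all(np.diff(f.time.to_numpy())
                      == np.timedelta64(30, "m"))
        assert np.all((f.pressure > 80) & (f.pressure < 110))

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            syn.gen_climate(0)
        with pytest.raises(ValueError):
            syn.gen_climate(5, syn.SeasonParams(wet_start_doy=400))


class TestSoilWater:
    def test_pure_recession_is_monotone_nonincreasing(self):
        season = syn.SeasonParams(wet_rate_per_day=0.0, dry_rate_per_day=0.0)
        f = syn.gen_climate(60, season, seed=1)
        s = syn.soil_water_forward(f, flood_window=None)
        for d in ("10cm", "30cm"):
            assert np.all(np.diff(s.theta[d]) <= 1e-15)

    def test_single_large_event_shallow_peak_precedes_deep(self):
        season = syn.SeasonParams(wet_rate_per_day=0.0, dry_rate_per_day=0.0)
        f = syn.gen_climate(40, season, seed=1)
        f.precip[10 * 48] = 130.0  # one 130 mm storm on day 10
        s = syn.soil_water_forward(f, flood_window=None)
        assert np.argmax(s.theta["10cm"]) < np.argmax(s.theta["30cm"])

    def test_water_balance_closes(self):
        f = syn.gen_climate(90, seed=5, start="2009-03-01")
        s = syn.soil_water_forward(f, flood_window=(121, 158))
        b = s.balance
        rhs = (b["infiltration"] - b["excess"] - b["deep_drainage"]
               - b["evaporation"] + b["flood_supply"]).sum()
        lhs = b["storage"][-1] - b["initial_storage"]
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-12)

    def test_flood_saturates_deep_layer_first(self):
        season = syn.SeasonParams(wet_rate_per_day=0.0, dry_rate_per_day=0.0)
        f = syn.gen_climate(80, season, seed=2, start="2009-04-15")
        s = syn.soil_water_forward(f, flood_window=(121, 158))
        wp = syn.WaterParams()
        sat30 = s.theta["30cm"] >= wp.theta_s - 1e-9
        assert sat30.any()
        assert not (s.theta["10cm"] >= wp.theta_s - 1e-9).any()

    def test_rejects_bad_params(self):
        f = syn.gen_climate(2, seed=0)
        with pytest.raises(ValueError):
            syn.soil_water_forward(
                f, params=syn.WaterParams(theta_s=0.04, theta_r=0.38))
        with pytest.raises(ValueError):
            syn.soil_water_forward(
                f, params=syn.WaterParams(k1_per_day=-0.1))


class TestRetention:
    def test_saturation_gives_zero_potential(self):
        vg = syn.VanGenuchten()
        assert syn.retention(vg.theta_s, vg, "drying") == 0.0
        assert syn.retention(vg.theta_s, vg, "wetting") == 0.0

    def test_wetting_branch_holds_less_tension(self):
        vg = syn.VanGenuchten()
        th = 0.2
        assert abs(syn.retention(th, vg, "wetting")) < \
            abs(syn.retention(th, vg, "drying"))
        # Kool-Parker alpha scaling: psi_wet = psi_dry / factor exactly
        assert syn.retention(th, vg, "wetting") == pytest.approx(
            syn.retention(th, vg, "drying") / vg.wetting_alpha_factor)

    @pytest.mark.parametrize("branch", ["wetting", "drying"])
    def test_roundtrip_same_branch(self, branch):
        vg = syn.VanGenuchten()
        theta = np.linspace(0.05, 0.37, 20)
        psi = syn.retention(theta, vg, branch)
        back = syn.theta_from_psi(psi, vg, branch)
        assert np.allclose(back, theta, atol=1e-8)

    def test_strictly_increasing_in_theta(self):
        vg = syn.VanGenuchten()
        theta = np.linspace(0.045, 0.38, 200)
        psi = syn.retention(theta, vg, "drying")
        assert np.all(np.diff(psi) > 0)
        assert np.all(psi <= 0)

    def test_rejects_invalid(self):
        vg = syn.VanGenuchten()
        with pytest.raises(ValueError):
            syn.retention(0.5, vg, "drying")
        with pytest.raises(ValueError):
            syn.VanGenuchten(n=0.9)
        with pytest.raises(ValueError):
            syn.retention(0.2, vg, "sideways")


class TestProduction:
    def test_moisture_shutoff_beyond_pf_max(self):
        pp = syn.ProductionParams()
        psi_dry = -10 ** pp.pf_max / prep.KPA_TO_CM_HEAD * 1.5  # pF > pF_max
        assert syn.production_rate(25.0, psi_dry, 0.05, pp) == 0.0

    def test_q10_doubling(self):
        pp = syn.ProductionParams(q10=2.0)
        r1 = syn.production_rate(20.0, -1.0, 0.05, pp)
        r2 = syn.production_rate(30.0, -1.0, 0.05, pp)
        assert r2 / r1 == pytest.approx(2.0, rel=1e-12)

    def test_birch_pulse_only_after_dry_spell(self):
        pp = syn.ProductionParams(antecedent_dry_steps=48 * 5,
                                  dry_pf=2.5, rewet_dtheta=0.01)
        vg = syn.VanGenuchten()
        n = 48 * 12
        # dry path: 10 dry days then a sharp rewet
        th_dry = np.full(n, 0.055)
        th_dry[48 * 10:] = 0.20
        psi_dry = syn.retention(th_dry, vg, "drying")
        r_dry = syn.production_rate(np.full(n, 25.0), psi_dry, 0.05, pp,
                                    theta=th_dry)
        base_dry = syn.production_rate(np.full(n, 25.0), psi_dry, 0.05, pp)
        # continuously wet control, same rewet step
        th_wet = np.full(n, 0.25)
        th_wet[48 * 10:] = 0.30
        psi_wet = syn.retention(th_wet, vg, "drying")
        r_wet = syn.production_rate(np.full(n, 25.0), psi_wet, 0.05, pp,
                                    theta=th_wet)
        base_wet = syn.production_rate(np.full(n, 25.0), psi_wet, 0.05, pp)
        assert np.any(r_dry > base_dry + 1e-12)      # pulse fired
        assert np.allclose(r_wet, base_wet)          # no pulse when never dry
        assert np.all(r_dry[:48 * 10] == base_dry[:48 * 10])

    def test_rejects_negative_r0(self):
        with pytest.raises(ValueError):
            syn.ProductionParams(r0_surface=-1.0)


class TestDiffuseProfile:
    def setup_method(self):
        self.grid = np.arange(0.0, 1.0001, 0.01)

    def test_equilibrium_with_no_production(self):
        nz = self.grid.size
        c_air = 1.6e4
        c, f0, _ = syn.diffuse_profile(np.zeros((nz, 20)), np.full(nz, 1e-6),
                                       self.grid, c_air, c_init=c_air)
        assert np.allclose(c, c_air)
        assert np.allclose(f0, 0.0, atol=1e-9)

    def test_steady_state_matches_closed_form_parabola(self):
        nz = self.grid.size
        R, Ds, c_air, L = 5.0, 1e-6, 1.6e4, 1.0
        c, f0, _ = syn.diffuse_profile(np.full((nz, 10), R),
                                       np.full(nz, Ds), self.grid, c_air)
        exact = c_air + (R / Ds) * (L * self.grid - self.grid**2 / 2)
        assert np.max(np.abs(c[:, -1] - exact) / exact) < 5e-3
        # surface flux equals the depth-integrated production
        assert f0[-1] == pytest.approx(R * L, rel=0.01)

    def test_mass_conservation_through_transient(self):
        nz = self.grid.size
        rng = np.random.default_rng(0)
        nt = 200
        production = 2.0 + rng.random((nz, nt))
        ds = np.full(nz, 5e-7)
        c, f0, diag = syn.diffuse_profile(production, ds, self.grid, 1.6e4)
        lhs = diag["storage"][-1] - diag["storage"][0]
        rhs = diag["cum_production"][-1] - diag["cum_surface"][-1]
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_rejects_bad_inputs(self):
        nz = self.grid.size
        with pytest.raises(ValueError):
            syn.diffuse_profile(np.zeros((nz, 5)), np.full(nz, -1e-6),
                                self.grid, 1e4)
        with pytest.raises(ValueError):
            syn.diffuse_profile(np.zeros((5, 5)), np.full(5, 1e-6),
                                np.array([0.0, 0.2, 0.1, 0.3, 0.4]), 1e4)


class TestChamberSim:
    def test_fick_arithmetic(self):
        run = syn.chamber_sim(2.5e-7, L=0.1, fs=0.6)
        assert run.f0 == pytest.approx(
            2.5e-7 * (run.cL - run.c0) / 0.1 + 0.6, rel=1e-12)
        assert run.cL > run.c0 and run.f0 >= run.fs >= 0

    def test_noise_free_roundtrip_is_exact(self):
        from soilflux.diffusivity import ds_from_chamber
        run = syn.chamber_sim(1e-6, fs=1.0)
        assert ds_from_chamber(run) == pytest.approx(1e-6, rel=1e-14)

    def test_monte_carlo_bias_below_one_percent(self):
        from soilflux.diffusivity import ds_from_chamber
        est = [ds_from_chamber(syn.chamber_sim(2.5e-7, noise_sd=0.02, seed=s))
               for s in range(100)]
        assert abs(np.mean(est) - 2.5e-7) / 2.5e-7 < 0.01

    def test_rejects_nonpositive_ds(self):
        with pytest.raises(ValueError):
            syn.chamber_sim(0.0)


class TestSensorize:
    def test_saturation_at_range_max(self):
        conc = prep.ppm_to_mole_concentration(
            np.array([130000.0, 90000.0]), 298.15, 101.325)
        ppm, sat = syn.sensorize(conc, np.full(2, 25.0), np.full(2, 101.325))
        assert ppm[0] == 115000.0 and sat[0]
        assert not sat[1]

    def test_wet_season_peak_scenario_reports_saturated_fraction(self, sim270):
        profile, _ = sim270
        frac = float(profile["co2_sat_30cm"].mean())
        assert 0.0 < frac < 0.2

    def test_simulation_reproducible_bit_for_bit(self):
        a, _ = syn.simulate(days=8, seed=11)
        b, _ = syn.simulate(days=8, seed=11)
        pd.testing.assert_frame_equal(a, b)
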