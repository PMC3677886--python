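"""Multitaper CSD, Wilson factorization, Granger spectra, wavelet coherence."""

import numpy as np
import pytest

from soilflux import spectral as sp
from _oracles import parametric_gc, simulate_var

A_COUPLED = np.array([[0.5, 0.0], [0.5, 0.5]])   # x drives y
SIG_COUPLED = np.diag([1.0, 0.64])


class TestCsdMatrix:
    def test_white_noise_flat_diagonal(self, rng):
        n = 16384
        x = rng.normal(0, 1.5, n)
        y = rng.normal(0, 1.5, n)
        freqs, S = sp.csd_matrix([x, y], fs=1.0, nperseg=512)
        nyquist = 0.5
        expected = 1.5**2 / nyquist  # one-sided density of white noise
        assert np.median(S[:, 0, 0].real) == pytest.approx(expected, rel=0.1)
        assert np.abs(S[5:-5, 0, 1]).mean() < 0.2 * expected

    def test_hermitian_at_every_frequency(self, rng):
        x = rng.normal(0, 1, 2048)
        y = np.roll(x, 3) + rng.normal(0, 1, 2048)
        _, S = sp.csd_matrix([x, y], nperseg=256)
        assert np.allclose(S, np.conj(np.swapaxes(S, 1, 2)))
        # positive semi-definite
        evals = np.linalg.eigvalsh(S)
        assert evals.min() > -1e-12

    def test_parseval_variance_bookkeeping(self, rng):
        x = simulate_var(A_COUPLED, SIG_COUPLED, 8192, seed=3)[1]
        freqs, S = sp.csd_matrix([x], fs=1.0, nperseg=1024)
        df = freqs[1] - freqs[0]
        integral = np.trapezoid(S[:, 0, 0].real, dx=df)
        assert integral == pytest.approx(np.var(x), rel=0.05)

    def test_segment_longer_than_series_rejected(self, rng):
        with pytest.raises(ValueError):
            sp.csd_matrix([rng.normal(0, 1, 100)], nperseg=256)


class TestWilsonFactorization:
    def test_white_noise_identity_transfer(self, rng):
        x = rng.normal(0, 2.0, 65536)
        y = rng.normal(0, 1.0, 65536)
        _, S = sp.csd_matrix([x, y], fs=1.0, nperseg=256)
        H, sigma, info = sp.wilson_factorization(S, fs=1.0)
        # H fluctuates around the identity with the PSD estimator's ripple
        assert np.mean(np.abs(H - np.eye(2))) < 0.05
        assert np.max(np.abs(H - np.eye(2))) < 0.25
        assert sigma[0, 0] == pytest.approx(4.0, rel=0.1)
        assert sigma[1, 1] == pytest.approx(1.0, rel=0.1)
        assert abs(sigma[0, 1]) < 0.1

    def test_var_innovation_covariance_recovered(self):
        x = simulate_var(A_COUPLED, SIG_COUPLED, 65536, seed=5)
        _, S = sp.csd_matrix([x[0], x[1]], fs=1.0, nperseg=1024)
        _, sigma, _ = sp.wilson_factorization(S, fs=1.0)
        assert sigma[0, 0] == pytest.approx(SIG_COUPLED[0, 0], rel=0.02)
        assert sigma[1, 1] == pytest.approx(SIG_COUPLED[1, 1], rel=0.02)

    def test_reconstruction_exact_on_analytic_var_spectrum(self):
        """On a smooth (exactly known) spectral matrix the factorization
        reproduces S to near machine precision."""
        from _oracles import var_spectral_matrix
        freqs = np.linspace(0.0, 0.5, 257)
        S2side = var_spectral_matrix(A_COUPLED, SIG_COUPLED, freqs)
        S1side = S2side.copy()
        S1side[1:-1] *= 2.0  # package one-sided density convention, fs = 1
        H, sigma, info = sp.wilson_factorization(S1side, fs=1.0)
        assert info["relative_error"] < 1e-6
        assert np.allclose(sigma, SIG_COUPLED, atol=1e-4)

    def test_reconstruction_error_modest_on_estimated_spectrum(self):
        """Estimated spectra carry sampling ripple at all representable lags;
        the factorization reproduces them to the ripple floor."""
        x = simulate_var(A_COUPLED, SIG_COUPLED, 8192, seed=6)
        _, S = sp.csd_matrix([x[0], x[1]], fs=1.0, nperseg=512)
        *_, info = sp.wilson_factorization(S, fs=1.0)
        assert info["relative_error"] < 1e-2


class TestGrangerSpectra:
    def test_independent_white_noise_gc_near_zero(self, rng):
        x = rng.normal(0, 1, 4096)
        y = rng.normal(0, 1, 4096)
        res = sp.spectral_gc_bivariate(x, y, fs=1.0, nperseg=512)
        assert res["gc_xy"].mean() < 0.05
        assert res["gc_yx"].mean() < 0.05

    def test_var_oracle_within_15_percent(self):
        x = simulate_var(A_COUPLED, SIG_COUPLED, 4096, seed=11)
        res = sp.spectral_gc_bivariate(x[0], x[1], fs=1.0, nperseg=512)
        par = parametric_gc(A_COUPLED, SIG_COUPLED, res["freqs"],
                            target=1, driver=0)
        assert res["gc_xy"].mean() == pytest.approx(par.mean(), rel=0.15)
        assert res["gc_yx"].mean() < 0.25 * par.mean()

    def test_convergence_to_parametric_value_with_n(self):
        errs = []
        for n in (1024, 4096, 16384):
            gcs = []
            for seed in range(6):
                x = simulate_var(A_COUPLED, SIG_COUPLED, n, seed=100 + seed)
                res = sp.spectral_gc_bivariate(x[0], x[1], fs=1.0, nperseg=256)
                gcs.append(res["gc_xy"].mean())
            par = parametric_gc(A_COUPLED, SIG_COUPLED, res["freqs"],
                                target=1, driver=0).mean()
            errs.append(abs(np.mean(gcs) - par))
        assert errs[2] < errs[0]
        assert errs[2] < 0.1 * par

    def test_total_interdependence_decomposition(self):
        """GC both ways + instantaneous equals the coherence-based total."""
        x = simulate_var(A_COUPLED, SIG_COUPLED, 8192, seed=12)
        res = sp.spectral_gc_bivariate(x[0], x[1], fs=1.0, nperseg=512)
        _, S = sp.csd_matrix([x[0], x[1]], fs=1.0, nperseg=512)
        coh2 = np.abs(S[:, 0, 1])**2 / (S[:, 0, 0].real * S[:, 1, 1].real)
        total_coh = -np.log(1 - np.clip(coh2, 0, 1 - 1e-12))
        lhs = res["gc_xy"] + res["gc_yx"] + res["instantaneous"]
        keep = total_coh > 0.05  # avoid 0/0 at incoherent frequencies
        assert np.allclose(lhs[keep], total_coh[keep], rtol=0.05)

    def test_conditional_suppresses_mediated_coupling(self, rng):
        n = 8192
        x, z, y = np.zeros((3, n))
        ex, ez, ey = rng.normal(0, 1, (3, n))
        for t in range(1, n):
            x[t] = 0.5 * x[t - 1] + ex[t]
            z[t] = 0.5 * z[t - 1] + 0.6 * x[t - 1] + ez[t]
            y[t] = 0.5 * y[t - 1] + 0.6 * z[t - 1] + ey[t]
        pair = sp.spectral_gc_bivariate(x, y, fs=1.0, nperseg=512)
        cond = sp.spectral_gc_conditional(y, x, z, fs=1.0, nperseg=512)
        assert cond["gc"].mean() < 0.2 * pair["gc_xy"].mean()

    def test_conditional_preserves_direct_coupling(self, rng):
        n = 8192
        x, z, y = np.zeros((3, n))
        ex, ez, ey = rng.normal(0, 1, (3, n))
        for t in range(1, n):
            x[t] = 0.5 * x[t - 1] + ex[t]
            z[t] = 0.5 * z[t - 1] + ez[t]
            y[t] = 0.5 * y[t - 1] + 0.5 * x[t - 1] + ey[t]
        pair = sp.spectral_gc_bivariate(x, y, fs=1.0, nperseg=512)
        cond = sp.spectral_gc_conditional(y, x, z, fs=1.0, nperseg=512)
        assert cond["gc"].mean() > 0.7 * pair["gc_xy"].mean()

    def test_conditioner_identical_to_driver_rejected(self, rng):
        x = rng.normal(0, 1, 1024)
        y = rng.normal(0, 1, 1024)
        with pytest.raises(ValueError):
            sp.spectral_gc_conditional(y, x, x, nperseg=256)

    def test_frequencies_in_cycles_per_day(self, rng):
        res = sp.granger_spectrum(rng.normal(0, 1, 2048),
                                  rng.normal(0, 1, 2048),
                                  dt_hours=0.5, nperseg=512)
        assert res.frequencies.max() == pytest.approx(24.0)  # Nyquist, cpd
        assert np.all(res.gc_pairwise["driver->target"] >= 0)


class TestGcSignificance:
    def test_threshold_positive_everywhere(self, rng):
        x = rng.normal(0, 1, 2048)
        y = rng.normal(0, 1, 2048)
        thr = sp.gc_significance(y, x, dt_hours=0.5, n_surrogates=25,
                                 seed=0, nperseg=256)
        assert np.all(thr > 0)

    def test_too_few_surrogates_rejected(self, rng):
        with pytest.raises(ValueError):
            sp.gc_significance(rng.normal(0, 1, 512), rng.normal(0, 1, 512),
                               n_surrogates=10)

    def test_coupled_var_exceeds_threshold(self):
        x = simulate_var(A_COUPLED, SIG_COUPLED, 4096, seed=21)
        res = sp.granger_spectrum(x[1], x[0], dt_hours=0.5, nperseg=512)
        thr = sp.gc_significance(x[1], x[0], dt_hours=0.5, n_surrogates=39,
                                 seed=2, nperseg=512)
        # the AR(1) coupling concentrates at low frequency
        low = res.frequencies < res.frequencies.max() / 4
        assert (res.gc_pairwise["driver->target"][low] > thr[low]).mean() > 0.9


class TestWaveletCoherence:
    def test_self_coherence_is_one_inside_coi(self, rng):
        x = rng.normal(0, 1, 2048) + np.sin(np.arange(2048) / 20)
        wc = sp.wavelet_coherence(x, x, dt=0.5, n_surrogates=20, seed=0)
        in_coi = wc.periods[:, None] <= wc.coi[None, :]
        assert wc.coherence[in_coi].min() > 0.99

    def test_invariant_to_linear_rescaling(self, rng):
        x = rng.normal(0, 1, 1024)
        y = rng.normal(0, 1, 1024) + 0.5 * x
        a = sp.wavelet_coherence(x, y, dt=0.5, n_surrogates=20, seed=3)
        b = sp.wavelet_coherence(5.0 * x + 2.0, -3.0 * y, dt=0.5,
                                 n_surrogates=20, seed=3)
        assert np.allclose(a.coherence, b.coherence, atol=1e-10)

    def test_rejects_nan_and_unequal_length(self, rng):
        x = rng.normal(0, 1, 512)
        with pytest.raises(ValueError):
            sp.wavelet_coherence(x, x[:-1], dt=0.5, n_surrogates=20)
        y = x.copy()
        y[10] = np.nan
        with pytest.raises(ValueError):
            sp.wavelet_coherence(x, y, dt=0.5, n_surrogates=20)
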