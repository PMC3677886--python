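"""Independent oracles used by the tests (kept separate from the package).

The parametric Geweke spectra here are computed directly from known VAR
coefficients, providing a route to the same quantities that never touches
the package's multitaper/Wilson implementation.
"""

from __future__ import annotations

import numpy as np


def simulate_var(A, Sig, n, seed, burn=500):
    """Simulate a stationary VAR(1) x_t = A x_{t-1} + e_t, e ~ N(0, Sig)."""
    A = np.asarray(A, dtype=float)
    Sig = np.asarray(Sig, dtype=float)
    m = A.shape[0]
    rng = np.random.default_rng(seed)
    e = rng.multivariate_normal(np.zeros(m), Sig, n + burn)
    x = np.zeros((n + burn, m))
    for t in range(1, n + burn):
        x[t] = A @ x[t - 1] + e[t]
    return x[burn:].T


def var_spectral_matrix(A, Sig, freqs):
    """Exact spectral density of a VAR(1) vs normalized frequency (fs = 1).

    Two-sided density: S(f) = H Sig H* with H = (I - A e^{-i 2 pi f})^{-1}.
    """
    A = np.asarray(A, dtype=float)
    m = A.shape[0]
    out = np.empty((len(freqs), m, m), dtype=complex)
    eye = np.eye(m)
    for i, f in enumerate(np.asarray(freqs, dtype=float)):
        H = np.linalg.inv(eye - A * np.exp(-2j * np.pi * f))
        out[i] = H @ Sig @ H.conj().T
    return out


def parametric_gc(A, Sig, freqs, target: int, driver: int):
    """Geweke spectral causality driver->target from true VAR(1) parameters."""
    A = np.asarray(A, dtype=float)
    Sig = np.asarray(Sig, dtype=float)
    m = A.shape[0]
    eye = np.eye(m)
    out = np.empty(len(freqs))
    for i, f in enumerate(np.asarray(freqs, dtype=float)):
        H = np.linalg.inv(eye - A * np.exp(-2j * np.pi * f))
        S = H @ Sig @ H.conj().T
        h_tt = H[target, target] + (Sig[target, driver] / Sig[target, target]) \
            * H[target, driver]
        out[i] = np.log(S[target, target].real
                        / (abs(h_tt) ** 2 * Sig[target, target]))
    return out
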