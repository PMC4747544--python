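"""MCMC chain diagnostics."""

from __future__ import annotations

import warnings

import numpy as np


def compute_ess(trace) -> float:
    """Effective sample size via Geyer's initial-positive-sequence estimator.

    Autocovariances are estimated by FFT; successive pairs
    ``Gamma_k = rho(2k) + rho(2k+1)`` are summed while positive, giving the
    integrated autocorrelation time.  The ESS is capped at the trace length;
    a constant trace has no autocorrelation information, and by convention
    its ESS is defined as the trace length (with a warning).
    """
    x = np.asarray(trace, float)
    n = x.size
    if n < 10:
        raise ValueError("trace too short for ESS estimation (need >= 10)")
    v = x.var()
    if v == 0:
        warnings.warn("constant trace: ESS defined as trace length",
                      stacklevel=2)
        return float(n)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    tau = -1.0  # accumulates 2*sum(rho) starting from rho_0 = 1
    k = 0
    while 2 * k + 1 < n:
        gamma = rho[2 * k] + rho[2 * k + 1]
        if gamma <= 0:
            break
        tau += 2.0 * gamma
        k += 1
    tau = max(tau, 1.0)
    return float(min(n, n / tau))
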