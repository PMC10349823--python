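"""Convergence diagnostics and design checks for the Gibbs samplers.

Gelman–Rubin here is the *split* potential scale reduction factor computed on
plain (not rank-normalized) draws: each chain is halved, so m chains
contribute 2m sequences; R̂ = sqrt(((n−1)/n · W + B/n) / W).  Constant chains
return 1 by convention (zero variance everywhere).

Effective sample size uses the chain-averaged autocorrelation function with
Geyer's initial-positive-sequence truncation: ESS = m·n / (1 + 2 Σ ρ_t),
summing ρ over lags until the first negative paired (even, odd) sum.  A
constant chain reports ESS 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["gelman_rubin", "effective_sample_size", "variance_inflation_factors"]


def _as_chains(draws: np.ndarray) -> np.ndarray:
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 1:
        draws = draws[None, :]
    if draws.ndim != 2:
        raise ValueError("draws must be (n_chains, n_draws)")
    return draws


def gelman_rubin(draws: np.ndarray) -> float:
    """Split-R̂ for one scalar parameter given (n_chains, n_draws) draws."""
    chains = _as_chains(draws)
    if chains.shape[0] < 2:
        raise ValueError("Gelman-Rubin needs at least 2 chains")
    n = chains.shape[1] // 2
    if n < 2:
        raise ValueError("chains too short to split")
    halves = np.concatenate([chains[:, :n], chains[:, -n:]], axis=0)
    within = halves.var(axis=1, ddof=1).mean()
    if within == 0:
        return 1.0
    between = n * halves.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def effective_sample_size(draws: np.ndarray) -> float:
    """Autocorrelation-based ESS pooled over chains (Geyer truncation)."""
    chains = _as_chains(draws)
    m, n = chains.shape
    if n < 100:
        raise ValueError("need at least 100 draws per chain for a stable ESS")
    centred = chains - chains.mean(axis=1, keepdims=True)
    var = centred.var(axis=1, ddof=0).mean()
    if var == 0:
        return 0.0
    # FFT autocovariance averaged across chains
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    fft = np.fft.rfft(centred, n=size, axis=1)
    acov = np.fft.irfft(fft * np.conj(fft), n=size, axis=1)[:, :n].real
    acov /= n
    rho = acov.mean(axis=0) / var
    # Geyer initial positive sequence on paired sums
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(m * n / tau)


def variance_inflation_factors(design: pd.DataFrame) -> pd.Series:
    """VIF per non-constant column from auxiliary OLS regressions.

    Each predictor is regressed on the remaining predictors plus an
    intercept; VIF = 1/(1 − R²).  Perfect collinearity reports ``inf``.
    """
    X = design.to_numpy(dtype=float)
    cols = list(design.columns)
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    if len(keep) < 2:
        raise ValueError("need at least 2 non-constant predictors")
    out = {}
    for j in keep:
        others = [k for k in keep if k != j]
        A = np.column_stack([np.ones(X.shape[0]), X[:, others]])
        y = X[:, j]
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[cols[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
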