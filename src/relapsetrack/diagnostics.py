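"""Chain diagnostics: Gelman-Rubin scale reduction and effective sample size.

The convergence statistic (C.S.) is the classic multi-chain potential scale
reduction factor sqrt(var+ / W) with var+ = (n-1)/n * W + B/n, i.e. the
non-split form matching the convention behind printed "C.S." columns that
declare convergence at values at or below 1.002.  ESS uses the multi-chain
autocorrelation estimate with Geyer's initial-monotone positive-pair rule.
"""

from __future__ import annotations

import numpy as np

from .errors import ModelError


def _as_chains(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ModelError("expected an (n_chains, n_draws) array")
    if x.shape[0] < 2:
        raise ModelError("convergence diagnostics need at least 2 chains")
    if x.shape[1] < 4:
        raise ModelError("chains are too short")
    return x


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor across chains of one scalar."""
    x = _as_chains(chains)
    m, n = x.shape
    chain_means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b_over_n = chain_means.var(ddof=1)
    if w == 0.0:
        # Identical constant chains: no detectable disagreement.
        return 1.0 if b_over_n == 0.0 else float("inf")
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


def _autocov(y: np.ndarray) -> np.ndarray:
    """Biased autocovariance of one demeaned chain via FFT."""
    n = y.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(y - y.mean(), nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    return acov


def effective_sample_size(chains) -> float:
    """Multi-chain ESS of one scalar (Geyer initial monotone sequence)."""
    x = _as_chains(chains)
    m, n = x.shape
    acov = np.mean([_autocov(x[j]) for j in range(m)], axis=0)
    chain_means = x.mean(axis=1)
    w = acov[0] * n / (n - 1)
    var_plus = (n - 1) / n * w + chain_means.var(ddof=1)
    if var_plus == 0.0:
        return float(m * n)
    rho = 1.0 - (w - acov) / var_plus  # rho[0] == 1 up to rounding
    # Paired sums rho[2t] + rho[2t+1]; stop at the first negative pair and
    # enforce monotone decrease.
    tau = -1.0
    prev_pair = np.inf
    for t in range(0, n - 1, 2):
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        tau += 2.0 * pair
        prev_pair = pair
    tau = max(tau, 1.0 / np.log10(n + 10))  # guard against pathological chains
    return float(min(m * n, m * n / tau))
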