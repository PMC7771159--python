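"""MCMC convergence diagnostics: split-chain R-hat and effective sample size.

Both statistics follow the constructions used by Stan: R-hat is the
potential scale reduction factor computed on half-split chains (between- vs
within-chain variance), and the effective sample size combines multi-chain
autocovariances truncated by Geyer's initial monotone positive sequence.

Degenerate conventions:

* chains that are all identical constants have zero between- and
  within-chain variance; R-hat is defined to be 1.0 there;
* constant chains have undefined autocorrelation time; ESS is reported as
  0.0 together with a ``ConstantChainWarning``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["rhat", "ess", "FitDiagnostics", "diagnose", "ConstantChainWarning"]


class ConstantChainWarning(UserWarning):
    """Raised (as a warning) when a diagnostic is undefined for constant chains."""


def _check_chains(draws: np.ndarray) -> np.ndarray:
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("draws must be a 2-D array of shape (chains, iterations)")
    m, n = draws.shape
    if m < 2:
        raise ValueError(
            "at least 2 chains are required; run the sampler with >= 2 chains"
        )
    if n < 4:
        raise ValueError("at least 4 draws per chain are required")
    return draws


def _split(draws: np.ndarray) -> np.ndarray:
    m, n = draws.shape
    half = n // 2
    return np.vstack([draws[:, :half], draws[:, n - half :]])


def rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    Parameters
    ----------
    draws
        Array of shape ``(chains, iterations)``.
    """
    x = _split(_check_chains(draws))
    m, n = x.shape
    chain_means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    if w == 0.0:
        return 1.0 if b == 0.0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _chain_autocov(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of one chain via FFT, lags 0..n-1."""
    n = x.size
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real
    return acov / n


def ess(draws: np.ndarray) -> float:
    """Multi-chain effective sample size with Geyer initial-monotone truncation.

    Returns 0.0 with a :class:`ConstantChainWarning` when every chain is
    constant (autocorrelation time undefined).
    """
    x = _split(_check_chains(draws))
    m, n = x.shape
    chain_var = x.var(axis=1, ddof=1)
    w = chain_var.mean()
    if w == 0.0 and x.std() == 0.0:
        warnings.warn(
            "effective sample size undefined for constant chains; reporting 0",
            ConstantChainWarning,
        )
        return 0.0
    b = n * x.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    acov = np.stack([_chain_autocov(x[i]) for i in range(m)])
    # Combined autocorrelation (Stan eq.): rho_t = 1 - (W - mean acov_t)/var+
    rho = 1.0 - (w - acov.mean(axis=0) * n / (n - 1)) / var_plus
    rho[0] = 1.0
    # Geyer: paired sums P_k = rho_{2k} + rho_{2k+1}; keep the initial
    # positive sequence, enforced monotone non-increasing, then
    # tau = -1 + 2 * sum(P_k).
    n_pairs = rho.size // 2
    tau_sum = 0.0
    running_min = np.inf
    for k in range(n_pairs):
        p = rho[2 * k] + rho[2 * k + 1]
        if p < 0.0:
            break
        running_min = min(running_min, p)
        tau_sum += running_min
    tau = max(-1.0 + 2.0 * tau_sum, 1e-12)
    ess_val = m * n / tau
    return float(min(ess_val, m * n))


@dataclass
class FitDiagnostics:
    """Per-parameter convergence summary of one fit."""

    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def min_ess(self) -> float:
        return min(self.ess.values())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": list(self.rhat),
                "rhat": list(self.rhat.values()),
                "ess": [self.ess[k] for k in self.rhat],
            }
        )


def diagnose(draws: dict[str, np.ndarray]) -> FitDiagnostics:
    """Compute R-hat and ESS for a dictionary of draw arrays.

    Each value has shape ``(chains, kept)`` for scalar parameters or
    ``(chains, kept, ...)`` for parameter arrays, in which case trailing
    axes are flattened and reported as ``name[idx]``.
    """
    out = FitDiagnostics()
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2:
            out.rhat[name] = rhat(arr)
            out.ess[name] = ess(arr)
        else:
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            for j in range(flat.shape[2]):
                key = f"{name}[{j}]"
                out.rhat[key] = rhat(flat[:, :, j])
                out.ess[key] = ess(flat[:, :, j])
    return out
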