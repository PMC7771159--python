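"""WAIC and PSIS-LOO model comparison from pointwise log-likelihood draws.

Both criteria estimate the expected log pointwise predictive density (elpd)
of a fitted Bayesian model from an S x N matrix of per-draw,
per-observation log-likelihood values:

* WAIC: ``elpd_i = log mean_s exp(ll_si) - var_s(ll_si)``;
* PSIS-LOO: leave-one-out importance ratios ``1 / p(y_i | theta_s)`` are
  stabilized by replacing the largest 20% with order statistics of a
  generalized Pareto distribution fitted to that tail (Pareto-smoothed
  importance sampling); tail-shape diagnostics k > 0.7 are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "WaicResult",
    "LooResult",
    "waic",
    "psis_loo",
    "compare_models",
    "gpd_fit",
]

PARETO_K_THRESHOLD = 0.7


def _check_loglik(loglik: np.ndarray) -> np.ndarray:
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be 2-D (draws x observations)")
    bad = ~np.isfinite(ll)
    if bad.any():
        obs = int(np.argwhere(bad.any(axis=0)).ravel()[0])
        raise ValueError(f"non-finite log-likelihood entries at observation {obs}")
    return ll


@dataclass
class WaicResult:
    elpd_waic: float
    p_waic: float
    pointwise: np.ndarray  # per-observation elpd contributions

    @property
    def se(self) -> float:
        n = self.pointwise.size
        return float(np.sqrt(n * np.var(self.pointwise, ddof=1)))


@dataclass
class LooResult:
    elpd_loo: float
    p_loo: float
    pointwise: np.ndarray
    pareto_k: np.ndarray
    smoothed: bool

    @property
    def se(self) -> float:
        n = self.pointwise.size
        return float(np.sqrt(n * np.var(self.pointwise, ddof=1)))

    @property
    def n_high_k(self) -> int:
        return int((self.pareto_k > PARETO_K_THRESHOLD).sum())


def waic(loglik: np.ndarray) -> WaicResult:
    """Widely applicable information criterion on the elpd scale."""
    ll = _check_loglik(loglik)
    s = ll.shape[0]
    lppd = logsumexp(ll, axis=0) - np.log(s)
    p_i = ll.var(axis=0, ddof=1) if s > 1 else np.zeros(ll.shape[1])
    pointwise = lppd - p_i
    return WaicResult(float(pointwise.sum()), float(p_i.sum()), pointwise)


def gpd_fit(exceedances: np.ndarray) -> tuple[float, float]:
    """Generalized Pareto shape/scale fit (Zhang & Stephens 2009 estimator).

    ``exceedances`` are positive values above the tail threshold. Returns
    ``(k, sigma)``; includes the weak prior regularization toward k = 0.5
    used by Pareto-smoothed importance sampling.
    """
    x = np.asarray(exceedances, dtype=float)
    x = np.sort(x[x > 0])  # ties at the threshold carry no tail information
    n = x.size
    if n < 5 or x[-1] <= 0:
        return np.inf, np.nan
    prior_bs, prior_k = 3.0, 10.0
    m = 30 + int(np.sqrt(n))
    b = 1.0 - np.sqrt(m / (np.arange(1, m + 1) - 0.5))
    b /= prior_bs * x[int(n / 4 + 0.5) - 1]
    b += 1.0 / x[-1]
    k_j = np.log1p(-b[:, None] * x).mean(axis=1)
    ll_j = n * (np.log(-(b / k_j)) - k_j - 1.0)
    w = 1.0 / np.exp(ll_j - ll_j[:, None]).sum(axis=1)
    b_post = float(np.sum(b * w))
    k_post = float(np.log1p(-b_post * x).mean())
    sigma = -k_post / b_post
    k_post = k_post * n / (n + prior_k) + prior_k * 0.5 / (n + prior_k)
    return k_post, sigma


def _gpd_quantile(p: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if abs(k) < 1e-12:
        return -sigma * np.log1p(-p)
    return sigma * np.expm1(-k * np.log1p(-p)) / k


def psis_loo(loglik: np.ndarray, min_draws_for_tail: int = 100) -> LooResult:
    """PSIS leave-one-out expected log predictive density.

    Falls back to unsmoothed importance sampling (with a warning) when fewer
    than ``min_draws_for_tail`` draws are available for the tail fit.
    """
    ll = _check_loglik(loglik)
    s, n_obs = ll.shape
    smoothed = s >= min_draws_for_tail
    if not smoothed:
        warnings.warn(
            f"only {s} draws: too few for a Pareto tail fit; "
            "using unsmoothed importance sampling",
            UserWarning,
        )
    pointwise = np.empty(n_obs)
    pareto_k = np.full(n_obs, np.nan)
    lppd = logsumexp(ll, axis=0) - np.log(s)
    for i in range(n_obs):
        lw = -ll[:, i]
        lw = lw - lw.max()
        if smoothed and lw.std() > 0:
            m_tail = int(np.ceil(0.2 * s))
            order = np.argsort(lw)
            tail_idx = order[-m_tail:]
            cutoff = np.exp(lw[order[-m_tail - 1]])
            exceed = np.exp(lw[tail_idx]) - cutoff
            k, sigma = gpd_fit(exceed)
            pareto_k[i] = k
            if np.isfinite(k) and np.isfinite(sigma) and sigma > 0:
                probs = (np.arange(1, m_tail + 1) - 0.5) / m_tail
                smoothed_tail = cutoff + _gpd_quantile(probs, k, sigma)
                smoothed_tail = np.minimum(smoothed_tail, np.exp(lw.max()))
                ranks = np.argsort(lw[tail_idx])
                new = np.empty(m_tail)
                new[ranks] = np.log(smoothed_tail)
                lw = lw.copy()
                lw[tail_idx] = new
        pointwise[i] = logsumexp(ll[:, i] + lw) - logsumexp(lw)
    elpd = float(pointwise.sum())
    p_loo = float(lppd.sum() - elpd)
    return LooResult(elpd, p_loo, pointwise, pareto_k, smoothed)


def compare_models(fits: dict[str, object]) -> pd.DataFrame:
    """Rank models by PSIS-LOO elpd (ties broken by fewer effective parameters).

    ``fits`` maps model names to pointwise log-likelihood matrices
    (draws x observations) or to objects exposing ``pointwise_loglik()``.
    All models must be fitted to the same observations.
    """
    mats: dict[str, np.ndarray] = {}
    for name, fit in fits.items():
        if hasattr(fit, "pointwise_loglik"):
            attr = fit.pointwise_loglik
            mats[name] = np.asarray(attr() if callable(attr) else attr, dtype=float)
        else:
            mats[name] = np.asarray(fit, dtype=float)
    n_obs = {name: m.shape[1] for name, m in mats.items()}
    if len(set(n_obs.values())) > 1:
        raise ValueError(f"models fitted to different observation counts: {n_obs}")
    rows = []
    loos: dict[str, LooResult] = {}
    for name, mat in mats.items():
        w = waic(mat)
        lo = psis_loo(mat)
        loos[name] = lo
        rows.append(
            {
                "model": name,
                "elpd_loo": lo.elpd_loo,
                "p_loo": lo.p_loo,
                "se_elpd_loo": lo.se,
                "elpd_waic": w.elpd_waic,
                "p_waic": w.p_waic,
                "n_pareto_k_high": lo.n_high_k,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["elpd_loo", "p_loo"], ascending=[False, True], kind="mergesort"
    )
    best = table.iloc[0]["model"]
    d_elpd, d_se = [], []
    for name in table["model"]:
        diff = loos[name].pointwise - loos[best].pointwise
        d_elpd.append(float(diff.sum()))
        d_se.append(float(np.sqrt(diff.size * np.var(diff, ddof=1))))
    table["d_elpd_loo"] = d_elpd
    table["d_se"] = d_se
    table["rank"] = np.arange(len(table))
    return table.reset_index(drop=True)
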