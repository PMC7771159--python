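"""Low-level MCMC building blocks shared by the model-fitting modules.

Three primitives cover every model in the package:

* :func:`slice_sample` — univariate stepping-out slice sampling (Neal 2003),
  used for standard-deviation parameters on the log scale.
* :func:`logistic_newton` — vectorized Newton mode/Hessian finder for
  two-parameter (intercept, slope) binomial-logit cells, the basis of
  Laplace-approximation independence Metropolis proposals.
* small helpers for bivariate-normal draws parameterized by 2x2 precision
  or covariance blocks, vectorized over an arbitrary leading shape.

All routines take an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = [
    "slice_sample",
    "logistic_newton",
    "binom_loglik",
    "chol2x2",
    "mvn2_draw",
    "mvn2_logpdf",
    "mvt2_draw",
    "mvt2_logpdf",
]


def slice_sample(
    logpdf: Callable[[float], float],
    x0: float,
    rng: np.random.Generator,
    width: float = 1.0,
    max_steps: int = 50,
) -> float:
    """One update of a univariate slice sampler with stepping-out.

    ``logpdf`` must be finite at ``x0``. Returns a new point whose
    stationary distribution is proportional to ``exp(logpdf)``.
    """
    f0 = logpdf(x0)
    if not np.isfinite(f0):
        raise ValueError("slice_sample: logpdf not finite at the current point")
    logy = f0 + np.log(rng.uniform())
    # Step out.
    u = rng.uniform()
    lo = x0 - width * u
    hi = lo + width
    j = int(np.floor(max_steps * rng.uniform()))
    k = max_steps - 1 - j
    while j > 0 and logpdf(lo) > logy:
        lo -= width
        j -= 1
    while k > 0 and logpdf(hi) > logy:
        hi += width
        k -= 1
    # Shrink in.
    for _ in range(200):
        x1 = rng.uniform(lo, hi)
        if logpdf(x1) > logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0  # pathological target; keep the current point


def binom_loglik(eta: np.ndarray, y: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood terms ``y*eta - n*log(1+exp(eta))`` (no binomial
    coefficient), elementwise and numerically stable."""
    return y * eta - n * np.logaddexp(0.0, eta)


def logistic_newton(
    y: np.ndarray,
    n: np.ndarray,
    t: np.ndarray,
    prior_prec: np.ndarray,
    offset: np.ndarray | float = 0.0,
    n_iter: int = 25,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and Hessian of independent binomial-logit cells.

    Each cell has model ``logit p_k = offset_k + u + v * t_k`` with an
    independent normal prior of precision ``prior_prec = (1/su^2, 1/sv^2)``
    and mean zero on ``(u, v)``.

    Parameters
    ----------
    y, n
        Successes and trials, shape ``(..., K)``; leading axes index cells
        (and possibly chains).
    t
        Covariate, shape ``(K,)`` or broadcastable to ``y``.
    prior_prec
        Prior precisions ``(2,)`` or shape broadcastable to ``(..., 2)``.
    offset
        Linear-predictor offset broadcastable to ``y``.

    Returns
    -------
    mode : ndarray, shape ``(..., 2)``
    hess : ndarray, shape ``(..., 2, 2)``
        Negative second derivative (observed information + prior precision)
        at the mode.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    lead = y.shape[:-1]
    theta = np.zeros(lead + (2,))
    prior_prec = np.broadcast_to(np.asarray(prior_prec, dtype=float), lead + (2,))
    for _ in range(n_iter):
        eta = offset + theta[..., :1] * np.ones_like(y) + theta[..., 1:] * t
        p = 1.0 / (1.0 + np.exp(-eta))
        w = n * p * (1.0 - p)
        r = y - n * p
        g0 = r.sum(axis=-1) - prior_prec[..., 0] * theta[..., 0]
        g1 = (r * t).sum(axis=-1) - prior_prec[..., 1] * theta[..., 1]
        h00 = w.sum(axis=-1) + prior_prec[..., 0]
        h01 = (w * t).sum(axis=-1)
        h11 = (w * t * t).sum(axis=-1) + prior_prec[..., 1]
        det = h00 * h11 - h01 * h01
        step0 = (h11 * g0 - h01 * g1) / det
        step1 = (h00 * g1 - h01 * g0) / det
        # Damp large steps for stability in separated cells.
        norm = np.hypot(step0, step1)
        damp = np.where(norm > 4.0, 4.0 / np.maximum(norm, 1e-12), 1.0)
        theta = theta + damp[..., None] * np.stack([step0, step1], axis=-1)
    eta = offset + theta[..., :1] * np.ones_like(y) + theta[..., 1:] * t
    p = 1.0 / (1.0 + np.exp(-eta))
    w = n * p * (1.0 - p)
    hess = np.empty(lead + (2, 2))
    hess[..., 0, 0] = w.sum(axis=-1) + prior_prec[..., 0]
    hess[..., 0, 1] = hess[..., 1, 0] = (w * t).sum(axis=-1)
    hess[..., 1, 1] = (w * t * t).sum(axis=-1) + prior_prec[..., 1]
    return theta, hess


def chol2x2(mat: np.ndarray) -> np.ndarray:
    """Cholesky factor of symmetric positive-definite 2x2 blocks, vectorized."""
    l00 = np.sqrt(mat[..., 0, 0])
    l10 = mat[..., 1, 0] / l00
    l11 = np.sqrt(mat[..., 1, 1] - l10 * l10)
    out = np.zeros_like(mat)
    out[..., 0, 0] = l00
    out[..., 1, 0] = l10
    out[..., 1, 1] = l11
    return out


def _invert2x2(mat: np.ndarray) -> np.ndarray:
    det = mat[..., 0, 0] * mat[..., 1, 1] - mat[..., 0, 1] * mat[..., 1, 0]
    inv = np.empty_like(mat)
    inv[..., 0, 0] = mat[..., 1, 1] / det
    inv[..., 1, 1] = mat[..., 0, 0] / det
    inv[..., 0, 1] = -mat[..., 0, 1] / det
    inv[..., 1, 0] = -mat[..., 1, 0] / det
    return inv


def mvn2_draw(
    mean: np.ndarray, cov: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw from N(mean, cov) for stacked 2-vectors / 2x2 covariances."""
    chol = chol2x2(cov)
    z = rng.standard_normal(mean.shape)
    return mean + np.einsum("...ij,...j->...i", chol, z)


def mvn2_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = x - mean
    prec = _invert2x2(cov)
    quad = np.einsum("...i,...ij,...j->...", d, prec, d)
    logdet = np.log(cov[..., 0, 0] * cov[..., 1, 1] - cov[..., 0, 1] * cov[..., 1, 0])
    return -0.5 * (quad + logdet) - np.log(2.0 * np.pi)


def mvt2_draw(
    mean: np.ndarray, cov: np.ndarray, df: float, rng: np.random.Generator
) -> np.ndarray:
    """Multivariate-t draws (dimension 2) with scale matrix ``cov``."""
    g = rng.chisquare(df, size=mean.shape[:-1]) / df
    z = mvn2_draw(np.zeros_like(mean), cov, rng)
    return mean + z / np.sqrt(g)[..., None]


def mvt2_logpdf(
    x: np.ndarray, mean: np.ndarray, cov: np.ndarray, df: float
) -> np.ndarray:
    from scipy.special import gammaln

    d = x - mean
    prec = _invert2x2(cov)
    quad = np.einsum("...i,...ij,...j->...", d, prec, d)
    logdet = np.log(cov[..., 0, 0] * cov[..., 1, 1] - cov[..., 0, 1] * cov[..., 1, 0])
    p = 2.0
    return (
        gammaln((df + p) / 2.0)
        - gammaln(df / 2.0)
        - (p / 2.0) * np.log(df * np.pi)
        - 0.5 * logdet
        - ((df + p) / 2.0) * np.log1p(quad / df)
    )
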