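"""Posterior cross-subregion correlation between trend parameters.

This is the inference stage that links initial food availability to the
rate of occupancy change. Two responses are modelled jointly with
independent likelihoods and fully independent fixed-effect coefficients per
age-by-subregion cell:

    E[log(CSF_ijk + offset)] = alpha_CSF,ij + beta_CSF,ij * Year_k
    logit[p_CO,ijk]          = alpha_CO,ij  + beta_CO,ij  * Year_k

(or bottom temperature in place of CSF, with its per-subregion coefficients
broadcast across ages, since temperature casts carry no age signal). For
each retained MCMC draw the Pearson correlation of a chosen coefficient
pair — e.g. (alpha_CSF,ij, beta_CO,ij) — is computed across the J
subregions at fixed age i, yielding a posterior distribution of the
correlation itself; its mean and central 95% credible interval propagate
the full estimation uncertainty of the intercepts and slopes.

Gaussian cells are sampled by conjugate Gibbs (given the shared residual
sd, itself slice-sampled); binomial-logit cells by independence
Metropolis-Hastings with a fixed multivariate-t proposal built from each
cell's Laplace approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._samplers import (
    binom_loglik,
    logistic_newton,
    mvt2_draw,
    mvt2_logpdf,
    slice_sample,
)
from .glmm import REFERENCE_YEAR, HALF_NORMAL_SD, _halfnormal_logpdf_logscale

__all__ = [
    "JointSpec",
    "JointPosterior",
    "CorrelationEstimate",
    "fit_joint",
    "correlation_per_draw",
    "estimate_correlations",
    "correlation_report",
]

PROPOSAL_DF = 7.0
PROPOSAL_INFLATION = 1.3


@dataclass(frozen=True)
class JointSpec:
    """Sampling configuration of the joint correlation model."""

    pair: str = "csf_co"  # "csf_co" or "temp_co"
    chains: int = 3
    iterations: int = 20_000
    burn_in: int = 10_000
    thin: int = 5
    prior_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pair not in ("csf_co", "temp_co"):
            raise ValueError("pair must be 'csf_co' or 'temp_co'")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def kept_per_chain(self) -> int:
        return math.ceil((self.iterations - self.burn_in) / self.thin)

    @property
    def retained_total(self) -> int:
        return self.chains * self.kept_per_chain


@dataclass
class JointPosterior:
    """Retained draws of every cell coefficient of both responses.

    Coefficient arrays have shape ``(chains, kept, n_ages, n_subregions)``;
    scale parameters ``(chains, kept)``. The two responses share no
    parameters (independent error terms).
    """

    spec: JointSpec
    ages: list[int]
    subregions: list[int]
    draws: dict[str, np.ndarray]
    acceptance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.draws.items():
            if arr.shape[0] != self.spec.chains or arr.shape[1] != self.spec.kept_per_chain:
                raise ValueError(
                    f"draw array {name} has shape {arr.shape}; expected "
                    f"({self.spec.chains}, {self.spec.kept_per_chain}, ...)"
                )

    def flat(self, name: str) -> np.ndarray:
        """Draws flattened over chains: (retained_total, n_ages, n_subregions)."""
        arr = self.draws[name]
        return arr.reshape((-1,) + arr.shape[2:])


@dataclass
class CorrelationEstimate:
    age: int
    pair: str
    x_role: str
    y_role: str
    posterior_mean: float
    ci_low: float
    ci_high: float
    draws: np.ndarray
    n_undefined: int


def _cell_suffstats(
    values: pd.DataFrame, value_col: str, ages: list[int], subregions: list[int], years: np.ndarray
):
    """Per-cell Gaussian sufficient statistics on the (age, subregion) grid."""
    t = years - REFERENCE_YEAR
    n_i, n_j, n_k = len(ages), len(subregions), len(years)
    n = np.zeros((n_i, n_j, n_k))
    s1 = np.zeros((n_i, n_j, n_k))
    s2 = np.zeros((n_i, n_j, n_k))
    amap = {a: i for i, a in enumerate(ages)}
    jmap = {s: j for j, s in enumerate(subregions)}
    kmap = {y: k for k, y in enumerate(years)}
    g = values.groupby(["age", "subregion", "year"])[value_col].agg(["size", "sum", lambda v: (v**2).sum()])
    for (a, s, y), row in g.iterrows():
        n[amap[a], jmap[s], kmap[y]] = row.iloc[0]
        s1[amap[a], jmap[s], kmap[y]] = row.iloc[1]
        s2[amap[a], jmap[s], kmap[y]] = row.iloc[2]
    return n, s1, s2, t


def _check_cells(df: pd.DataFrame, ages, subregions, what: str) -> None:
    have = set(zip(df["age"], df["subregion"]))
    missing = [(a, s) for a in ages for s in subregions if (a, s) not in have]
    if missing:
        raise ValueError(
            f"{what} data lack (age, subregion) cells: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )


def fit_joint(
    data_response: pd.DataFrame,
    data_occupancy: pd.DataFrame,
    spec: JointSpec,
) -> JointPosterior:
    """Sample the joint two-response cell-coefficient model.

    ``data_occupancy`` are occupancy cells (year, subregion, age, n_sets,
    n_present). ``data_response`` is fish-level transformed CSF (columns
    year, subregion, age, csf_transformed) for pair "csf_co", or
    standardized temperature casts (columns year, subregion, temp_std) for
    pair "temp_co"; temperature has no age structure and its per-subregion
    coefficients are broadcast across ages.
    """
    occ = data_occupancy
    ages = sorted(occ["age"].unique().tolist())
    subregions = sorted(occ["subregion"].unique().tolist())
    years = np.array(sorted(occ["year"].unique()))
    _check_cells(occ, ages, subregions, "occupancy")
    if spec.pair == "csf_co":
        _check_cells(data_response, ages, subregions, "stomach-fullness")

    rng_master = np.random.SeedSequence(spec.seed)
    rng_gauss, rng_binom = (np.random.default_rng(s) for s in rng_master.spawn(2))

    # --- binomial-logit occupancy cells ------------------------------------
    t = years.astype(float) - REFERENCE_YEAR
    n_i, n_j, n_k = len(ages), len(subregions), len(years)
    y = np.zeros((n_i, n_j, n_k))
    n = np.zeros((n_i, n_j, n_k))
    amap = {a: i for i, a in enumerate(ages)}
    jmap = {s: j for j, s in enumerate(subregions)}
    kmap = {yy: k for k, yy in enumerate(years)}
    for row in occ.itertuples(index=False):
        y[amap[row.age], jmap[row.subregion], kmap[row.year]] += row.n_present
        n[amap[row.age], jmap[row.subregion], kmap[row.year]] += row.n_sets
    co_draws, co_accept = _sample_binomial_cells(y, n, t, spec, rng_binom)

    draws = {
        "alpha_co": co_draws[..., 0],
        "beta_co": co_draws[..., 1],
    }
    acceptance = {"occupancy_cells": co_accept}

    # --- Gaussian response -------------------------------------------------
    if spec.pair == "csf_co":
        gn, gs1, gs2, gt = _cell_suffstats(
            data_response, "csf_transformed", ages, subregions, years
        )
        coef, sigma = _sample_gaussian_cells(gn, gs1, gs2, gt, spec, rng_gauss)
        draws["alpha_csf"] = coef[..., 0]
        draws["beta_csf"] = coef[..., 1]
        draws["sigma_csf"] = sigma
    else:
        temp = data_response.copy()
        temp["age"] = 0  # single pseudo-age: per-subregion coefficients only
        gn, gs1, gs2, gt = _cell_suffstats(temp, "temp_std", [0], subregions, years)
        coef, sigma = _sample_gaussian_cells(gn, gs1, gs2, gt, spec, rng_gauss)
        # Broadcast across ages: temperature carries no age information.
        draws["alpha_temp"] = np.repeat(coef[..., 0], n_i, axis=2)
        draws["beta_temp"] = np.repeat(coef[..., 1], n_i, axis=2)
        draws["sigma_temp"] = sigma

    return JointPosterior(
        spec=spec, ages=ages, subregions=subregions, draws=draws, acceptance=acceptance
    )


def _retained_iter(spec: JointSpec):
    return range(spec.burn_in, spec.iterations, spec.thin)


def _sample_binomial_cells(y, n, t, spec: JointSpec, rng) -> tuple[np.ndarray, float]:
    """Independence MH for all binomial cells at once.

    The target of every cell is fixed (no shared parameters), so a single
    Laplace-based multivariate-t proposal per cell serves all iterations;
    chains are vectorized in the leading axis.
    """
    n_i, n_j, _ = y.shape
    C = spec.chains
    prior_prec = np.array([1.0, 1.0]) / spec.prior_sd**2
    mode, hess = logistic_newton(y, n, t, prior_prec, n_iter=30)
    cov = np.linalg.inv(hess) * PROPOSAL_INFLATION
    mode_b = np.broadcast_to(mode, (C, n_i, n_j, 2))
    cov_b = np.broadcast_to(cov, (C, n_i, n_j, 2, 2))

    def logpost(theta):
        eta = theta[..., :1] + theta[..., 1:] * t
        ll = binom_loglik(eta, y[None], n[None]).sum(axis=-1)
        lp = -0.5 * (prior_prec[0] * theta[..., 0] ** 2 + prior_prec[1] * theta[..., 1] ** 2)
        return ll + lp

    cur = mvt2_draw(mode_b, cov_b, PROPOSAL_DF, rng)
    cur_lp = logpost(cur) - mvt2_logpdf(cur, mode_b, cov_b, PROPOSAL_DF)
    kept = spec.kept_per_chain
    out = np.empty((C, kept, n_i, n_j, 2))
    retained = set(_retained_iter(spec))
    k_idx = 0
    accepted = 0.0
    for it in range(spec.iterations):
        prop = mvt2_draw(mode_b, cov_b, PROPOSAL_DF, rng)
        prop_lp = logpost(prop) - mvt2_logpdf(prop, mode_b, cov_b, PROPOSAL_DF)
        acc = np.log(rng.uniform(size=prop_lp.shape)) < prop_lp - cur_lp
        cur = np.where(acc[..., None], prop, cur)
        cur_lp = np.where(acc, prop_lp, cur_lp)
        accepted += acc.mean()
        if it in retained:
            out[:, k_idx] = cur
            k_idx += 1
    return out, accepted / spec.iterations


def _sample_gaussian_cells(n, s1, s2, t, spec: JointSpec, rng):
    """Gibbs for independent Gaussian cells with a shared residual sd.

    Empty (cell, year) combinations contribute nothing (their counts are 0).
    """
    n_i, n_j, _ = n.shape
    C = spec.chains
    prior_prec = 1.0 / spec.prior_sd**2
    S_n = n.sum(axis=-1)
    S_t = (n * t).sum(axis=-1)
    S_tt = (n * t * t).sum(axis=-1)
    S_y = s1.sum(axis=-1)
    S_yt = (s1 * t).sum(axis=-1)
    S_yy = s2.sum(axis=-1)
    n_total = float(S_n.sum())

    kept = spec.kept_per_chain
    coef_out = np.empty((C, kept, n_i, n_j, 2))
    sigma_out = np.empty((C, kept))
    retained = set(_retained_iter(spec))

    coef = np.zeros((C, n_i, n_j, 2))
    log_sigma = np.full(C, 0.0)
    k_idx = 0
    for it in range(spec.iterations):
        sig2 = np.exp(2.0 * log_sigma)[:, None, None]
        p00 = S_n / sig2 + prior_prec
        p01 = S_t / sig2 + 0.0
        p11 = S_tt / sig2 + prior_prec
        det = p00 * p11 - p01 * p01
        h0 = S_y / sig2
        h1 = S_yt / sig2
        m0 = (p11 * h0 - p01 * h1) / det
        m1 = (p00 * h1 - p01 * h0) / det
        # Draw from N(m, P^-1) via the precision Cholesky.
        l00 = np.sqrt(p00)
        l10 = p01 / l00
        l11 = np.sqrt(p11 - l10 * l10)
        z0 = rng.standard_normal(m0.shape)
        z1 = rng.standard_normal(m1.shape)
        # Solve L^T x = z for the correlated noise.
        e1 = z1 / l11
        e0 = (z0 - l10 * e1) / l00
        coef[..., 0] = m0 + e0
        coef[..., 1] = m1 + e1
        # Residual sd given all coefficients.
        a, b = coef[..., 0], coef[..., 1]
        rss = (
            S_yy
            - 2.0 * a * S_y
            - 2.0 * b * S_yt
            + a * a * S_n
            + 2.0 * a * b * S_t
            + b * b * S_tt
        ).sum(axis=(1, 2))
        for c in range(C):
            def logpdf(ls):
                return (
                    -n_total * ls
                    - 0.5 * rss[c] * np.exp(-2.0 * ls)
                    + _halfnormal_logpdf_logscale(ls, HALF_NORMAL_SD)
                )

            log_sigma[c] = slice_sample(logpdf, log_sigma[c], rng, width=0.3)
        if it in retained:
            coef_out[:, k_idx] = coef
            sigma_out[:, k_idx] = np.exp(log_sigma)
            k_idx += 1
    return coef_out, sigma_out


def correlation_per_draw(
    posterior: JointPosterior,
    age: int,
    x: str,
    y: str,
) -> CorrelationEstimate:
    """Per-draw Pearson correlation across subregions at one age.

    ``x`` and ``y`` name coefficient roles, e.g. ``"alpha_csf"`` and
    ``"beta_co"``. Draws in which either vector has zero variance across
    subregions are recorded as undefined and excluded (with accounting).
    """
    if len(posterior.subregions) < 3:
        raise ValueError("need at least 3 subregions for a correlation")
    ai = posterior.ages.index(age)
    xv = posterior.flat(x)[:, ai, :]
    yv = posterior.flat(y)[:, ai, :]
    xc = xv - xv.mean(axis=1, keepdims=True)
    yc = yv - yv.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    defined = (sx > 0) & (sy > 0)
    r = np.full(xv.shape[0], np.nan)
    r[defined] = (xc[defined] * yc[defined]).sum(axis=1) / (sx[defined] * sy[defined])
    r = np.clip(r, -1.0, 1.0)
    vals = r[defined]
    n_undef = int((~defined).sum())
    if vals.size == 0:
        raise ValueError("all draws had zero variance; correlation undefined")
    return CorrelationEstimate(
        age=age,
        pair=posterior.spec.pair,
        x_role=x,
        y_role=y,
        posterior_mean=float(vals.mean()),
        ci_low=float(np.quantile(vals, 0.025)),
        ci_high=float(np.quantile(vals, 0.975)),
        draws=vals,
        n_undefined=n_undef,
    )


def estimate_correlations(
    posterior: JointPosterior, x: str | None = None, y: str = "beta_co"
) -> list[CorrelationEstimate]:
    """The headline estimates for every age: Cor(alpha_CSF, beta_CO) for the
    stomach-fullness pair, Cor(beta_Temp, beta_CO) for the temperature pair."""
    if x is None:
        x = "alpha_csf" if posterior.spec.pair == "csf_co" else "beta_temp"
    return [correlation_per_draw(posterior, a, x, y) for a in posterior.ages]


def correlation_report(estimates: list[CorrelationEstimate]) -> pd.DataFrame:
    """Tidy point-interval table ordered by age (figure-ready)."""
    rows = [
        {
            "age": e.age,
            "pair": e.pair,
            "x_role": e.x_role,
            "y_role": e.y_role,
            "mean": e.posterior_mean,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "n_undefined_draws": e.n_undefined,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows).sort_values(["pair", "age"]).reset_index(drop=True)
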