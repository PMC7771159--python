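"""Hierarchical year-trend models for occupancy and stomach fullness.

The global model for a response ``Y_ijk`` (age i, subregion j, year k) is

    f(mu_ijk | a_ij, b_ij) = alpha + beta * Year_k + a_ij + b_ij * Year_k

with f the logit for occupancy (binomial counts of sets with fish present)
and the identity for transformed stomach fullness (Gaussian), Year_k the
calendar year minus 2004, and Gaussian random intercepts/slopes with zero
mean and variances sigma_a^2, sigma_b^2. The random-effect grouping forms a
ladder: none, age, subregion, age + subregion (additive), or the full
age-by-subregion interaction. Models with varying slopes but constant
intercepts are not representable.

Priors are weakly informative normals (sd 10 for the intercept, 2.5 for the
year coefficient, optionally autoscaled by the response/predictor spread)
and half-Normal(0, 2.5) on every standard deviation.

Posterior sampling is by blocked MCMC, vectorized across chains:

* Gaussian responses use exact conjugate Gibbs draws for all location
  blocks;
* binomial responses use independence Metropolis-Hastings with a Laplace
  (Newton-mode) Gaussian proposal per block, recomputed each sweep from the
  conditioning state only;
* standard deviations use slice sampling on the log scale;
* an exact Gibbs "recentering" move resolves the translation degeneracy
  between fixed effects and random-effect means, which would otherwise mix
  slowly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._samplers import binom_loglik, logistic_newton, mvn2_draw, mvn2_logpdf, slice_sample
from .diagnostics import FitDiagnostics, diagnose

__all__ = [
    "RandomStructure",
    "GlmmSpec",
    "Design",
    "build_design",
    "fit_glmm",
    "GlmmPosterior",
]

REFERENCE_YEAR = 2004
HALF_NORMAL_SD = 2.5  # prior scale for all standard-deviation parameters


class RandomStructure(str, Enum):
    NONE = "none"
    AGE = "age"
    SUBREGION = "subregion"
    AGE_PLUS_SUBREGION = "age_plus_subregion"
    AGE_BY_SUBREGION = "age_by_subregion"


@dataclass(frozen=True)
class GlmmSpec:
    """One model variant of the ladder and its sampling configuration."""

    response: str = "occupancy"  # "occupancy" (logit link) or "csf" (identity)
    random_structure: RandomStructure = RandomStructure.AGE_BY_SUBREGION
    random_slopes: bool = True
    prior_intercept_sd: float = 10.0
    prior_coef_sd: float = 2.5
    autoscale: bool = False
    chains: int = 4
    iterations: int = 2000
    burn_in: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.response not in ("occupancy", "csf"):
            raise ValueError("response must be 'occupancy' or 'csf'")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        object.__setattr__(
            self, "random_structure", RandomStructure(self.random_structure)
        )

    @property
    def link(self) -> str:
        return "logit" if self.response == "occupancy" else "identity"

    @property
    def kept(self) -> int:
        return self.iterations - self.burn_in


@dataclass
class Factor:
    name: str
    index: np.ndarray  # (n_obs,) level index per observation
    n_levels: int
    membership: np.ndarray = field(repr=False, default=None)  # (n_obs, n_levels)

    def __post_init__(self):
        if self.membership is None:
            m = np.zeros((self.index.size, self.n_levels))
            m[np.arange(self.index.size), self.index] = 1.0
            self.membership = m

    def reduce(self, values: np.ndarray) -> np.ndarray:
        """Sum ``values`` (..., n_obs) within each level -> (..., n_levels)."""
        return values @ self.membership

    def expand(self, per_level: np.ndarray) -> np.ndarray:
        """Broadcast per-level values (..., n_levels) to (..., n_obs)."""
        return per_level[..., self.index]


@dataclass
class Design:
    """Assembled model inputs for one response/structure combination."""

    spec: GlmmSpec
    t: np.ndarray  # (n_obs,) year since 2004
    factors: list[Factor]
    # occupancy: per-cell successes / trials
    successes: np.ndarray | None = None
    trials: np.ndarray | None = None
    # csf: per-cell sufficient statistics of the transformed response
    n_fish: np.ndarray | None = None
    sum_z: np.ndarray | None = None
    sum_z2: np.ndarray | None = None
    fish_z: np.ndarray | None = None  # fish-level values for pointwise loglik
    fish_cell: np.ndarray | None = None  # fish -> cell row index
    labels: pd.DataFrame | None = None  # per-obs (year, subregion, age)
    prior_sds: tuple[float, float] = (10.0, 2.5)

    @property
    def n_obs(self) -> int:
        return self.t.size


def _factor_indices(
    age: np.ndarray, subregion: np.ndarray, structure: RandomStructure
) -> list[tuple[str, np.ndarray]]:
    age_levels, age_idx = np.unique(age, return_inverse=True)
    sub_levels, sub_idx = np.unique(subregion, return_inverse=True)
    if structure is RandomStructure.NONE:
        return []
    if structure is RandomStructure.AGE:
        return [("age", age_idx, age_levels.size)]
    if structure is RandomStructure.SUBREGION:
        return [("subregion", sub_idx, sub_levels.size)]
    if structure is RandomStructure.AGE_PLUS_SUBREGION:
        return [
            ("age", age_idx, age_levels.size),
            ("subregion", sub_idx, sub_levels.size),
        ]
    inter = age_idx * sub_levels.size + sub_idx
    return [("age_by_subregion", inter, age_levels.size * sub_levels.size)]


def build_design(data: pd.DataFrame, spec: GlmmSpec) -> Design:
    """Assemble sampler inputs from occupancy cells or fish-level CSF records.

    Occupancy data need columns (year, subregion, age, n_sets, n_present);
    a set-level Bernoulli representation is simply the same table with one
    row per set and ``n_sets = 1``. CSF data need (year, subregion, age,
    csf_transformed), one row per fish.
    """
    if data.empty:
        raise ValueError("empty data")
    for col in ("year", "subregion", "age"):
        if col not in data.columns:
            raise ValueError(f"data lacks required column {col!r}")
        if data[col].isna().any():
            raise ValueError(f"unknown (missing) {col} label in data")
    prior_sds = (spec.prior_intercept_sd, spec.prior_coef_sd)
    if spec.response == "occupancy":
        if not {"n_sets", "n_present"} <= set(data.columns):
            raise ValueError("occupancy data need n_sets and n_present columns")
        if (data["n_sets"] <= 0).any():
            raise ValueError("non-positive trial counts")
        cells = data.reset_index(drop=True)
        t = cells["year"].to_numpy(float) - REFERENCE_YEAR
        factors = [
            Factor(name, idx, n)
            for name, idx, n in _factor_indices(
                cells["age"].to_numpy(), cells["subregion"].to_numpy(), spec.random_structure
            )
        ]
        if spec.autoscale:
            prior_sds = (
                spec.prior_intercept_sd,
                spec.prior_coef_sd / max(t.std(), 1e-12),
            )
        return Design(
            spec=spec,
            t=t,
            factors=factors,
            successes=cells["n_present"].to_numpy(float),
            trials=cells["n_sets"].to_numpy(float),
            labels=cells[["year", "subregion", "age"]],
            prior_sds=prior_sds,
        )
    # Gaussian response: collapse fish records to per-(age, subregion, year)
    # sufficient statistics; keep fish-level values for pointwise likelihoods.
    if "csf_transformed" not in data.columns:
        raise ValueError("csf data need a csf_transformed column")
    df = data.reset_index(drop=True)
    grouped = (
        df.assign(z=df["csf_transformed"], z2=df["csf_transformed"] ** 2)
        .groupby(["year", "subregion", "age"], sort=True)
        .agg(n_fish=("z", "size"), sum_z=("z", "sum"), sum_z2=("z2", "sum"))
        .reset_index()
    )
    t = grouped["year"].to_numpy(float) - REFERENCE_YEAR
    factors = [
        Factor(name, idx, n)
        for name, idx, n in _factor_indices(
            grouped["age"].to_numpy(), grouped["subregion"].to_numpy(), spec.random_structure
        )
    ]
    key = ["year", "subregion", "age"]
    cell_row = grouped.reset_index().set_index(key)["index"]
    fish_cell = cell_row.loc[list(map(tuple, df[key].to_numpy()))].to_numpy()
    z = df["csf_transformed"].to_numpy(float)
    if spec.autoscale:
        t_obs = df["year"].to_numpy(float) - REFERENCE_YEAR
        prior_sds = (
            spec.prior_intercept_sd * z.std(),
            spec.prior_coef_sd * z.std() / max(t_obs.std(), 1e-12),
        )
    return Design(
        spec=spec,
        t=t,
        factors=factors,
        n_fish=grouped["n_fish"].to_numpy(float),
        sum_z=grouped["sum_z"].to_numpy(float),
        sum_z2=grouped["sum_z2"].to_numpy(float),
        fish_z=z,
        fish_cell=fish_cell,
        labels=grouped[["year", "subregion", "age"]],
        prior_sds=prior_sds,
    )


class GlmmPosterior:
    """Retained posterior draws of one model fit.

    ``draws`` maps parameter names to arrays of shape ``(chains, kept)`` or
    ``(chains, kept, n_levels)``. Scalar fixed effects are ``alpha`` and
    ``beta``; per-factor effects are ``a_<factor>`` / ``b_<factor>`` with
    matching ``sigma_a_<factor>`` / ``sigma_b_<factor>``; Gaussian fits add
    ``sigma_resid``.
    """

    def __init__(self, draws: dict[str, np.ndarray], spec: GlmmSpec, design: Design):
        self.draws = draws
        self.spec = spec
        self.design = design
        first = next(iter(draws.values()))
        self.chains, self.kept = first.shape[:2]
        for name, arr in draws.items():
            if arr.shape[1] != self.kept:
                raise ValueError(f"inconsistent kept draws for {name}")
        for name, arr in draws.items():
            if name.startswith("sigma") and (arr <= 0).any():
                raise ValueError(f"non-positive scale draws in {name}")

    def _eta_draws(self) -> np.ndarray:
        """Linear predictor per draw and observation, flattened over chains."""
        d = self.draws
        S = self.chains * self.kept
        eta = (
            d["alpha"].reshape(S, 1)
            + d["beta"].reshape(S, 1) * self.design.t[None, :]
        )
        for f in self.design.factors:
            a = d[f"a_{f.name}"].reshape(S, -1)
            eta = eta + a[:, f.index]
            bkey = f"b_{f.name}"
            if bkey in d:
                b = d[bkey].reshape(S, -1)
                eta = eta + b[:, f.index] * self.design.t[None, :]
        return eta

    def pointwise_loglik(self, chunk: int = 200) -> np.ndarray:
        """Per-draw per-observation log-likelihood (draws x observations).

        Observations are binomial cells for occupancy and individual fish
        for the Gaussian stomach-fullness model.
        """
        des = self.design
        eta = self._eta_draws()
        S = eta.shape[0]
        if self.spec.response == "occupancy":
            y, n = des.successes, des.trials
            const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
            out = np.empty((S, des.n_obs))
            for s0 in range(0, S, chunk):
                e = eta[s0 : s0 + chunk]
                out[s0 : s0 + chunk] = const + binom_loglik(e, y, n)
            return out
        sigma = self.draws["sigma_resid"].reshape(S, 1)
        mu = eta[:, des.fish_cell]
        z = des.fish_z[None, :]
        return (
            -0.5 * np.log(2 * np.pi)
            - np.log(sigma)
            - 0.5 * ((z - mu) / sigma) ** 2
        )

    def focal_draws(self) -> dict[str, np.ndarray]:
        """Fixed effects and variance components (the convergence-critical
        parameters reported by the diagnostics summary)."""
        return {
            k: v
            for k, v in self.draws.items()
            if k in ("alpha", "beta") or k.startswith("sigma")
        }

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws: chain, iteration, parameter, value."""
        rows = []
        for name, arr in self.draws.items():
            if arr.ndim == 2:
                for c in range(self.chains):
                    rows.append(
                        pd.DataFrame(
                            {
                                "chain": c,
                                "iteration": np.arange(self.kept),
                                "parameter": name,
                                "value": arr[c],
                            }
                        )
                    )
            else:
                for g in range(arr.shape[2]):
                    for c in range(self.chains):
                        rows.append(
                            pd.DataFrame(
                                {
                                    "chain": c,
                                    "iteration": np.arange(self.kept),
                                    "parameter": f"{name}[{g}]",
                                    "value": arr[c, :, g],
                                }
                            )
                        )
        return pd.concat(rows, ignore_index=True)

    def cell_trends(self) -> pd.DataFrame:
        """Posterior-mean intercept/slope per observation cell's (age,
        subregion) combination — the fitted trend-line surface."""
        d = self.draws
        alpha = d["alpha"].mean()
        beta = d["beta"].mean()
        labels = self.design.labels[["subregion", "age"]].drop_duplicates()
        out = []
        for _, row in labels.iterrows():
            icpt, slope = alpha, beta
            for f in self.design.factors:
                mask = (
                    (self.design.labels["subregion"] == row["subregion"])
                    & (self.design.labels["age"] == row["age"])
                ).to_numpy()
                level = int(f.index[mask][0])
                icpt += d[f"a_{f.name}"][:, :, level].mean()
                bkey = f"b_{f.name}"
                if bkey in d:
                    slope += d[bkey][:, :, level].mean()
            out.append(
                {
                    "subregion": row["subregion"],
                    "age": row["age"],
                    "intercept": icpt,
                    "slope": slope,
                }
            )
        return pd.DataFrame(out)


def _halfnormal_logpdf_logscale(log_sigma: float, scale: float) -> float:
    """log p(log sigma) for sigma ~ HalfNormal(scale), including the Jacobian."""
    sigma2 = np.exp(2.0 * log_sigma)
    return -sigma2 / (2.0 * scale**2) + log_sigma


def _update_sigma(
    ss: np.ndarray, count: int, log_sigma: float, rng: np.random.Generator
) -> float:
    """Slice-update log sigma for a vector of ``count`` zero-mean normals with
    sum of squares ``ss`` under a half-normal prior."""

    def logpdf(ls: float) -> float:
        return (
            -count * ls
            - 0.5 * ss * np.exp(-2.0 * ls)
            + _halfnormal_logpdf_logscale(ls, HALF_NORMAL_SD)
        )

    return slice_sample(logpdf, log_sigma, rng, width=0.5)


def fit_glmm(
    data: pd.DataFrame, spec: GlmmSpec
) -> tuple[GlmmPosterior, FitDiagnostics]:
    """Fit one model of the ladder; returns draws and convergence diagnostics.

    Diagnostics cover the focal parameters (fixed effects and variance
    components). Sampling problems are surfaced, never silently dropped: a
    binomial block whose acceptance rate stays below 5% raises after the run
    with the offending block named.
    """
    design = build_design(data, spec)
    if spec.response == "occupancy":
        post = _sample_binomial(design)
    else:
        post = _sample_gaussian(design)
    diag = diagnose(post.focal_draws())
    return post, diag


# ---------------------------------------------------------------------------
# samplers (chains vectorized in the leading axis)
# ---------------------------------------------------------------------------


def _init_state(design: Design, rng: np.random.Generator):
    C = design.spec.chains
    state = {
        "alpha": 0.1 * rng.standard_normal(C),
        "beta": 0.1 * rng.standard_normal(C),
    }
    for f in design.factors:
        state[f"u_{f.name}"] = np.zeros((C, f.n_levels))
        state[f"v_{f.name}"] = np.zeros((C, f.n_levels))
        state[f"ls_u_{f.name}"] = np.full(C, np.log(0.5))
        state[f"ls_v_{f.name}"] = np.full(C, np.log(0.1))
    return state


def _eta_without(design: Design, state, skip: str | None):
    """Linear predictor (chains, n_obs), optionally excluding one factor or
    the fixed effects ("fixed")."""
    t = design.t
    if skip == "fixed":
        eta = np.zeros((design.spec.chains, design.n_obs))
    else:
        eta = state["alpha"][:, None] + state["beta"][:, None] * t
    for f in design.factors:
        if f.name == skip:
            continue
        eta = eta + f.expand(state[f"u_{f.name}"]) + f.expand(state[f"v_{f.name}"]) * t
    return eta


_SLOPE_OFF_PREC = 1e12  # pins slope deviations at ~0 when random_slopes is off


def _sample_binomial(design: Design) -> GlmmPosterior:
    spec = design.spec
    y, n, t = design.successes, design.trials, design.t
    C = spec.chains
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    state = _init_state(design, rng)
    s0, s1 = design.prior_sds
    kept = spec.kept
    store = _make_store(design, kept)
    accept_counts = {f.name: 0.0 for f in design.factors}
    accept_counts["fixed"] = 0.0

    for it in range(spec.iterations):
        # --- fixed effects: Laplace independence MH on the full data
        offset = _eta_without(design, state, skip="fixed")
        prior_prec = np.array([1.0 / s0**2, 1.0 / s1**2])
        cur = np.stack([state["alpha"], state["beta"]], axis=-1)
        ymat = np.broadcast_to(y, (C, y.size))
        nmat = np.broadcast_to(n, (C, n.size))
        mode, hess = logistic_newton(
            ymat, nmat, t, prior_prec, offset=offset, n_iter=8
        )
        cov = _inv2(hess)
        prop = mvn2_draw(mode, cov, rng)
        logr = (
            _binom_block_ll(prop, offset, y, n, t, None)
            + _normal_prior(prop, (s0, s1))
            - mvn2_logpdf(prop, mode, cov)
            - _binom_block_ll(cur, offset, y, n, t, None)
            - _normal_prior(cur, (s0, s1))
            + mvn2_logpdf(cur, mode, cov)
        )
        acc = np.log(rng.uniform(size=C)) < logr
        cur = np.where(acc[:, None], prop, cur)
        state["alpha"], state["beta"] = cur[..., 0], cur[..., 1]
        accept_counts["fixed"] += acc.mean()

        # --- random-effect blocks per factor
        for f in design.factors:
            offset = _eta_without(design, state, skip=f.name)
            su = np.exp(state[f"ls_u_{f.name}"])
            sv = np.exp(state[f"ls_v_{f.name}"])
            prec_u = 1.0 / su**2
            prec_v = (
                np.full(C, _SLOPE_OFF_PREC) if not spec.random_slopes else 1.0 / sv**2
            )
            pp = np.stack(
                [
                    np.repeat(prec_u[:, None], f.n_levels, axis=1),
                    np.repeat(prec_v[:, None], f.n_levels, axis=1),
                ],
                axis=-1,
            )
            mode, hess, cov, prop, cur = _factor_laplace_proposal(
                f, y, n, t, offset, pp, state, rng, C
            )
            ll_prop = _binom_block_ll(prop, offset, y, n, t, f)
            ll_cur = _binom_block_ll(cur, offset, y, n, t, f)
            pri_prop = -0.5 * (pp * prop**2).sum(axis=-1)
            pri_cur = -0.5 * (pp * cur**2).sum(axis=-1)
            logr = (
                ll_prop
                + pri_prop
                - mvn2_logpdf(prop, mode, cov)
                - ll_cur
                - pri_cur
                + mvn2_logpdf(cur, mode, cov)
            )
            acc = np.log(rng.uniform(size=(C, f.n_levels))) < logr
            newval = np.where(acc[..., None], prop, cur)
            state[f"u_{f.name}"] = newval[..., 0]
            state[f"v_{f.name}"] = newval[..., 1]
            accept_counts[f.name] += acc.mean()

            _recenter(state, f, rng, (s0, s1), spec.random_slopes)
            _update_factor_sigmas(state, f, rng, spec.random_slopes)

        if it >= spec.burn_in:
            _store_iteration(store, state, design, it - spec.burn_in)

    _check_acceptance(accept_counts, spec.iterations)
    return GlmmPosterior(_finalize_store(store, design), spec, design)


def _factor_laplace_proposal(f, y, n, t, offset, prior_prec, state, rng, C):
    """Newton mode and Gaussian proposal for all levels of one factor.

    The mode search starts from zero so the proposal depends only on the
    conditioning state (a requirement for valid independence MH).
    """
    # Arrange per-level observation blocks through membership reductions.
    # Work on obs-level arrays, reducing inside the Newton iteration.
    theta = np.zeros((C, f.n_levels, 2))
    for _ in range(8):
        eta = offset + f.expand(theta[..., 0]) + f.expand(theta[..., 1]) * t
        p = 1.0 / (1.0 + np.exp(-eta))
        w = n * p * (1.0 - p)
        r = y - n * p
        g0 = f.reduce(r) - prior_prec[..., 0] * theta[..., 0]
        g1 = f.reduce(r * t) - prior_prec[..., 1] * theta[..., 1]
        h00 = f.reduce(w) + prior_prec[..., 0]
        h01 = f.reduce(w * t)
        h11 = f.reduce(w * t * t) + prior_prec[..., 1]
        det = h00 * h11 - h01 * h01
        step0 = (h11 * g0 - h01 * g1) / det
        step1 = (h00 * g1 - h01 * g0) / det
        norm = np.hypot(step0, step1)
        damp = np.where(norm > 4.0, 4.0 / np.maximum(norm, 1e-12), 1.0)
        theta[..., 0] += damp * step0
        theta[..., 1] += damp * step1
    eta = offset + f.expand(theta[..., 0]) + f.expand(theta[..., 1]) * t
    p = 1.0 / (1.0 + np.exp(-eta))
    w = n * p * (1.0 - p)
    hess = np.empty((C, f.n_levels, 2, 2))
    hess[..., 0, 0] = f.reduce(w) + prior_prec[..., 0]
    hess[..., 0, 1] = hess[..., 1, 0] = f.reduce(w * t)
    hess[..., 1, 1] = f.reduce(w * t * t) + prior_prec[..., 1]
    cov = _inv2(hess)
    prop = mvn2_draw(theta, cov, rng)
    cur = np.stack([state[f"u_{f.name}"], state[f"v_{f.name}"]], axis=-1)
    return theta, hess, cov, prop, cur


def _binom_block_ll(theta, offset, y, n, t, factor):
    """Block log-likelihoods: per (chain,) for fixed effects (factor None) or
    per (chain, level)."""
    if factor is None:
        eta = offset + theta[..., :1] + theta[..., 1:] * t
        return binom_loglik(eta, y, n).sum(axis=-1)
    eta = offset + factor.expand(theta[..., 0]) + factor.expand(theta[..., 1]) * t
    return factor.reduce(binom_loglik(eta, y, n))


def _normal_prior(theta, sds):
    return -0.5 * (
        (theta[..., 0] / sds[0]) ** 2 + (theta[..., 1] / sds[1]) ** 2
    )


def _inv2(mat):
    det = mat[..., 0, 0] * mat[..., 1, 1] - mat[..., 0, 1] * mat[..., 1, 0]
    inv = np.empty_like(mat)
    inv[..., 0, 0] = mat[..., 1, 1] / det
    inv[..., 1, 1] = mat[..., 0, 0] / det
    inv[..., 0, 1] = inv[..., 1, 0] = -mat[..., 0, 1] / det
    return inv


def _recenter(state, f, rng, fixed_sds, slopes_on):
    """Exact Gibbs draw along the likelihood-invariant translation
    (alpha + d, u_g - d); same for the slopes."""
    C, G = state[f"u_{f.name}"].shape
    s0, s1 = fixed_sds
    su = np.exp(state[f"ls_u_{f.name}"])
    prec = 1.0 / s0**2 + G / su**2
    mean = (-state["alpha"] / s0**2 + state[f"u_{f.name}"].sum(axis=1) / su**2) / prec
    d = mean + rng.standard_normal(C) / np.sqrt(prec)
    state["alpha"] = state["alpha"] + d
    state[f"u_{f.name}"] = state[f"u_{f.name}"] - d[:, None]
    if slopes_on:
        sv = np.exp(state[f"ls_v_{f.name}"])
        prec = 1.0 / s1**2 + G / sv**2
        mean = (
            -state["beta"] / s1**2 + state[f"v_{f.name}"].sum(axis=1) / sv**2
        ) / prec
        d = mean + rng.standard_normal(C) / np.sqrt(prec)
        state["beta"] = state["beta"] + d
        state[f"v_{f.name}"] = state[f"v_{f.name}"] - d[:, None]


def _update_factor_sigmas(state, f, rng, slopes_on):
    C, G = state[f"u_{f.name}"].shape
    for c in range(C):
        ss_u = float((state[f"u_{f.name}"][c] ** 2).sum())
        state[f"ls_u_{f.name}"][c] = _update_sigma(
            ss_u, G, state[f"ls_u_{f.name}"][c], rng
        )
        if slopes_on:
            ss_v = float((state[f"v_{f.name}"][c] ** 2).sum())
            state[f"ls_v_{f.name}"][c] = _update_sigma(
                ss_v, G, state[f"ls_v_{f.name}"][c], rng
            )


def _make_store(design: Design, kept: int):
    spec = design.spec
    C = spec.chains
    store = {
        "alpha": np.empty((C, kept)),
        "beta": np.empty((C, kept)),
    }
    for f in design.factors:
        store[f"a_{f.name}"] = np.empty((C, kept, f.n_levels))
        store[f"sigma_a_{f.name}"] = np.empty((C, kept))
        if spec.random_slopes:
            store[f"b_{f.name}"] = np.empty((C, kept, f.n_levels))
            store[f"sigma_b_{f.name}"] = np.empty((C, kept))
    if spec.response == "csf":
        store["sigma_resid"] = np.empty((C, kept))
    return store


def _store_iteration(store, state, design, idx):
    spec = design.spec
    store["alpha"][:, idx] = state["alpha"]
    store["beta"][:, idx] = state["beta"]
    for f in design.factors:
        store[f"a_{f.name}"][:, idx] = state[f"u_{f.name}"]
        store[f"sigma_a_{f.name}"][:, idx] = np.exp(state[f"ls_u_{f.name}"])
        if spec.random_slopes:
            store[f"b_{f.name}"][:, idx] = state[f"v_{f.name}"]
            store[f"sigma_b_{f.name}"][:, idx] = np.exp(state[f"ls_v_{f.name}"])
    if spec.response == "csf":
        store["sigma_resid"][:, idx] = np.exp(state["ls_resid"])


def _finalize_store(store, design):
    return store


def _check_acceptance(accept_counts, iterations):
    for name, total in accept_counts.items():
        rate = total / iterations
        if rate < 0.05:
            raise RuntimeError(
                f"sampler block '{name}' accepted only {rate:.1%} of proposals; "
                "the posterior approximation failed — inspect the data/model"
            )


def _sample_gaussian(design: Design) -> GlmmPosterior:
    spec = design.spec
    t = design.t
    C = spec.chains
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    state = _init_state(design, rng)
    state["ls_resid"] = np.full(C, np.log(0.5))
    s0, s1 = design.prior_sds
    n_c, sum_z, sum_z2 = design.n_fish, design.sum_z, design.sum_z2
    n_total = float(n_c.sum())
    kept = spec.kept
    store = _make_store(design, kept)

    for it in range(spec.iterations):
        sig2 = np.exp(2.0 * state["ls_resid"])  # (C,)

        # --- fixed effects: exact bivariate normal conditional
        offset = _eta_without(design, state, skip="fixed")
        r1 = (sum_z - n_c * offset).sum(axis=-1)  # sum residuals
        rt = ((sum_z - n_c * offset) * t).sum(axis=-1)
        S_n, S_t, S_tt = n_c.sum(), (n_c * t).sum(), (n_c * t * t).sum()
        prec = np.empty((C, 2, 2))
        prec[:, 0, 0] = S_n / sig2 + 1.0 / s0**2
        prec[:, 0, 1] = prec[:, 1, 0] = S_t / sig2
        prec[:, 1, 1] = S_tt / sig2 + 1.0 / s1**2
        cov = _inv2(prec)
        h = np.stack([r1 / sig2, rt / sig2], axis=-1)
        mean = np.einsum("cij,cj->ci", cov, h)
        draw = mvn2_draw(mean, cov, rng)
        state["alpha"], state["beta"] = draw[..., 0], draw[..., 1]

        # --- random-effect blocks: exact conjugate draws per level
        for f in design.factors:
            offset = _eta_without(design, state, skip=f.name)
            su2 = np.exp(2.0 * state[f"ls_u_{f.name}"])
            sv2 = (
                np.full(C, 1.0 / _SLOPE_OFF_PREC)
                if not spec.random_slopes
                else np.exp(2.0 * state[f"ls_v_{f.name}"])
            )
            res = sum_z - n_c * offset
            g_r = f.reduce(res)
            g_rt = f.reduce(res * t)
            g_n = f.reduce(np.broadcast_to(n_c, (C, n_c.size)))
            g_t = f.reduce(np.broadcast_to(n_c * t, (C, n_c.size)))
            g_tt = f.reduce(np.broadcast_to(n_c * t * t, (C, n_c.size)))
            prec = np.empty((C, f.n_levels, 2, 2))
            prec[..., 0, 0] = g_n / sig2[:, None] + 1.0 / su2[:, None]
            prec[..., 0, 1] = prec[..., 1, 0] = g_t / sig2[:, None]
            prec[..., 1, 1] = g_tt / sig2[:, None] + 1.0 / sv2[:, None]
            cov = _inv2(prec)
            h = np.stack(
                [g_r / sig2[:, None], g_rt / sig2[:, None]], axis=-1
            )
            mean = np.einsum("cgij,cgj->cgi", cov, h)
            draw = mvn2_draw(mean, cov, rng)
            state[f"u_{f.name}"] = draw[..., 0]
            state[f"v_{f.name}"] = draw[..., 1]

            _recenter(state, f, rng, (s0, s1), spec.random_slopes)
            _update_factor_sigmas(state, f, rng, spec.random_slopes)

        # --- residual sd
        mu = _eta_without(design, state, skip=None)
        rss = (sum_z2 - 2.0 * mu * sum_z + n_c * mu**2).sum(axis=-1)
        for c in range(C):
            state["ls_resid"][c] = _update_sigma(
                float(rss[c]), int(n_total), state["ls_resid"][c], rng
            )

        if it >= spec.burn_in:
            _store_iteration(store, state, design, it - spec.burn_in)

    return GlmmPosterior(_finalize_store(store, design), spec, design)
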