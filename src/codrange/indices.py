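"""Derived analysis variables from raw trawl-survey records.

* stomach-fullness index (stomach weight / length^3 x 10^4) and its
  log(x + offset) transform, with Box-Cox profile-likelihood support for the
  transform choice;
* per (year, subregion, age) occupancy proportions;
* bottom temperature standardized to a reference depth (200 m) and survey
  date (3 September) via an additive spline adjustment;
* equal-interval latitude/longitude grid binning as an alternative,
  design-free subregion definition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from .synth import REFERENCE_DEPTH_M, REFERENCE_DOY, Survey

__all__ = [
    "compute_csf",
    "transform_csf",
    "compute_csf_records",
    "BoxCoxResult",
    "boxcox_select",
    "compute_occupancy",
    "standardize_temperature",
    "bin_grid_subregions",
    "read_aggregated",
]

logger = logging.getLogger(__name__)

DEFAULT_CSF_OFFSET = 0.02
DEFAULT_LAMBDA_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)
# Bounding box of the survey region (lat south/north, lon west/east).
DEFAULT_BBOX = (68.0, 82.0, 14.0, 57.0)


def compute_csf(stomach_weight, length, *, weight_unit: str = "g"):
    """Length-standardized stomach-fullness index.

    ``stomach_weight / length^3 * 1e4`` with weight in grams and length in
    cm. ``weight_unit="mg"`` accepts milligram-precision weights and
    converts internally, yielding identical values.
    """
    w = np.asarray(stomach_weight, dtype=float)
    length = np.asarray(length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("fish length must be positive")
    if np.any(w < 0):
        raise ValueError("stomach weight must be non-negative")
    if weight_unit == "mg":
        w = w * 1e-3
    elif weight_unit != "g":
        raise ValueError(f"unknown weight unit {weight_unit!r}")
    out = w / length**3 * 1e4
    return out if out.ndim else float(out)


def transform_csf(csf, offset: float = DEFAULT_CSF_OFFSET):
    """Natural log of (CSF + offset); the offset keeps empty stomachs finite."""
    if offset <= 0:
        raise ValueError("offset must be > 0")
    csf = np.asarray(csf, dtype=float)
    if np.any(csf < 0):
        raise ValueError("CSF must be non-negative")
    out = np.log(csf + offset)
    return out if out.ndim else float(out)


def compute_csf_records(
    survey: Survey, offset: float = DEFAULT_CSF_OFFSET
) -> pd.DataFrame:
    """Fish-level table of CSF and transformed CSF with survey context.

    Columns: set_id, year, subregion, age, csf, csf_transformed.
    """
    fish = survey.fish
    meta = survey.sets[["set_id", "year", "subregion"]]
    df = fish.merge(meta, on="set_id", how="left", validate="many_to_one")
    df["csf"] = compute_csf(df["stomach_weight_g"], df["length_cm"])
    df["csf_transformed"] = transform_csf(df["csf"].to_numpy(), offset)
    return df[["set_id", "year", "subregion", "age", "csf", "csf_transformed"]]


@dataclass
class BoxCoxResult:
    lambda_grid: np.ndarray
    profile_loglik: np.ndarray
    lambda_hat: float
    offset: float


def boxcox_select(
    values,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    offset: float = DEFAULT_CSF_OFFSET,
) -> BoxCoxResult:
    """Box-Cox profile log-likelihood over a lambda grid on offset-shifted data.

    The profile log-likelihood at each lambda includes the Jacobian term
    ``(lambda - 1) * sum(log y)``; the grid maximizer is returned.
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda_grid must be non-empty")
    shifted = values + offset
    if np.any(shifted <= 0):
        idx = int(np.argwhere(shifted <= 0).ravel()[0])
        raise ValueError(
            f"value at index {idx} ({values.ravel()[idx]}) is non-positive "
            f"after adding offset {offset}"
        )
    ll = np.array([stats.boxcox_llf(lmb, shifted) for lmb in grid])
    lam = float(grid[int(np.argmax(ll))])
    return BoxCoxResult(grid, ll, lam, offset)


def compute_occupancy(survey: Survey | pd.DataFrame) -> pd.DataFrame:
    """Occupancy cells per (year, subregion, age).

    Returns one row per group with ``n_sets`` (trawl sets in that
    subregion-year), ``n_present`` (sets where the age was present) and the
    proportion. Subregion-years with no sets are absent, not zero-filled.
    """
    sets = survey.sets if isinstance(survey, Survey) else survey
    if sets.empty:
        raise ValueError("no trawl sets")
    present_cols = [c for c in sets.columns if c.startswith("present_age")]
    long = sets.melt(
        id_vars=["year", "subregion"],
        value_vars=present_cols,
        var_name="age",
        value_name="present",
    )
    long["age"] = long["age"].str.removeprefix("present_age").astype(int)
    cells = (
        long.groupby(["year", "subregion", "age"], sort=True)
        .agg(n_sets=("present", "size"), n_present=("present", "sum"))
        .reset_index()
    )
    cells["proportion"] = cells["n_present"] / cells["n_sets"]
    return cells


def _bspline_basis(x: np.ndarray, lo: float, hi: float, n_basis: int, ref: float):
    """Cubic B-spline design matrix minus its row at ``ref``, dropping the last
    column (the reference-differenced partition-of-unity basis is rank
    deficient by one)."""
    degree = 3
    n_interior = n_basis - degree - 1
    interior = (
        np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
        if n_interior > 0
        else np.array([])
    )
    knots = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    design = BSpline.design_matrix(
        np.clip(x, lo, hi), knots, degree, extrapolate=False
    ).toarray()
    ref_row = BSpline.design_matrix(
        np.array([ref]), knots, degree, extrapolate=False
    ).toarray()
    return (design - ref_row)[:, :-1]


def standardize_temperature(
    casts: pd.DataFrame,
    reference_depth: float = REFERENCE_DEPTH_M,
    reference_doy: int = REFERENCE_DOY,
    n_basis_depth: int = 5,
    n_basis_date: int = 4,
) -> pd.DataFrame:
    """Standardize bottom-temperature casts to a common depth and survey date.

    Fits ``temp ~ subregion-year cell means + s(depth) + s(day-of-year)``
    with regression splines and subtracts the fitted smooth adjustment
    relative to the reference point, so each cast's value is its prediction
    at (``reference_depth``, ``reference_doy``) plus its own residual. A
    cast already at the reference point is returned unchanged.

    ``casts`` needs columns set_id, year, subregion, depth_m, date,
    bottom_temp_c. Returns the same rows plus ``temp_std``.
    """
    import statsmodels.api as sm

    required = {"set_id", "year", "subregion", "depth_m", "date", "bottom_temp_c"}
    missing = required - set(casts.columns)
    if missing:
        raise ValueError(f"casts table is missing columns: {sorted(missing)}")
    out = casts.copy()
    temp = out["bottom_temp_c"].to_numpy(dtype=float)
    if len(out) < 10 or (
        out["depth_m"].nunique() == 1 and out["date"].nunique() == 1
    ):
        warnings.warn(
            "fewer than 10 casts or no depth/date variation; "
            "returning temperatures unadjusted",
            UserWarning,
        )
        out["temp_std"] = temp
        return out

    blocks = []
    depth = out["depth_m"].to_numpy(dtype=float)
    doy = out["date"].to_numpy(dtype=float)
    if out["depth_m"].nunique() > n_basis_depth:
        lo = min(depth.min(), reference_depth) - 1.0
        hi = max(depth.max(), reference_depth) + 1.0
        blocks.append(_bspline_basis(depth, lo, hi, n_basis_depth, reference_depth))
    else:
        logger.info("single-depth casts: depth smooth dropped from the adjustment")
    if out["date"].nunique() > n_basis_date:
        lo = min(doy.min(), reference_doy) - 1.0
        hi = max(doy.max(), reference_doy) + 1.0
        blocks.append(_bspline_basis(doy, lo, hi, n_basis_date, reference_doy))
    else:
        logger.info("single-date casts: date smooth dropped from the adjustment")
    cell = pd.get_dummies(
        out["subregion"].astype(str) + ":" + out["year"].astype(str), dtype=float
    ).to_numpy()
    if not blocks:
        out["temp_std"] = temp
        return out
    exog = np.column_stack([cell] + blocks)
    fit = sm.OLS(temp, exog).fit()
    n_smooth = sum(b.shape[1] for b in blocks)
    smooth_part = exog[:, -n_smooth:] @ fit.params[-n_smooth:]
    out["temp_std"] = temp - smooth_part
    return out


def bin_grid_subregions(
    latitudes,
    longitudes,
    n_lat: int,
    n_lon: int,
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX,
) -> list[tuple[int, int]]:
    """Equal-interval lat/lon grid labels over a bounding box.

    Intervals are half-open (a point on an interior edge joins the higher
    bin); the upper boundary belongs to the last bin. Labels are
    ``(lat_bin, lon_bin)`` 0-based pairs.
    """
    if n_lat < 1 or n_lon < 1:
        raise ValueError("n_lat and n_lon must be >= 1")
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    south, north, west, east = bbox
    if np.any((lat < south) | (lat > north) | (lon < west) | (lon > east)):
        idx = int(
            np.argwhere(
                (lat < south) | (lat > north) | (lon < west) | (lon > east)
            ).ravel()[0]
        )
        raise ValueError(
            f"coordinate ({lat.ravel()[idx]}, {lon.ravel()[idx]}) outside the "
            f"bounding box {bbox}"
        )
    ilat = np.minimum((np.floor((lat - south) / (north - south) * n_lat)).astype(int), n_lat - 1)
    ilon = np.minimum((np.floor((lon - west) / (east - west) * n_lon)).astype(int), n_lon - 1)
    return list(zip(ilat.tolist(), ilon.tolist()))


def read_aggregated(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Degraded-mode reader for an aggregated table (subregion, year, age,
    occupancy, mean CSF), skipping all fish-level steps.

    Returns ``(occupancy_cells, csf_cells)``; occupancy proportions come
    without trial counts, so ``n_sets``/``n_present`` are absent.
    """
    df = pd.read_csv(path)
    required = {"subregion", "year", "age", "occupancy", "mean_csf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"aggregated table missing columns: {sorted(missing)}")
    occ = df[["year", "subregion", "age", "occupancy"]].rename(
        columns={"occupancy": "proportion"}
    )
    csf = df[["year", "subregion", "age", "mean_csf"]]
    return occ, csf
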