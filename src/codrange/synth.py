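"""Synthetic bottom-trawl survey generator with known hierarchical structure.

The generator emulates a decade-long demersal trawl survey of a shelf sea
split into categorical subregions: each station visit (a "trawl set")
records bottom temperature, depth and sampling day, per-age-class presence
of the focal fish, and stomach-content weights of sampled individuals.

The statistical structure is exactly the one the downstream models assume:

* per-age, per-subregion occupancy follows a logit-linear trend in year,
  with random intercepts and slopes composed of age, subregion and
  age-by-subregion components;
* fish-level log-transformed stomach fullness, ``log(CSF + offset)``,
  follows a linear trend with the same random-effect composition plus
  Gaussian residual noise;
* subregion bottom temperature follows a linear trend plus a shared
  subregion-by-year anomaly (interannual variability) and per-cast noise;
* the subregion-level components of the stomach-fullness *intercepts* and
  the occupancy *slopes* are drawn from a bivariate normal with a
  configurable cross-correlation — the known truth that the correlation
  estimator is meant to recover.

All randomness derives from a single master seed via named
``numpy.random.SeedSequence`` streams, so identical configurations yield
byte-identical datasets.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SigmaComponents",
    "SynthConfig",
    "TrueParameters",
    "FishRecord",
    "TrawlSet",
    "Survey",
    "generate_parameters",
    "generate_survey",
    "generate_dataset",
    "write_survey",
    "read_survey",
]

# Station counts per survey year: within the observed 310-580 range, with the
# extremes placed in the years where they occurred and a total of 3,416 sets.
DEFAULT_SETS_PER_YEAR: tuple[int, ...] = (316, 580, 316, 316, 315, 315, 310, 316, 316, 316)

# Mean length-at-age (cm) for ages 1..10, a typical gadoid growth curve.
DEFAULT_LENGTH_MEAN: tuple[float, ...] = (15.0, 25.0, 35.0, 45.0, 55.0, 64.0, 72.0, 80.0, 87.0, 95.0)
DEFAULT_LENGTH_SD = 4.0

REFERENCE_YEAR = 2004
REFERENCE_DEPTH_M = 200.0
REFERENCE_DOY = 246  # 3 September


@dataclass(frozen=True)
class SigmaComponents:
    """Random-effect standard deviations for one coefficient of one response.

    ``age`` varies by age class only, ``subregion`` by subregion only (shared
    across ages), ``interaction`` independently per age-by-subregion cell.
    """

    age: float = 0.0
    subregion: float = 0.0
    interaction: float = 0.0

    def validate(self, name: str) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"{name}.{f.name} must be >= 0, got {v}")

    @property
    def subregion_level_sd(self) -> float:
        """SD of the across-subregion (within-age) part of the effect."""
        return float(np.hypot(self.subregion, self.interaction))


@dataclass(frozen=True)
class SynthConfig:
    """Full specification of one synthetic survey."""

    n_subregions: int = 11
    ages: tuple[int, ...] = tuple(range(1, 11))
    years: tuple[int, ...] = tuple(range(2004, 2014))
    sets_per_year: int | Sequence[int] | None = None
    fish_per_set_per_age: int = 1

    # Population-level trend coefficients.
    alpha_co: float = -0.5  # logit occupancy in the reference year
    beta_co: float = 0.15  # logit occupancy change per year
    alpha_csf: float = -1.5  # log(CSF + offset) in the reference year
    beta_csf: float = -0.04

    # Random-effect scales.
    sigma_a_co: SigmaComponents = SigmaComponents(0.8, 0.7, 0.7)
    sigma_b_co: SigmaComponents = SigmaComponents(0.05, 0.10, 0.10)
    sigma_a_csf: SigmaComponents = SigmaComponents(0.30, 0.35, 0.35)
    sigma_b_csf: SigmaComponents = SigmaComponents(0.02, 0.04, 0.04)

    # Cross-response correlation between the subregion-level components of
    # the CSF intercept and the occupancy slope (the expansion mechanism).
    rho_init_expansion: float = 0.8

    # Temperature model (per subregion).
    temp_intercepts: tuple[float, ...] | None = None
    temp_slopes: tuple[float, ...] | None = None
    sigma_temp: float = 0.3  # per-cast noise, degC
    sigma_temp_year: float = 0.4  # shared subregion-by-year anomaly, degC
    temp_depth_slope: float = 0.0  # degC per m, relative to 200 m
    temp_date_slope: float = 0.0  # degC per day, relative to 3 September

    sigma_resid_csf: float = 0.6
    prob_empty_stomach: float = 0.10
    csf_offset: float = 0.02

    length_mean_by_age: tuple[float, ...] | None = None
    length_sd: float = DEFAULT_LENGTH_SD
    depth_range: tuple[float, float] = (50.0, 450.0)
    doy_range: tuple[int, int] = (213, 273)  # Aug 1 - Sep 30

    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho_init_expansion <= 1.0:
            raise ValueError(
                "rho_init_expansion must lie in [-1, 1], got "
                f"{self.rho_init_expansion}"
            )
        for name in ("sigma_temp", "sigma_temp_year", "sigma_resid_csf", "length_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sigma_a_co", "sigma_b_co", "sigma_a_csf", "sigma_b_csf"):
            getattr(self, name).validate(name)
        if self.csf_offset <= 0:
            raise ValueError("csf_offset must be > 0")
        if not 0.0 <= self.prob_empty_stomach <= 1.0:
            raise ValueError("prob_empty_stomach must lie in [0, 1]")
        if self.n_subregions < 1:
            raise ValueError("n_subregions must be >= 1")

    @property
    def n_ages(self) -> int:
        return len(self.ages)

    @property
    def year_index(self) -> np.ndarray:
        """Years since the reference year (2004 -> 0)."""
        return np.asarray(self.years, dtype=float) - REFERENCE_YEAR

    def resolved_sets_per_year(self) -> np.ndarray:
        spec = self.sets_per_year
        n_years = len(self.years)
        if spec is None:
            if n_years == len(DEFAULT_SETS_PER_YEAR):
                return np.asarray(DEFAULT_SETS_PER_YEAR, dtype=int)
            return np.full(n_years, 342, dtype=int)
        if np.isscalar(spec):
            return np.full(n_years, int(spec), dtype=int)
        arr = np.asarray(spec, dtype=int)
        if arr.size != n_years:
            raise ValueError(
                f"sets_per_year has {arr.size} entries for {n_years} years"
            )
        return arr

    def resolved_temp_intercepts(self) -> np.ndarray:
        if self.temp_intercepts is not None:
            arr = np.asarray(self.temp_intercepts, dtype=float)
        else:
            arr = np.linspace(0.0, 4.0, self.n_subregions)
        if arr.size != self.n_subregions:
            raise ValueError("temp_intercepts length must equal n_subregions")
        return arr

    def resolved_temp_slopes(self) -> np.ndarray:
        if self.temp_slopes is not None:
            arr = np.asarray(self.temp_slopes, dtype=float)
        else:
            # Divergent subregional trends: cooling through stable to warming.
            arr = np.linspace(-0.05, 0.08, self.n_subregions)
        if arr.size != self.n_subregions:
            raise ValueError("temp_slopes length must equal n_subregions")
        return arr

    def resolved_length_means(self) -> np.ndarray:
        if self.length_mean_by_age is not None:
            arr = np.asarray(self.length_mean_by_age, dtype=float)
            if arr.size != self.n_ages:
                raise ValueError("length_mean_by_age length must match ages")
            return arr
        base = np.asarray(DEFAULT_LENGTH_MEAN, dtype=float)
        if self.n_ages <= base.size:
            return base[: self.n_ages]
        return np.interp(np.arange(self.n_ages), np.arange(base.size), base)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        for key in ("sigma_a_co", "sigma_b_co", "sigma_a_csf", "sigma_b_csf"):
            if key in d and isinstance(d[key], dict):
                d[key] = SigmaComponents(**d[key])
        for key in (
            "ages",
            "years",
            "temp_intercepts",
            "temp_slopes",
            "length_mean_by_age",
            "depth_range",
            "doy_range",
        ):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if isinstance(d.get("sets_per_year"), list):
            d["sets_per_year"] = tuple(d["sets_per_year"])
        return cls(**d)


@dataclass
class TrueParameters:
    """Generator ground truth: realized coefficient values per (age, subregion).

    Arrays are shaped ``(n_ages, n_subregions)`` except the per-subregion
    temperature coefficients. Totals include the population-level intercept
    and slope, so e.g. the realized logit-occupancy line of cell (i, j) is
    ``(alpha_co + a_co[i, j]) + (beta_co + b_co[i, j]) * t``.
    """

    config: SynthConfig
    a_co: np.ndarray
    b_co: np.ndarray
    a_csf: np.ndarray
    b_csf: np.ndarray
    alpha_temp: np.ndarray
    beta_temp: np.ndarray
    temp_year_anomaly: np.ndarray  # (n_subregions, n_years)

    def realized_init_expansion_correlation(self) -> np.ndarray:
        """Empirical per-age correlation across subregions between the realized
        CSF intercepts and occupancy slopes (the estimand of the correlation
        stage for this dataset)."""
        out = np.empty(self.config.n_ages)
        for i in range(self.config.n_ages):
            out[i] = np.corrcoef(self.a_csf[i], self.b_co[i])[0, 1]
        return out

    def population_init_expansion_correlation(self) -> float:
        """Closed-form correlation of the across-subregion parts of
        (CSF intercept, occupancy slope) implied by the configuration."""
        c = self.config
        num = c.rho_init_expansion * (
            c.sigma_a_csf.subregion * c.sigma_b_co.subregion
            + c.sigma_a_csf.interaction * c.sigma_b_co.interaction
        )
        den = c.sigma_a_csf.subregion_level_sd * c.sigma_b_co.subregion_level_sd
        return float(num / den) if den > 0 else np.nan

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "config": self.config.to_dict(),
            "a_co": self.a_co.tolist(),
            "b_co": self.b_co.tolist(),
            "a_csf": self.a_csf.tolist(),
            "b_csf": self.b_csf.tolist(),
            "alpha_temp": self.alpha_temp.tolist(),
            "beta_temp": self.beta_temp.tolist(),
            "temp_year_anomaly": self.temp_year_anomaly.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TrueParameters":
        payload = json.loads(Path(path).read_text())
        return cls(
            config=SynthConfig.from_dict(payload["config"]),
            a_co=np.asarray(payload["a_co"]),
            b_co=np.asarray(payload["b_co"]),
            a_csf=np.asarray(payload["a_csf"]),
            b_csf=np.asarray(payload["b_csf"]),
            alpha_temp=np.asarray(payload["alpha_temp"]),
            beta_temp=np.asarray(payload["beta_temp"]),
            temp_year_anomaly=np.asarray(payload["temp_year_anomaly"]),
        )


@dataclass(frozen=True)
class FishRecord:
    age: int
    length: float  # cm
    stomach_weight: float  # g


@dataclass(frozen=True)
class TrawlSet:
    set_id: int
    year: int
    subregion: int
    date: int  # day of year
    depth: float  # m
    bottom_temperature: float  # degC
    fish: tuple[FishRecord, ...]
    cod_present_by_age: dict[int, bool]


@dataclass
class Survey:
    """A generated survey as two tidy tables.

    ``sets`` has one row per trawl set (with 0/1 presence columns per age);
    ``fish`` one row per sampled fish. ``iter_trawl_sets`` yields the
    record-oriented view.
    """

    sets: pd.DataFrame
    fish: pd.DataFrame
    config: SynthConfig | None = None

    @property
    def ages(self) -> list[int]:
        return sorted(
            int(c.removeprefix("present_age"))
            for c in self.sets.columns
            if c.startswith("present_age")
        )

    def iter_trawl_sets(self) -> Iterator[TrawlSet]:
        fish_by_set: dict[int, list[FishRecord]] = {}
        for row in self.fish.itertuples(index=False):
            fish_by_set.setdefault(int(row.set_id), []).append(
                FishRecord(int(row.age), float(row.length_cm), float(row.stomach_weight_g))
            )
        ages = self.ages
        for row in self.sets.itertuples(index=False):
            yield TrawlSet(
                set_id=int(row.set_id),
                year=int(row.year),
                subregion=int(row.subregion),
                date=int(row.date),
                depth=float(row.depth_m),
                bottom_temperature=float(row.bottom_temp_c),
                fish=tuple(fish_by_set.get(int(row.set_id), ())),
                cod_present_by_age={
                    a: bool(getattr(row, f"present_age{a}")) for a in ages
                },
            )


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = [
        "parameters",
        "temp_anomaly",
        "station",
        "presence",
        "length",
        "stomach",
        "temperature",
    ]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _correlated_pair(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    sd_x: float,
    sd_y: float,
    rho: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (x, y) fields with Corr(x, y) = rho elementwise."""
    z1 = rng.standard_normal(shape)
    z2 = rng.standard_normal(shape)
    x = sd_x * z1
    y = sd_y * (rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * z2)
    return x, y


def generate_parameters(config: SynthConfig) -> TrueParameters:
    """Realize the random-effect structure and temperature trends.

    The subregion-main and interaction components of the pair
    (CSF intercept, occupancy slope) are each drawn with cross-correlation
    ``rho_init_expansion``; when the two components of each member have
    proportional standard deviations (as in the defaults) the correlation of
    the summed, across-subregion effects equals ``rho_init_expansion``
    exactly, otherwise it is attenuated (see
    :meth:`TrueParameters.population_init_expansion_correlation`).
    """
    rng = _streams(config.seed)["parameters"]
    n_i, n_j = config.n_ages, config.n_subregions

    def components(sig: SigmaComponents):
        return (
            sig.age * rng.standard_normal(n_i),
            sig.subregion * rng.standard_normal(n_j),
            sig.interaction * rng.standard_normal((n_i, n_j)),
        )

    # Correlated pair: a_csf (subregion + interaction parts) with b_co.
    a_csf_sub, b_co_sub = _correlated_pair(
        rng,
        (n_j,),
        config.sigma_a_csf.subregion,
        config.sigma_b_co.subregion,
        config.rho_init_expansion,
    )
    a_csf_int, b_co_int = _correlated_pair(
        rng,
        (n_i, n_j),
        config.sigma_a_csf.interaction,
        config.sigma_b_co.interaction,
        config.rho_init_expansion,
    )
    a_csf_age = config.sigma_a_csf.age * rng.standard_normal(n_i)
    b_co_age = config.sigma_b_co.age * rng.standard_normal(n_i)
    a_csf = a_csf_age[:, None] + a_csf_sub[None, :] + a_csf_int
    b_co = b_co_age[:, None] + b_co_sub[None, :] + b_co_int

    a_co_age, a_co_sub, a_co_int = components(config.sigma_a_co)
    a_co = a_co_age[:, None] + a_co_sub[None, :] + a_co_int
    b_csf_age, b_csf_sub, b_csf_int = components(config.sigma_b_csf)
    b_csf = b_csf_age[:, None] + b_csf_sub[None, :] + b_csf_int

    anomaly_rng = _streams(config.seed)["temp_anomaly"]
    anomaly = config.sigma_temp_year * anomaly_rng.standard_normal(
        (n_j, len(config.years))
    )
    return TrueParameters(
        config=config,
        a_co=a_co,
        b_co=b_co,
        a_csf=a_csf,
        b_csf=b_csf,
        alpha_temp=config.resolved_temp_intercepts(),
        beta_temp=config.resolved_temp_slopes(),
        temp_year_anomaly=anomaly,
    )


def _allocate_sets(n_sets: int, n_subregions: int) -> np.ndarray:
    """Equal allocation of a year's sets among subregions (remainder to the
    lowest-numbered subregions)."""
    base = n_sets // n_subregions
    counts = np.full(n_subregions, base, dtype=int)
    counts[: n_sets - base * n_subregions] += 1
    return counts


def generate_survey(config: SynthConfig, truth: TrueParameters) -> Survey:
    """Generate the trawl-set and fish tables implied by the realized truth."""
    streams = _streams(config.seed)
    rng_station = streams["station"]
    rng_presence = streams["presence"]
    rng_length = streams["length"]
    rng_stomach = streams["stomach"]
    rng_temp = streams["temperature"]

    n_j = config.n_subregions
    ages = np.asarray(config.ages)
    length_means = config.resolved_length_means()
    sets_per_year = config.resolved_sets_per_year()
    year_index = config.year_index

    set_rows = []
    fish_rows = []
    set_id = 0
    for yi, (year, n_year_sets) in enumerate(zip(config.years, sets_per_year)):
        t = year_index[yi]
        counts = _allocate_sets(int(n_year_sets), n_j)
        for j in range(n_j):
            n_here = counts[j]
            if n_here == 0:
                continue
            depth = rng_station.uniform(*config.depth_range, size=n_here)
            doy = rng_station.integers(
                config.doy_range[0], config.doy_range[1] + 1, size=n_here
            )
            temp = (
                truth.alpha_temp[j]
                + truth.beta_temp[j] * t
                + truth.temp_year_anomaly[j, yi]
                + config.temp_depth_slope * (depth - REFERENCE_DEPTH_M)
                + config.temp_date_slope * (doy - REFERENCE_DOY)
                + config.sigma_temp * rng_temp.standard_normal(n_here)
            )
            # Presence per (set, age) at the cell's logit-linear truth.
            eta = (config.alpha_co + truth.a_co[:, j]) + (
                config.beta_co + truth.b_co[:, j]
            ) * t
            p = 1.0 / (1.0 + np.exp(-eta))
            present = rng_presence.uniform(size=(n_here, ages.size)) < p[None, :]
            for s in range(n_here):
                sid = set_id
                set_id += 1
                row = {
                    "set_id": sid,
                    "year": int(year),
                    "subregion": j + 1,
                    "date": int(doy[s]),
                    "depth_m": float(depth[s]),
                    "bottom_temp_c": float(temp[s]),
                }
                for ai, age in enumerate(ages):
                    row[f"present_age{age}"] = int(present[s, ai])
                set_rows.append(row)
                for ai, age in enumerate(ages):
                    if not present[s, ai]:
                        continue
                    for _ in range(config.fish_per_set_per_age):
                        length = max(
                            5.0,
                            rng_length.normal(length_means[ai], config.length_sd),
                        )
                        z = (
                            config.alpha_csf
                            + truth.a_csf[ai, j]
                            + (config.beta_csf + truth.b_csf[ai, j]) * t
                            + config.sigma_resid_csf * rng_stomach.standard_normal()
                        )
                        csf = max(np.exp(z) - config.csf_offset, 0.0)
                        if rng_stomach.uniform() < config.prob_empty_stomach:
                            csf = 0.0
                        fish_rows.append(
                            {
                                "set_id": sid,
                                "age": int(age),
                                "length_cm": float(length),
                                "stomach_weight_g": float(csf * length**3 / 1e4),
                            }
                        )
    sets = pd.DataFrame(set_rows)
    fish = pd.DataFrame(
        fish_rows, columns=["set_id", "age", "length_cm", "stomach_weight_g"]
    )
    return Survey(sets=sets, fish=fish, config=config)


def generate_dataset(config: SynthConfig) -> tuple[Survey, TrueParameters]:
    """Convenience wrapper: realize parameters, then the survey."""
    truth = generate_parameters(config)
    return generate_survey(config, truth), truth


def write_survey(survey: Survey, destination: str | os.PathLike) -> None:
    """Write ``sets.csv`` and ``fish.csv`` (lossless round-trip with
    :func:`read_survey`)."""
    if survey.sets.empty:
        raise ValueError("refusing to write an empty survey")
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    survey.sets.to_csv(dest / "sets.csv", index=False)
    survey.fish.to_csv(dest / "fish.csv", index=False)


def read_survey(source: str | os.PathLike) -> Survey:
    src = Path(source)
    sets = pd.read_csv(src / "sets.csv")
    fish = pd.read_csv(src / "fish.csv")
    return Survey(sets=sets, fish=fish)
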