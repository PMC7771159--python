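"""End-to-end pipeline: generation (or CSV input) -> indices -> trend models
-> correlation inference, with a reproducibility manifest.

Every stage writes plain CSV; the manifest (JSON) records the configuration,
seeds, package versions and a diagnostics summary, and suffices to
reproduce a run bit-for-bit with the same library versions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import compare_models
from .correlation import JointSpec, correlation_report, estimate_correlations, fit_joint

from .glmm import GlmmSpec, fit_glmm
from .indices import compute_csf_records, compute_occupancy, standardize_temperature
from .synth import SynthConfig, generate_dataset, read_survey, write_survey

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A stage failed; partial outputs up to that stage remain on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Wiring of one full analysis run."""

    mode: str = "synthetic"  # "synthetic" or "csv"
    input_dir: str | None = None  # csv mode: directory with sets.csv / fish.csv
    synth: SynthConfig = field(default_factory=SynthConfig)
    glmm_specs: list[GlmmSpec] = field(
        default_factory=lambda: [
            GlmmSpec(response="occupancy", random_structure="age_by_subregion"),
            GlmmSpec(response="occupancy", random_structure="none"),
            GlmmSpec(response="csf", random_structure="age_by_subregion"),
        ]
    )
    joint_specs: list[JointSpec] = field(
        default_factory=lambda: [JointSpec(pair="csf_co"), JointSpec(pair="temp_co")]
    )
    outdir: str = "codrange_run"
    seed: int | None = None  # overrides the seeds of all stage specs
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "csv"):
            raise ValueError("mode must be 'synthetic' or 'csv'")
        if self.mode == "csv" and not self.input_dir:
            raise ValueError("csv mode requires input_dir")
        if self.seed is not None:
            self._reseed(int(self.seed))

    def _reseed(self, seed: int) -> None:
        ss = np.random.SeedSequence(seed)
        subseeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(
            1 + len(self.glmm_specs) + len(self.joint_specs)
        )]
        self.synth = dataclasses.replace(self.synth, seed=subseeds[0])
        self.glmm_specs = [
            dataclasses.replace(s, seed=subseeds[1 + i])
            for i, s in enumerate(self.glmm_specs)
        ]
        self.joint_specs = [
            dataclasses.replace(s, seed=subseeds[1 + len(self.glmm_specs) + i])
            for i, s in enumerate(self.joint_specs)
        ]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synth" in raw:
            raw["synth"] = SynthConfig.from_dict(raw["synth"])
        if "glmm_specs" in raw:
            raw["glmm_specs"] = [GlmmSpec(**d) for d in raw["glmm_specs"]]
        if "joint_specs" in raw:
            raw["joint_specs"] = [JointSpec(**d) for d in raw["joint_specs"]]
        return cls(**raw)


def _spec_name(spec: GlmmSpec) -> str:
    return f"{spec.response}_{spec.random_structure.value}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "mode": config.mode,
        "synth_config": config.synth.to_dict() if config.mode == "synthetic" else None,
        "glmm_specs": [dataclasses.asdict(s) for s in config.glmm_specs],
        "joint_specs": [dataclasses.asdict(s) for s in config.joint_specs],
        "stages": {},
        "diagnostics": {},
        "assumptions": [
            "temperature coefficients are broadcast across ages in the "
            "correlation stage (casts carry no age signal)",
            "occupancy is modelled at the aggregated (year, subregion, age) "
            "cell level",
        ],
    }
    timings: dict[str, float] = {}

    def stage(name):
        class _Ctx:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_.t0, 3)
                if exc is not None:
                    logger.error("stage %s: FAILED (%s)", name, exc)
                    raise PipelineStageError(name, exc) from exc
                logger.info("stage %s: done in %.1fs", name, timings[name])
                return False

        return _Ctx()

    # --- stage 1: data -----------------------------------------------------
    with stage("data"):
        if config.mode == "synthetic":
            survey, truth = generate_dataset(config.synth)
            write_survey(survey, out)
            truth.to_json(out / "truth.json")
            manifest["stages"]["data"] = {
                "sets": len(survey.sets),
                "fish": len(survey.fish),
            }
        else:
            survey = read_survey(config.input_dir)
            manifest["stages"]["data"] = {
                "sets": len(survey.sets),
                "fish": len(survey.fish),
                "input_dir": str(config.input_dir),
            }

    # --- stage 2: indices --------------------------------------------------
    with stage("indices"):
        csf = compute_csf_records(survey)
        occ = compute_occupancy(survey)
        temp = standardize_temperature(
            survey.sets[
                ["set_id", "year", "subregion", "depth_m", "date", "bottom_temp_c"]
            ]
        )
        csf.to_csv(out / "csf.csv", index=False)
        occ.to_csv(out / "occupancy.csv", index=False)
        temp.to_csv(out / "temperature_std.csv", index=False)
        manifest["stages"]["indices"] = {
            "csf_records": len(csf),
            "occupancy_cells": len(occ),
        }

    # --- stage 3: trend models --------------------------------------------
    with stage("glmm"):
        fits: dict[str, tuple] = {}
        for spec in config.glmm_specs:
            name = _spec_name(spec)
            data = occ if spec.response == "occupancy" else csf
            post, diag = fit_glmm(data, spec)
            fits[name] = (post, diag)
            post.to_frame().to_csv(out / f"posterior_{name}.csv", index=False)
            diag.to_frame().to_csv(out / f"diagnostics_{name}.csv", index=False)
            manifest["diagnostics"][name] = {
                "max_rhat": diag.max_rhat,
                "min_ess": diag.min_ess,
            }
        for response in ("occupancy", "csf"):
            group = {
                n: p for n, (p, _) in fits.items() if p.spec.response == response
            }
            if len(group) > 1:
                compare_models(group).to_csv(
                    out / f"model_comparison_{response}.csv", index=False
                )
        # Figure surfaces: fitted trend lines from the richest model of each
        # response, if present.
        for response, fname in (
            ("occupancy", "occupancy_trends.csv"),
            ("csf", "csf_trends.csv"),
        ):
            best = [
                p
                for n, (p, _) in fits.items()
                if p.spec.response == response
                and p.spec.random_structure.value == "age_by_subregion"
            ]
            if best:
                best[0].cell_trends().to_csv(out / fname, index=False)
        manifest["stages"]["glmm"] = {"models": list(fits)}

    # --- stage 4: correlation inference ------------------------------------
    with stage("correlation"):
        all_reports = []
        all_draws = []
        for jspec in config.joint_specs:
            data_resp = csf if jspec.pair == "csf_co" else temp
            post = fit_joint(data_resp, occ, jspec)
            ests = estimate_correlations(post)
            all_reports.append(correlation_report(ests))
            for e in ests:
                all_draws.append(
                    pd.DataFrame(
                        {
                            "age": e.age,
                            "pair": e.pair,
                            "draw": np.arange(e.draws.size),
                            "value": e.draws,
                        }
                    )
                )
            manifest["diagnostics"][f"joint_{jspec.pair}"] = {
                "acceptance": post.acceptance,
                "retained_total": jspec.retained_total,
            }
        report = pd.concat(all_reports, ignore_index=True)
        report.to_csv(out / "correlations.csv", index=False)
        pd.concat(all_draws, ignore_index=True).to_csv(
            out / "correlation_draws.csv", index=False
        )
        manifest["stages"]["correlation"] = {"rows": len(report)}

    manifest["timings_s"] = timings
    manifest_for_disk = {k: v for k, v in manifest.items() if k != "timings_s"}
    (out / "manifest.json").write_text(json.dumps(manifest_for_disk, indent=1, default=str))
    return manifest
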