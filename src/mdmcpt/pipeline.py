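"""End-to-end pipeline: generate task -> simulate cohort -> fit -> analyse.

A single YAML (or dict) configuration drives all stages.  Every stage
seed is derived deterministically from the master seed and the stage
name, so stages can be rerun independently and two runs with the same
config produce byte-identical CSV artifacts.  A JSON manifest records
the config hash, derived seeds, stage timings and artifact checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import pandas as pd
import yaml

from .cpt import CPTParams
from .task import TaskConfig, generate_task, validate_task, write_task_csv
from .cohort import GroupSpec, default_groups, simulate_cohort
from .model import FitSettings, fit_cohort_two_stage, fit_cohort_hierarchical
from . import analysis

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger("mdmcpt.pipeline")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: hash of (master seed, stage name)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Parsed pipeline configuration with study-shaped defaults."""

    seed: int = 0
    task: TaskConfig = field(default_factory=TaskConfig)
    groups: List[GroupSpec] = field(default_factory=default_groups)
    timeout_rate: float = 0.0
    fit_mode: str = "two-stage"           # or "hierarchical"
    fit_settings: FitSettings = field(default_factory=FitSettings)
    family_size_params: int = 12
    family_size_corr: int = 16
    single_domain_only: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        cfg.seed = int(d.get("seed", 0))
        if "task" in d:
            cfg.task = TaskConfig(**d["task"])
        if "groups" in d:
            cfg.groups = []
            for g in d["groups"]:
                kwargs = dict(g)
                if "param_means" in kwargs:
                    kwargs["param_means"] = CPTParams(**kwargs["param_means"])
                if "param_clinical_corr" in kwargs and kwargs["param_clinical_corr"]:
                    kwargs["param_clinical_corr"] = tuple(kwargs["param_clinical_corr"])
                cfg.groups.append(GroupSpec(**kwargs))
        cohort = d.get("cohort", {})
        cfg.timeout_rate = float(cohort.get("timeout_rate", d.get("timeout_rate", 0.0)))
        fit = d.get("fit", {})
        cfg.fit_mode = fit.get("mode", "two-stage")
        fs = {k: v for k, v in fit.items() if k != "mode"}
        if fs:
            cfg.fit_settings = FitSettings(**fs)
        ana = d.get("analysis", {})
        cfg.family_size_params = int(ana.get("family_size_params", 12))
        cfg.family_size_corr = int(ana.get("family_size_corr", 16))
        cfg.single_domain_only = bool(ana.get("single_domain_only", True))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> Dict:
    """Execute all stages, writing artifacts, a log and a manifest.

    Returns the manifest dict.  On stage failure the exception propagates
    after partial artifacts are left in place; the manifest names the
    completed stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest: Dict = {"seed": config.seed, "stages": {}, "artifacts": {}}
    config_repr = json.dumps({
        "seed": config.seed, "task": vars(config.task),
        "groups": [{"label": g.label, "n": g.n_subjects,
                    "means": g.param_means.to_dict(), "sds": g.param_sds}
                   for g in config.groups],
        "timeout_rate": config.timeout_rate, "fit_mode": config.fit_mode,
    }, sort_keys=True, default=str)
    manifest["config_sha256"] = hashlib.sha256(config_repr.encode()).hexdigest()

    def _stage(name):
        logger.info("stage %s: start", name)
        manifest["stages"][name] = {"seed": stage_seed(config.seed, name),
                                    "t_start": time.time()}
        return manifest["stages"][name]

    def _done(name, *paths):
        st = manifest["stages"][name]
        st["elapsed_s"] = round(time.time() - st["t_start"], 3)
        del st["t_start"]
        for p in paths:
            manifest["artifacts"][p.name] = _sha256(p)
        logger.info("stage %s: done (%.2fs)", name, st["elapsed_s"])

    try:
        # --- task -----------------------------------------------------
        st = _stage("task")
        task = generate_task(st["seed"], config.task)
        problems = validate_task(task, config.task)
        if problems:
            raise RuntimeError(f"stage task: generated task failed validation: {problems}")
        task_path = out / "task.csv"
        write_task_csv(task, task_path)
        _done("task", task_path)

        # --- cohort ---------------------------------------------------
        st = _stage("cohort")
        dataset = simulate_cohort(config.groups, task, seed=st["seed"],
                                  timeout_rate=config.timeout_rate)
        data_dir = out / "data"
        dataset.to_dir(data_dir)
        _done("cohort", data_dir / "choices.csv")

        # --- fit ------------------------------------------------------
        st = _stage("fit")
        settings = config.fit_settings
        if settings.seed == 0:
            from dataclasses import replace
            settings = replace(settings, seed=stage_seed(config.seed, "fit-starts"))
        fits_path = out / "fits.csv"
        if config.fit_mode == "hierarchical":
            hfit = fit_cohort_hierarchical(dataset, settings)
            fits_df = hfit.subject_blups
            (out / "hierarchical.json").write_text(json.dumps({
                "fixed_effects": {g: p.to_dict() for g, p in hfit.fixed_effects.items()},
                "random_effect_sds": hfit.random_effect_sds,
                "total_neg_log_lik": hfit.total_neg_log_lik,
                "dof_residual": hfit.dof_residual,
                "reference_group": hfit.reference_group,
                "dummy_offsets": hfit.dummy_offsets.to_dict(orient="records"),
            }, indent=1))
        else:
            result = fit_cohort_two_stage(dataset, settings)
            fits_df = result.to_frame()
            if result.skipped:
                logger.info("fit: skipped subjects below trial minimum: %s", result.skipped)
        fits_df.to_csv(fits_path, index=False)
        _done("fit", fits_path)

        # --- analysis -------------------------------------------------
        _stage("analysis")
        written = []
        sizes = fits_df.groupby("group").size()
        testable = sizes[sizes >= 2].index
        if len(testable) >= 2 and "HC" in testable:
            tt = analysis.group_parameter_tests(
                fits_df[fits_df["group"].isin(testable)],
                reference="HC", family_size=config.family_size_params)
            tt_path = out / "parameter_tests.csv"
            tt.to_csv(tt_path, index=False)
            written.append(tt_path)
            lam_rows = []
            for g in testable:
                r = analysis.one_sample_test_vs_one(
                    fits_df.loc[fits_df["group"] == g, "lam"])
                lam_rows.append({"group": g, "mean": r.mean_diff, "t": r.statistic,
                                 "dof": r.dof, "p": r.p_value, "d": r.cohens_d,
                                 "ci_low": r.ci_low, "ci_high": r.ci_high})
            lam_path = out / "loss_aversion_tests.csv"
            pd.DataFrame(lam_rows).to_csv(lam_path, index=False)
            written.append(lam_path)
        else:
            logger.info("analysis: group t-tests skipped "
                        "(need >= 2 groups with >= 2 fitted subjects incl. HC)")
        dev = analysis.delta_ev_analysis(dataset, task,
                                         single_domain_only=config.single_domain_only)
        dev_path = out / "delta_ev.csv"
        dev.to_csv(dev_path, index=False)
        written.append(dev_path)
        if dataset.clinical_scores is not None and len(fits_df):
            patients = fits_df[fits_df["group"] != "HC"]
            if len(patients) >= 3:
                corr = analysis.parameter_clinical_correlations(
                    patients, dataset.clinical_scores,
                    family_size=config.family_size_corr)
                corr_path = out / "clinical_correlations.csv"
                corr.to_csv(corr_path, index=False)
                written.append(corr_path)
        group_means = {
            g: CPTParams(**sub[list(analysis.PARAM_NAMES)].mean().to_dict())
            for g, sub in fits_df.groupby("group")}
        curve_paths = analysis.plot_functions(group_means, out / "figures")
        written.extend(Path(p) for p in curve_paths.values() if p.endswith(".csv"))
        _done("analysis", *written)

        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        logger.info("pipeline complete: %s", out)
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()
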