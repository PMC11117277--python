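"""End-to-end orchestration: simulate -> build -> weight/fit -> bias -> report.

One :class:`RunConfig` drives the full run. A single global seed spawns
independent per-stage RNG streams (generation, confounder imputation), so any
stage can be re-run from cached upstream artifacts with byte-identical
numeric outputs. Artifacts are plain CSV/JSON files in the output directory;
the :class:`RunManifest` records the selection-flow counts, per-stage wall
times and the output inventory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bias import BiasParameters, forest_summary, paired_grid, run_pba
from .cohort import (
    MAIN_COVARIATES,
    SUBGROUP_COVARIATES,
    build_analysis_table,
    load_drug_dictionary,
)
from .cox import cumulative_incidence, fit_weighted_cox, weighted_survival_curves
from .exceptions import ArtifactMissingError, ConfigurationError
from .propensity import fit_iptw
from .records import read_raw_csv, write_raw_csv
from .simulate import GeneratorConfig, generate_cohort

__all__ = ["RunConfig", "RunManifest", "run_pipeline",
           "stage_simulate", "stage_build", "stage_analyze", "stage_bias",
           "stage_report"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "empyema_run"
    input_csv: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    drug_dictionary_path: Optional[str] = None
    covariates_main: list[str] = field(default_factory=lambda: list(MAIN_COVARIATES))
    covariates_subgroup: list[str] = field(default_factory=lambda: list(SUBGROUP_COVARIATES))
    bias_grid: list[BiasParameters] = field(default_factory=paired_grid)
    bias_iterations: int = 2000
    require_thoracostomy: bool = True
    thoracostomy_day01: bool = False
    make_plots: bool = False

    def validate(self) -> None:
        if (self.input_csv is None) == (self.generator is None):
            raise ConfigurationError(
                "exactly one of input_csv and generator must be set")
        if self.seed is None:
            raise ConfigurationError("seed must be set")
        if self.bias_iterations < 1:
            raise ConfigurationError("bias_iterations must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "generator" in kwargs and kwargs["generator"] is not None:
            kwargs["generator"] = GeneratorConfig.from_dict(kwargs["generator"])
        if "bias_grid" in kwargs and kwargs["bias_grid"] is not None:
            kwargs["bias_grid"] = [BiasParameters(**cell) for cell in kwargs["bias_grid"]]
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bias_grid"] = [vars(c) for c in self.bias_grid]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seeds(self) -> dict[str, int]:
        """Independent per-stage integer seeds spawned from the global seed."""
        children = np.random.SeedSequence(self.seed).spawn(2)
        return {"simulate": int(children[0].generate_state(1)[0] % 2**31),
                "bias": int(children[1].generate_state(1)[0] % 2**31)}


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stage_counts: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _out(cfg: RunConfig) -> Path:
    p = Path(cfg.output_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise ArtifactMissingError(
            f"missing artifact {path.name}; run the {stage!r} stage first")
    return path


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def stage_simulate(cfg: RunConfig) -> dict:
    cfg.validate()
    if cfg.generator is None:
        raise ConfigurationError("simulate stage needs a generator config")
    out = _out(cfg)
    gen = GeneratorConfig(**{**cfg.generator.to_dict(), "seed": cfg.stage_seeds()["simulate"]})
    records = generate_cohort(gen)
    write_raw_csv(records, out / "raw.csv")
    return {"n_raw": len(records)}


def stage_build(cfg: RunConfig) -> dict:
    out = _out(cfg)
    src = Path(cfg.input_csv) if cfg.input_csv else out / "raw.csv"
    if cfg.input_csv is None:
        _require(src, "simulate")
    elif not src.exists():
        raise ArtifactMissingError(f"input file {src} not found")
    records = read_raw_csv(src)
    drug_dict = load_drug_dictionary(cfg.drug_dictionary_path)
    elig, df = build_analysis_table(
        records, drug_dict,
        require_thoracostomy=cfg.require_thoracostomy,
        thoracostomy_day01=cfg.thoracostomy_day01)
    df.to_csv(out / "cohort.csv", index=False)
    _write_json(out / "eligibility.json", elig.to_dict())
    return {"n_raw": len(records), **elig.to_dict()}


def _load_cohort(cfg: RunConfig) -> pd.DataFrame:
    out = _out(cfg)
    path = _require(out / "cohort.csv", "build-cohort")
    return pd.read_csv(path)


def stage_analyze(cfg: RunConfig) -> dict:
    out = _out(cfg)
    df = _load_cohort(cfg)
    cc = df[df["complete_case"]].reset_index(drop=True)
    sub = cc[cc["mdr_risk"]].reset_index(drop=True)

    fits = {}
    analyses = [("main", cc, cfg.covariates_main),
                ("subgroup", sub, cfg.covariates_subgroup)]
    smd_frames = []
    ps_coefs = {}
    curve_frames = []
    for label, data, covs in analyses:
        ps = fit_iptw(data, covs)
        ps_coefs[label] = ps.coefficients.to_dict()
        smd = ps.smd_table.reset_index()
        smd.insert(0, "analysis", label)
        smd_frames.append(smd)
        for cause in ("surgery", "death"):
            fit = fit_weighted_cox(data, ps.weights, cause)
            fits[f"{label}_{cause}"] = fit.to_dict()
            curves = weighted_survival_curves(data, ps.weights, cause, fit=fit)
            curves.insert(0, "analysis", label)
            curves.insert(1, "cause", cause)
            curve_frames.append(curves)
    _write_json(out / "cox_fits.json", fits)
    _write_json(out / "propensity.json", ps_coefs)
    pd.concat(smd_frames, ignore_index=True).to_csv(out / "smd.csv", index=False)
    pd.concat(curve_frames, ignore_index=True).to_csv(out / "curves.csv", index=False)

    cif_frames = [cumulative_incidence(df, g).to_frame()
                  for g in ("anti_pseudomonal", "non_anti_pseudomonal")]
    pd.concat(cif_frames, ignore_index=True).to_csv(out / "cif.csv", index=False)
    return {"n_complete_case": len(cc), "n_subgroup": len(sub), **{
        k: round(v["hr"], 4) for k, v in fits.items()}}


def stage_bias(cfg: RunConfig) -> dict:
    out = _out(cfg)
    df = _load_cohort(cfg)
    sub = df[df["complete_case"] & df["mdr_risk"]].reset_index(drop=True)
    results = run_pba(sub, grid=cfg.bias_grid, iterations=cfg.bias_iterations,
                      seed=cfg.stage_seeds()["bias"],
                      covariates=cfg.covariates_subgroup)
    summary = forest_summary(results)
    summary.to_csv(out / "bias_summary.csv", index=False)
    _write_json(out / "bias_results.json",
                [{**r.to_dict(), "adjusted_log_hrs": [round(v, 10) for v in r.adjusted_log_hrs]}
                 for r in results])
    if cfg.make_plots:
        from .bias import forest_plot
        forest_plot(results, out / "forest.png")
    return {"n_subgroup": len(sub), "n_cells": len(results)}


def stage_report(cfg: RunConfig) -> dict:
    out = _out(cfg)
    elig = json.loads(_require(out / "eligibility.json", "build-cohort").read_text())
    fits = json.loads(_require(out / "cox_fits.json", "analyze").read_text())
    smd = pd.read_csv(_require(out / "smd.csv", "analyze"))
    lines = ["# Empyema empirical-antibiotics analysis report", ""]
    lines += ["## Selection flow", ""]
    for k, v in elig.items():
        lines.append(f"- {k}: {v}")
    lines += ["", "## Covariate balance (max |SMD|)", ""]
    for label, g in smd.groupby("analysis"):
        lines.append(f"- {label}: unweighted {g.smd_unweighted.abs().max():.3f} "
                     f"-> weighted {g.smd_weighted.abs().max():.3f}")
    lines += ["", "## Cause-specific hazard ratios (IPTW, robust 95% CI)", ""]
    lines.append("| analysis | cause | HR | 95% CI | p | events/n |")
    lines.append("|---|---|---|---|---|---|")
    for key, f in fits.items():
        lines.append(f"| {key.rsplit('_', 1)[0]} | {f['cause']} | {f['hr']:.2f} "
                     f"| {f['ci95_low']:.2f}-{f['ci95_high']:.2f} "
                     f"| {f['p_value']:.3f} | {f['events']}/{f['n']} |")
    bias_path = out / "bias_summary.csv"
    if bias_path.exists():
        bias = pd.read_csv(bias_path)
        lines += ["", "## Probabilistic bias analysis (90-day death, subgroup)", ""]
        lines.append("| p1 | p0 | RRcd | median HR | 95% interval |")
        lines.append("|---|---|---|---|---|")
        for r in bias.itertuples():
            lines.append(f"| {r.p1} | {r.p0} | {r.rr_cd} | {r.median_hr:.2f} "
                         f"| {r.hr_ci95_low:.2f}-{r.hr_ci95_high:.2f} |")
    (out / "report.md").write_text("\n".join(lines) + "\n")
    return {"report_lines": len(lines)}


_STAGES = [("simulate", stage_simulate), ("build", stage_build),
           ("analyze", stage_analyze), ("bias", stage_bias),
           ("report", stage_report)]


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute all stages in order; any stage failure aborts with the stage
    name attached."""
    cfg.validate()
    manifest = RunManifest(config_hash=cfg.config_hash(), version=__version__)
    out = _out(cfg)
    for name, fn in _STAGES:
        if name == "simulate" and cfg.generator is None:
            continue
        t0 = time.perf_counter()
        try:
            counts = fn(cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest.stage_seconds[name] = round(time.perf_counter() - t0, 3)
        manifest.stage_counts[name] = counts
        log.info("stage=%s counts=%s", name, counts)
    manifest.outputs = sorted(p.name for p in out.iterdir() if p.is_file())
    _write_json(out / "manifest.json", manifest.to_dict())
    return manifest
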