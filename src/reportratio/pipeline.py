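"""End-to-end pipeline: load or simulate, analyze, write a report bundle.

A :class:`RunConfig` names exactly one data source (input files or a
simulate block) and the analysis stages to run. The bundle written to
the output directory contains full-precision CSVs, display-rounded
markdown tables, and a machine-readable manifest (seed, parameters,
exclusion counts) so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import model
from .bootstrap import bootstrap_ratio
from .errors import ConfigError, UndefinedProportionError, UndefinedRatioError
from .io import cohort_summary, read_cohort, write_cohort
from .model import Cohort, ROUND_2002
from .ratios import expanded_reporting_ratio, reporting_ratio, stratified_ratios
from .report import render_table
from .sensitivity import lifetime_match_proportion
from .simulate import GeneratorConfig, TruthLedger, generate_cohort

ANALYSES = ("ratios", "bootstrap", "sensitivity")


@dataclass
class RunConfig:
    """One pipeline run: a single data source plus analysis settings."""

    input: Optional[dict] = None      # {"respondents": path, "pregnancies": path, "schema": path|dict}
    simulate: Optional[dict] = None   # GeneratorConfig kwargs
    analyses: tuple[str, ...] = ("ratios",)
    B: int = 5000
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "results/run"
    decimals: int = 2

    def __post_init__(self) -> None:
        if (self.input is None) == (self.simulate is None):
            raise ConfigError("exactly one of input / simulate must be given")
        bad = [a for a in self.analyses if a not in ANALYSES]
        if bad:
            raise ConfigError(f"unknown analyses: {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        return cls(**raw)


def _load(config: RunConfig) -> tuple[Cohort, Optional[TruthLedger], dict]:
    if config.simulate is not None:
        gc_kwargs = dict(config.simulate)
        gc_kwargs.setdefault("seed", config.seed)
        if "interview_month" in gc_kwargs and isinstance(gc_kwargs["interview_month"], list):
            gc_kwargs["interview_month"] = tuple(gc_kwargs["interview_month"])
        gen = GeneratorConfig(**gc_kwargs)
        cohort, truth = generate_cohort(gen)
        meta = {"source": "simulate", "generator": dataclasses.asdict(gen),
                "n_loaded": len(cohort), "n_excluded": 0}
        return cohort, truth, meta
    inp = config.input
    schema = inp.get("schema")
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    cohort, report = read_cohort(inp["respondents"], inp.get("pregnancies"), schema)
    meta = {"source": "input", "paths": {k: str(v) for k, v in inp.items()
                                         if k != "schema"},
            "n_loaded": report.n_loaded, "n_excluded": report.n_excluded,
            "exclusions": report.excluded}
    return cohort, None, meta


def _ratio_stage(cohort: Cohort, decimals: int) -> tuple[pd.DataFrame, str]:
    rows = []
    for cat in model.CATEGORIES:
        try:
            est = reporting_ratio(cohort, cat)
        except UndefinedRatioError as exc:
            rows.append({"category": cat, "stratum_axis": "", "stratum_level": "",
                         "error": str(exc)})
            continue
        expanded = None
        if cohort.round != ROUND_2002:
            try:
                expanded = expanded_reporting_ratio(cohort, cat).ratio
            except UndefinedRatioError:
                expanded = None
        rows.append({"category": cat, "stratum_axis": "", "stratum_level": "",
                     "n_acasi": est.n_acasi, "n_ftf": est.n_ftf,
                     "ratio": est.ratio, "expanded_ratio": expanded,
                     "n_total": est.n_total, "error": ""})
        for axis in model.DEMOGRAPHIC_AXES:
            strat = stratified_ratios(cohort, cat, axis)
            for s in strat.estimates:
                rows.append({"category": cat, "stratum_axis": axis,
                             "stratum_level": s.stratum[1],
                             "n_acasi": s.n_acasi, "n_ftf": s.n_ftf,
                             "ratio": s.ratio, "expanded_ratio": None,
                             "n_total": s.n_total, "error": ""})
            for level, why in strat.failures.items():
                rows.append({"category": cat, "stratum_axis": axis,
                             "stratum_level": level, "error": why})
    df = pd.DataFrame(rows)
    overall = df[(df["stratum_axis"] == "") & (df["error"] == "")]
    md_rows = [
        {"round": cohort.round, "category": r["category"], "ratio": r["ratio"],
         "ci": None, "expanded_ratio": r["expanded_ratio"], "letters": ""}
        for _, r in overall.iterrows()
    ]
    return df, render_table(md_rows, "round_by_outcome", decimals)


def _bootstrap_stage(cohort: Cohort, config: RunConfig) -> pd.DataFrame:
    rows = []
    for cat in model.CATEGORIES:
        boot = bootstrap_ratio(cohort, cat, B=config.B,
                               seed=config.seed, alpha=config.alpha)
        rows.append({"category": cat, "window": boot.point.ftf_window_label,
                     "ratio": boot.point.ratio, "ci_low": boot.ci_low,
                     "ci_high": boot.ci_high, "B": boot.B,
                     "n_undefined": boot.n_undefined, "seed": boot.seed})
        if cohort.round != ROUND_2002:
            boot = bootstrap_ratio(cohort, cat, "expanded", B=config.B,
                                   seed=config.seed, alpha=config.alpha)
            rows.append({"category": cat, "window": "expanded",
                         "ratio": boot.point.ratio, "ci_low": boot.ci_low,
                         "ci_high": boot.ci_high, "B": boot.B,
                         "n_undefined": boot.n_undefined, "seed": boot.seed})
    return pd.DataFrame(rows)


def _sensitivity_stage(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for cat in model.CATEGORIES:
        # the source analysis reports births and abortions; the loss row
        # is computed the same way but flagged as extra output
        try:
            s = lifetime_match_proportion(cohort, cat)
            rows.append({"category": cat, "n_discordant": s.n_discordant,
                         "n_lifetime_match": s.n_lifetime_match,
                         "proportion": s.proportion,
                         "extra_output": cat == "loss", "error": ""})
        except UndefinedProportionError as exc:
            rows.append({"category": cat, "n_discordant": 0,
                         "n_lifetime_match": 0, "proportion": float("nan"),
                         "extra_output": cat == "loss", "error": str(exc)})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; return {artifact name: path}.

    A stage failure removes any partial outputs and re-raises with the
    failing stage named.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_csv(df: pd.DataFrame, name: str) -> Path:
        p = out_dir / name
        df.to_csv(p, index=False)
        written.append(p)
        return p

    def _write_text(text: str, name: str) -> Path:
        p = out_dir / name
        p.write_text(text + "\n")
        written.append(p)
        return p

    artifacts: dict[str, Path] = {}
    stage = "load"
    try:
        cohort, truth, meta = _load(config)
        artifacts["summary"] = _write_csv(cohort_summary(cohort), "summary.csv")
        if config.simulate is not None:
            rp, pp = out_dir / "respondents.csv", out_dir / "pregnancies.csv"
            write_cohort(cohort, rp, pp)
            written += [rp, pp]
            artifacts["respondents"], artifacts["pregnancies"] = rp, pp
            lp = out_dir / "truth_events.csv"
            truth.events.to_csv(lp, index=False)
            written.append(lp)
            artifacts["truth_events"] = lp
        if "ratios" in config.analyses:
            stage = "ratios"
            df, md = _ratio_stage(cohort, config.decimals)
            artifacts["ratios"] = _write_csv(df, "ratios.csv")
            artifacts["ratios_md"] = _write_text(md, "ratios.md")
        if "bootstrap" in config.analyses:
            stage = "bootstrap"
            artifacts["bootstrap"] = _write_csv(_bootstrap_stage(cohort, config),
                                                "bootstrap.csv")
        if "sensitivity" in config.analyses:
            stage = "sensitivity"
            artifacts["sensitivity"] = _write_csv(_sensitivity_stage(cohort),
                                                  "sensitivity.csv")
        stage = "manifest"
        manifest = {
            "seed": config.seed, "B": config.B, "alpha": config.alpha,
            "analyses": list(config.analyses), "decimals": config.decimals,
            "round": cohort.round, "n": len(cohort), "meta": meta,
        }
        p = out_dir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        written.append(p)
        artifacts["manifest"] = p
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return artifacts
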