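"""End-to-end pipeline: simulate/ingest -> impute -> score -> evaluate -> report.

Every artifact is written under one output directory and listed in a
manifest with content hashes; an identical config and seed reproduces the
manifest bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable, load_cohort, write_cohort
from .discrimination import confusion_at, roc_curve
from .impute import impute_fcs
from .inference import anova_tukey, table_one
from .scoring import score_cohort
from .simulate import GeneratorConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("fallrisk")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Exactly one input source is used: ``input_csv`` (an existing cohort) or
    ``generator`` (synthetic).  ``seed`` feeds every stochastic stage
    (generation, imputation, bootstrap).
    """

    out_dir: str = "fallrisk_out"
    input_csv: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    m: int = 8
    iterations: int = 10
    stratify_by_sex: bool = False
    cutoff: float | None = None          # None -> Youden-optimal
    n_boot: int = 2000
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d and not isinstance(d["generator"], GeneratorConfig):
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the artifact manifest.

    Writes (under ``config.out_dir``): the cohort CSV, the m imputed CSVs
    plus convergence trace, the scored CSV, a JSON ROC report with per-
    threshold CSV, and a cohort-characteristics report with the three-group
    ANOVA.  A failed stage raises :class:`PipelineError` naming the stage;
    artifacts written so far gain a ``.partial`` marker file.
    """
    out = Path(config.out_dir)
    if config.input_csv is not None and not Path(config.input_csv).exists():
        raise PipelineError(f"config: input_csv {config.input_csv!r} does not exist")
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stage = "setup"
    try:
        stage = "ingest"
        if config.input_csv is not None:
            cohort = load_cohort(config.input_csv)
        else:
            gen = config.generator
            gen.seed = config.seed
            cohort = generate_cohort(gen)
        log.info("cohort: %d participants, %d with missing cells", cohort.n,
                 int(cohort.data.isna().any(axis=1).sum()))
        cohort_csv = out / "cohort.csv"
        write_cohort(cohort, cohort_csv)
        artifacts.append(cohort_csv)
        sidecar = out / "cohort.provenance.json"
        sidecar.write_text(json.dumps(cohort.provenance, indent=1, default=str))
        artifacts.append(sidecar)

        stage = "impute"
        result = impute_fcs(cohort, m=config.m, iterations=config.iterations,
                            seed=config.seed)
        for k, tbl in enumerate(result.completed):
            p = out / f"cohort_imp{k}.csv"
            write_cohort(tbl, p)
            artifacts.append(p)
        trace_csv = out / "imputation_trace.csv"
        result.trace.to_csv(trace_csv, index=False)
        artifacts.append(trace_csv)
        pooled = result.pooled()

        stage = "score"
        scored = score_cohort(pooled, stratify_by_sex=config.stratify_by_sex)
        scored_df = pd.concat(
            [pooled.data.reset_index(drop=True), scored.to_frame()], axis=1)
        scored_csv = out / "scored.csv"
        scored_df.to_csv(scored_csv, index=False, float_format="%.6g")
        artifacts.append(scored_csv)

        stage = "evaluate"
        labels = pooled.recurrent_indicator()
        roc = roc_curve(scored.cfrs, labels)
        cutoff = config.cutoff if config.cutoff is not None else roc.youden_cutoff
        conf = confusion_at(scored.cfrs, labels, cutoff,
                            n_boot=config.n_boot, seed=config.seed)
        report = {
            "auc": roc.auc, "auc_ci": [roc.auc_ci_low, roc.auc_ci_high],
            "band": roc.band,
            "youden_cutoff": roc.youden_cutoff,
            "youden_index": roc.youden_index,
            "cutoff_used": cutoff,
            "confusion": {
                "tp": conf.tp, "fp": conf.fp, "tn": conf.tn, "fn": conf.fn,
                "sensitivity": conf.sensitivity,
                "sensitivity_ci": list(conf.sensitivity_ci),
                "specificity": conf.specificity,
                "specificity_ci": list(conf.specificity_ci),
                "ppv": conf.ppv, "ppv_ci": list(conf.ppv_ci),
                "npv": conf.npv, "npv_ci": list(conf.npv_ci),
            },
        }
        roc_json = out / "roc_report.json"
        roc_json.write_text(json.dumps(report, indent=1))
        artifacts.append(roc_json)
        roc_csv = out / "roc_curve.csv"
        pd.DataFrame({"threshold": roc.thresholds,
                      "sensitivity": roc.sensitivity,
                      "specificity": roc.specificity}).to_csv(
            roc_csv, index=False, float_format="%.6g")
        artifacts.append(roc_csv)

        stage = "report"
        t1 = table_one(pooled, scores=scored.cfrs)
        t1_csv = out / "table_one.csv"
        t1.to_csv(t1_csv, index=False, float_format="%.6g")
        artifacts.append(t1_csv)
        anova = anova_tukey(scored.cfrs, pooled.fall_group().to_numpy())
        anova_rows = [{"contrast": f"{a} vs {b}", **vals}
                      for (a, b), vals in anova.tukey.items()]
        anova_df = pd.DataFrame(anova_rows)
        anova_df.insert(0, "anova_p", anova.p_value)
        anova_df.insert(0, "anova_f", anova.f)
        anova_csv = out / "anova_tukey.csv"
        anova_df.to_csv(anova_csv, index=False, float_format="%.6g")
        artifacts.append(anova_csv)
    except PipelineError:
        raise
    except Exception as exc:
        for p in artifacts:
            marker = p.with_suffix(p.suffix + ".partial")
            marker.touch()
        raise PipelineError(f"{stage}: {exc}") from exc

    manifest = {"seed": config.seed,
                "files": {p.name: _sha256(p) for p in sorted(artifacts)}}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
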