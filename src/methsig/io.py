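"""Delimited-text I/O for matrices, cohorts, immune scores and configs.

All tables are tab-separated with a header row; missing values are empty
fields. Stage-omics matrices have genes as rows and stages as columns.
Patient tables carry ``patient_id, time_months, event, stage, grade,
debulk`` followed by molecular columns prefixed ``meth_`` (beta values)
and ``expr_`` (expression intensities).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .datatypes import ImmuneProfile, PlantedTruth, StageOmics, SurvivalCohort
from .simulate import SimConfig

_CLINICAL_COLS = ["time_months", "event", "stage", "grade", "debulk"]


def read_stage_omics(meth_path: str | Path, expr_path: str | Path) -> StageOmics:
    meth = pd.read_csv(meth_path, sep="\t", index_col=0)
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    return StageOmics(methylation=meth, expression=expr)


def write_stage_omics(omics: StageOmics, meth_path: str | Path, expr_path: str | Path) -> None:
    omics.methylation.rename_axis("gene").to_csv(meth_path, sep="\t")
    omics.expression.rename_axis("gene").to_csv(expr_path, sep="\t")


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """BED-like TSS annotation: columns chrom, tss, strand, gene."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "tss", "strand", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    return df


def write_cohort(cohort: SurvivalCohort, path: str | Path) -> None:
    out = cohort.table[_CLINICAL_COLS].copy()
    for g in cohort.values.columns:
        out[f"meth_{g}"] = cohort.values[g]
    if cohort.expression is not None:
        for g in cohort.expression.columns:
            out[f"expr_{g}"] = cohort.expression[g]
    out.rename_axis("patient_id").to_csv(path, sep="\t")


def read_cohort(path: str | Path, cohort_id: str | None = None) -> SurvivalCohort:
    df = pd.read_csv(path, sep="\t", index_col="patient_id")
    meth_cols = [c for c in df.columns if c.startswith("meth_")]
    expr_cols = [c for c in df.columns if c.startswith("expr_")]
    values = df[meth_cols].rename(columns=lambda c: c.removeprefix("meth_"))
    expression = (
        df[expr_cols].rename(columns=lambda c: c.removeprefix("expr_"))
        if expr_cols
        else None
    )
    clinical = [c for c in _CLINICAL_COLS if c in df.columns]
    return SurvivalCohort(
        cohort_id or Path(path).stem, df[clinical], values, expression
    )


def write_immune_profile(profile: ImmuneProfile, path: str | Path) -> None:
    profile.scores.rename_axis("patient_id").to_csv(path, sep="\t")


def read_immune_profile(path: str | Path) -> ImmuneProfile:
    return ImmuneProfile(pd.read_csv(path, sep="\t", index_col="patient_id"))


def write_planted_truth(truth: PlantedTruth, path: str | Path) -> None:
    rows = [
        {"kind": "candidate", "gene": g, "info1": phase, "info2": klass}
        for g, phase, klass in truth.candidate_genes
    ]
    rows += [
        {"kind": "risk", "gene": g, "info1": direction, "info2": hr}
        for g, direction, hr in truth.risk_genes
    ]
    rows += [
        {"kind": "immune", "gene": g, "info1": cell, "info2": sign}
        for g, cell, sign in truth.immune_links
    ]
    pd.DataFrame(rows, columns=["kind", "gene", "info1", "info2"]).to_csv(
        path, sep="\t", index=False
    )


def load_sim_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from a YAML (or JSON, a YAML subset) key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "planted_per_phase" in raw:
        raw["planted_per_phase"] = {
            k: tuple(v) for k, v in raw["planted_per_phase"].items()
        }
    for key in ("risk_genes", "immune_link"):
        if key in raw:
            raw[key] = tuple(tuple(item) for item in raw[key])
    return SimConfig(**raw)
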