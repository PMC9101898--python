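"""Immune-infiltration context: gene-score correlation and joint strata.

Surrogate analyses relating a gene's molecular level to immune-cell
infiltration scores (cytotoxic T lymphocytes, M1/M2 macrophages, T
follicular helper cells, cancer-associated fibroblasts): a correlation
test between the gene and a score, and a four-way survival comparison of
the joint gene-high/low x cell-high/low strata (median splits, ties to
the low arm). Infiltration scores are consumed as given — no
deconvolution is performed here.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ImmuneProfile,
    KmCurve,
    SurvivalCohort,
    ValidationError,
)
from .signature import km_estimate, multi_group_logrank, survival_at

STRATA_ORDER = ("high/high", "high/low", "low/high", "low/low")


class CorrelationResult(NamedTuple):
    r: float
    p: float
    n: int


def correlate_gene_infiltrate(
    gene_values: np.ndarray,
    scores: np.ndarray,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlate a gene's values with an infiltration score.

    Positive r means higher gene level with higher infiltration. Pearson
    by default; Spearman is the rank-based option for bounded methylation
    betas. Requires >= 3 complete pairs and non-constant inputs.
    """
    x = np.asarray(gene_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("gene values and scores must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


class JointStrataResult(NamedTuple):
    km: dict[str, KmCurve | None]
    sizes: dict[str, int]
    logrank_p: float
    logrank_statistic: float
    df: int
    worst_stratum: str
    survival_at_horizon: dict[str, float]


def joint_strata_survival(
    cohort: SurvivalCohort,
    profile: ImmuneProfile,
    gene: str,
    cell_type: str,
    gene_cutoff: float | None = None,
    cell_cutoff: float | None = None,
    layer: str = "expression",
    horizon_months: float = 60.0,
) -> JointStrataResult:
    """Survival across the four gene x infiltration high/low strata.

    Both axes are split at their medians unless explicit cutoffs are
    given; values at the cutoff go to the low arm. Empty strata are
    reported with n = 0 and excluded from the log-rank test (df reduced).
    The worst stratum is the one with the lowest survival at the horizon
    (ties broken by final survival value, then by fixed stratum order).
    """
    if cell_type not in profile.scores.columns:
        raise ValidationError(f"unknown immune cell type {cell_type!r}")
    values = cohort.expression if layer == "expression" else cohort.values
    if values is None or gene not in values.columns:
        raise ValidationError(f"gene {gene!r} not found in cohort layer {layer!r}")

    g = values[gene].astype(float)
    s = profile.scores[cell_type].reindex(g.index).astype(float)
    keep = g.notna() & s.notna()
    g, s = g[keep], s[keep]
    if len(g) == 0:
        raise ValidationError("no analysable patients")
    g_cut = float(np.median(g)) if gene_cutoff is None else gene_cutoff
    c_cut = float(np.median(s)) if cell_cutoff is None else cell_cutoff
    gene_high = g > g_cut
    cell_high = s > c_cut

    times = cohort.table.loc[g.index, "time_months"].to_numpy(float)
    events = cohort.table.loc[g.index, "event"].to_numpy(int)

    masks = {
        "high/high": gene_high & cell_high,
        "high/low": gene_high & ~cell_high,
        "low/high": ~gene_high & cell_high,
        "low/low": ~gene_high & ~cell_high,
    }
    km: dict[str, KmCurve | None] = {}
    sizes: dict[str, int] = {}
    surv: dict[str, float] = {}
    samples: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in STRATA_ORDER:
        m = masks[name].to_numpy()
        sizes[name] = int(m.sum())
        if sizes[name] == 0:
            km[name] = None
            continue
        samples[name] = (times[m], events[m])
        km[name] = km_estimate(times[m], events[m])
        surv[name] = survival_at(km[name], horizon_months)

    if len(samples) >= 2:
        lr = multi_group_logrank(samples)
        stat, df, p = lr.statistic, lr.df, lr.p
    else:
        stat, df, p = 0.0, 0, 1.0

    def _rank(name: str) -> tuple[float, float, int]:
        curve = km[name]
        final = curve.survival[-1] if curve and curve.survival else 1.0
        return (surv.get(name, 1.0), final, STRATA_ORDER.index(name))

    worst = min(samples.keys(), key=_rank)
    return JointStrataResult(km, sizes, float(p), float(stat), df, worst, surv)
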