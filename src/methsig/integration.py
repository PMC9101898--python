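"""Promoter-window definition, sample QC and three-phase candidate selection.

The integration step crosses differential promoter methylation with
differential expression along the three differentiation-phase contrasts
(A: SR1 vs SR2; B: spheroids vs early adherent; C: early vs late adherent)
and keeps only the discordant pairings — hypomethylated with up-regulated
expression or hypermethylated with down-regulated expression. Thresholds
are closed: a group-mean beta change of exactly 0.10 counts as a DMR and a
group-mean expression ratio of exactly 1.5 (or 1/1.5) as a DEG.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    PHASE_CONTRASTS,
    PHASES,
    CandidateGene,
    ConfigurationError,
    ContrastResult,
    GenomicInterval,
    PhaseContrast,
    StageOmics,
    ValidationError,
)

DELTA_BETA_THRESHOLD = 0.10
FOLD_CHANGE_THRESHOLD = 1.5
PROMOTER_HALF_WIDTH = 1000  # bp on each side of the TSS


def make_promoter_window(tss: int, chrom: str, strand: str = ".") -> GenomicInterval:
    """Return the 2 kb promoter window spanning 1 kb up- and downstream of a TSS.

    The span is symmetric so the strand is recorded but does not move the
    window; the start is clipped at coordinate 0 on contig edges.
    Coordinates are 0-based half-open.
    """
    if tss < 0:
        raise ValidationError(f"TSS coordinate must be >= 0, got {tss}")
    return GenomicInterval(
        chrom=chrom,
        start=max(0, tss - PROMOTER_HALF_WIDTH),
        end=tss + PROMOTER_HALF_WIDTH,
        strand=strand,
    )


def qc_filter_samples(
    sample_stats: Iterable[tuple[str, float]], min_unique_fraction: float = 0.40
) -> list[str]:
    """Retain samples whose uniquely-mapped read fraction is >= 40%.

    The boundary is inclusive; input order is preserved.
    """
    retained = []
    for sample_id, frac in sample_stats:
        if not 0.0 <= frac <= 1.0:
            raise ValidationError(
                f"uniquely-mapped fraction for {sample_id} outside [0, 1]: {frac}"
            )
        if frac >= min_unique_fraction:
            retained.append(sample_id)
    return retained


def _group_means(
    omics: StageOmics, contrast: PhaseContrast
) -> tuple[pd.Series, pd.Series, pd.Series, pd.Series]:
    for stage in contrast.baseline_stages + contrast.comparison_stages:
        if stage not in omics.stages:
            raise ConfigurationError(f"stage {stage!r} missing from omics matrices")
    mb = omics.methylation[list(contrast.baseline_stages)].mean(axis=1)
    mc = omics.methylation[list(contrast.comparison_stages)].mean(axis=1)
    eb = omics.expression[list(contrast.baseline_stages)].mean(axis=1)
    ec = omics.expression[list(contrast.comparison_stages)].mean(axis=1)
    return mb, mc, eb, ec


def contrast_table(omics: StageOmics, contrast: PhaseContrast) -> pd.DataFrame:
    """Vectorised per-gene contrast over all genes.

    Columns: delta_beta, fold_change, dmr_flag, dmr_direction, deg_flag,
    deg_direction; indexed by gene.
    """
    mb, mc, eb, ec = _group_means(omics, contrast)
    delta = mc - mb
    fc = ec / eb
    # closed thresholds with a tiny tolerance so that exact-boundary group
    # means (e.g. 0.60 - 0.50) are not lost to floating-point rounding
    eps = 1e-9
    dmr = delta.abs() >= DELTA_BETA_THRESHOLD - eps
    deg = (fc >= FOLD_CHANGE_THRESHOLD - eps) | (
        fc <= 1.0 / FOLD_CHANGE_THRESHOLD + eps
    )
    dmr_dir = np.where(~dmr, "none", np.where(delta < 0, "hypo", "hyper"))
    deg_dir = np.where(~deg, "none", np.where(fc > 1, "up", "down"))
    return pd.DataFrame(
        {
            "phase_id": contrast.phase_id,
            "delta_beta": delta,
            "fold_change": fc,
            "dmr_flag": dmr,
            "dmr_direction": dmr_dir,
            "deg_flag": deg,
            "deg_direction": deg_dir,
        }
    )


def compute_contrast(
    omics: StageOmics, contrast: PhaseContrast, gene: str
) -> ContrastResult:
    """Differential methylation/expression call for one gene in one phase."""
    if gene not in omics.genes:
        raise KeyError(f"gene {gene!r} not in omics matrices")
    row = contrast_table(omics, contrast).loc[gene]
    return ContrastResult(
        gene=gene,
        phase_id=contrast.phase_id,
        delta_beta=float(row["delta_beta"]),
        fold_change=float(row["fold_change"]),
        dmr_flag=bool(row["dmr_flag"]),
        dmr_direction=str(row["dmr_direction"]),
        deg_flag=bool(row["deg_flag"]),
        deg_direction=str(row["deg_direction"]),
    )


def select_candidates(results: Sequence[ContrastResult]) -> list[CandidateGene]:
    """Keep the discordant DMR+DEG genes (hypo+up, hyper+down) only.

    Concordant pairings and single-omic hits are excluded. Output sorted by
    (phase, class, gene).
    """
    seen: set[tuple[str, str]] = set()
    out: list[CandidateGene] = []
    for r in results:
        key = (r.phase_id, r.gene)
        if key in seen:
            raise ValidationError(f"duplicate result for gene {r.gene} in phase {r.phase_id}")
        seen.add(key)
        if not (r.dmr_flag and r.deg_flag):
            continue
        if r.dmr_direction == "hypo" and r.deg_direction == "up":
            out.append(CandidateGene(r.gene, r.phase_id, "hypo_up"))
        elif r.dmr_direction == "hyper" and r.deg_direction == "down":
            out.append(CandidateGene(r.gene, r.phase_id, "hyper_down"))
    out.sort(key=lambda c: (c.phase_id, c.klass, c.gene))
    return out


def run_all_phases(
    omics: StageOmics,
) -> tuple[dict[str, list[CandidateGene]], list[CandidateGene]]:
    """Apply the three phase contrasts and pool the candidates.

    Returns per-phase candidate lists plus the pooled list; the pooled
    count tallies distinct (gene, phase) pairs, so a gene recurring in two
    phases contributes twice, matching per-phase tallies.
    """
    per_phase: dict[str, list[CandidateGene]] = {}
    pooled: list[CandidateGene] = []
    for phase in PHASES:
        contrast = PHASE_CONTRASTS[phase]
        table = contrast_table(omics, contrast)
        hits = table[table["dmr_flag"] & table["deg_flag"]]
        cands = [
            CandidateGene(gene, phase, "hypo_up")
            if row["dmr_direction"] == "hypo" and row["deg_direction"] == "up"
            else CandidateGene(gene, phase, "hyper_down")
            for gene, row in hits.iterrows()
            if (row["dmr_direction"] == "hypo" and row["deg_direction"] == "up")
            or (row["dmr_direction"] == "hyper" and row["deg_direction"] == "down")
        ]
        cands.sort(key=lambda c: (c.phase_id, c.klass, c.gene))
        per_phase[phase] = cands
        pooled.extend(cands)
    return per_phase, pooled
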