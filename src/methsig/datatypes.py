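"""Shared domain containers.

The package operates on three substrates:

* stage-level omics — gene x stage methylation (beta fractions) and
  expression (positive intensities) matrices over the six differentiation
  stages SR1, SR2, AD1-AD4 of the ovarian-cancer-stem-cell model;
* patient survival cohorts — progression-free-survival time/event plus
  per-gene molecular values and clinical covariates;
* derived analysis records — phase-contrast results, recurrent-risk-score
  votes, signature risk assignments, Kaplan-Meier curves and Cox terms.

All tabular data live in pandas objects; the dataclasses here add the
domain invariants (betas in [0,1], positive expression, vote bounds, ...)
and small convenience accessors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGES = ("SR1", "SR2", "AD1", "AD2", "AD3", "AD4")

#: The three differentiation-phase contrasts: A compares the stem spheroid
#: SR1 against the progenitor spheroid SR2; B compares pooled spheroids
#: against early adherent progeny; C compares early against late adherent
#: progeny.
PHASES = ("A", "B", "C")

RISK_GROUP_LABELS = ("0-1", "2", ">=3")

SIGNATURE_GENES = ("GNPDA1", "GPD1", "GRASP", "HOXC11", "MSLN")

IMMUNE_CELL_TYPES = ("CTL", "M1", "M2", "Tfh", "CAF")


class MethsigError(Exception):
    """Base class for package errors."""


class ValidationError(MethsigError, ValueError):
    """Invalid input values or malformed containers."""


class ConfigurationError(MethsigError, ValueError):
    """Inconsistent simulation or analysis configuration."""


class InsufficientDataError(MethsigError, ValueError):
    """Too few observations for the requested computation."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based (BED convention)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"unknown strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class StageOmics:
    """Gene x stage methylation-beta and expression matrices.

    Both matrices are indexed by gene with one column per stage; the six
    canonical stages must all be present (extra stages are permitted).
    """

    methylation: pd.DataFrame
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        m, e = self.methylation, self.expression
        if not m.index.equals(e.index) or not m.columns.equals(e.columns):
            raise ValidationError("methylation/expression matrices must be aligned")
        missing = [s for s in STAGES if s not in m.columns]
        if missing:
            raise ConfigurationError(f"missing stages: {missing}")
        mv = m.to_numpy(dtype=float)
        if np.isnan(mv).any() or (mv < 0).any() or (mv > 1).any():
            raise ValidationError("methylation betas must lie in [0, 1]")
        ev = e.to_numpy(dtype=float)
        if np.isnan(ev).any() or (ev <= 0).any():
            raise ValidationError("expression intensities must be strictly positive")

    @property
    def genes(self) -> pd.Index:
        return self.methylation.index

    @property
    def stages(self) -> pd.Index:
        return self.methylation.columns


@dataclass(frozen=True)
class PhaseContrast:
    """A baseline-vs-comparison stage grouping along differentiation."""

    phase_id: str
    baseline_stages: tuple[str, ...]
    comparison_stages: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.baseline_stages or not self.comparison_stages:
            raise ValidationError("contrast groups must be non-empty")
        if set(self.baseline_stages) & set(self.comparison_stages):
            raise ValidationError("contrast groups must be disjoint")


#: Phase A: stem vs progenitor spheroids; phase B: spheroids vs early
#: adherent cells; phase C: early vs late adherent cells.
PHASE_CONTRASTS: dict[str, PhaseContrast] = {
    "A": PhaseContrast("A", ("SR1",), ("SR2",)),
    "B": PhaseContrast("B", ("SR1", "SR2"), ("AD1", "AD2")),
    "C": PhaseContrast("C", ("AD1", "AD2"), ("AD3", "AD4")),
}


@dataclass(frozen=True)
class ContrastResult:
    """Per-gene differential methylation/expression call for one phase.

    ``delta_beta`` is comparison-group mean beta minus baseline-group mean
    beta; ``fold_change`` is the ratio of group-mean expression
    (comparison over baseline) on the linear intensity scale.
    """

    gene: str
    phase_id: str
    delta_beta: float
    fold_change: float
    dmr_flag: bool
    dmr_direction: str  # hypo | hyper | none
    deg_flag: bool
    deg_direction: str  # up | down | none


@dataclass(frozen=True)
class CandidateGene:
    """A gene with discordant methylation/expression change in one phase."""

    gene: str
    phase_id: str
    klass: str  # hypo_up | hyper_down

    def __post_init__(self) -> None:
        if self.klass not in {"hypo_up", "hyper_down"}:
            raise ValidationError(f"unknown candidate class {self.klass!r}")


@dataclass
class SurvivalCohort:
    """Patients with PFS follow-up, per-gene molecular values and covariates.

    ``table`` is indexed by patient id with columns ``time_months`` (> 0),
    ``event`` (0/1) and the clinical covariates ``stage`` (early/late),
    ``grade`` (G1-G3), ``debulk`` (optimal/suboptimal). ``values`` holds the
    molecular level analysed for survival (methylation beta by default),
    one column per gene, aligned to the same patients. ``expression`` is an
    optional second layer used by the immune-context analyses.
    """

    cohort_id: str
    table: pd.DataFrame
    values: pd.DataFrame
    expression: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"time_months", "event"}
        if not required <= set(self.table.columns):
            raise ValidationError(f"cohort table needs columns {sorted(required)}")
        t = self.table["time_months"].to_numpy(dtype=float)
        if (t <= 0).any() or np.isnan(t).any():
            raise ValidationError("survival times must be positive")
        ev = self.table["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValidationError("event indicator must be 0/1")
        if not self.values.index.equals(self.table.index):
            raise ValidationError("values must be aligned to the patient table")
        if self.expression is not None and not self.expression.index.equals(
            self.table.index
        ):
            raise ValidationError("expression must be aligned to the patient table")

    @property
    def n_patients(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "SurvivalCohort":
        return SurvivalCohort(
            self.cohort_id,
            self.table.copy(),
            self.values.copy(),
            None if self.expression is None else self.expression.copy(),
        )


@dataclass(frozen=True)
class CutoffGrid:
    """Five per-gene dichotomisation thresholds at the quartile/tertile/median
    percentiles (25, 33.3, 50, 66.7, 75) of the cohort's values."""

    gene: str
    thresholds: tuple[float, ...]
    probs: tuple[float, ...]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.probs):
            raise ValidationError("one threshold per probability")
        if any(b < a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValidationError("thresholds must be non-decreasing")


@dataclass(frozen=True)
class EndpointSpec:
    """A PFS endpoint: follow-up truncated at ``horizon_months`` (inf = overall)."""

    endpoint_id: str
    horizon_months: float

    def __post_init__(self) -> None:
        if not self.horizon_months > 0:
            raise ValidationError("horizon must be positive (or inf)")


#: The three endpoints of the recurrent risk score: 1.5 years, 3 years, overall.
ENDPOINTS: tuple[EndpointSpec, ...] = (
    EndpointSpec("18m", 18.0),
    EndpointSpec("36m", 36.0),
    EndpointSpec("overall", math.inf),
)


@dataclass(frozen=True)
class ConditionVote:
    """One cell of the 5 x 3 cutoff-by-endpoint grid.

    vote = +1 when the low-value arm has significantly inferior survival,
    -1 when the high-value arm does, 0 otherwise (including degenerate
    splits with an empty arm or no events).
    """

    gene: str
    cutoff_id: str
    endpoint_id: str
    logrank_p: float
    inferior_group: str  # low | high | none
    vote: int

    def __post_init__(self) -> None:
        if self.vote not in (-1, 0, 1):
            raise ValidationError("vote must be -1, 0 or +1")


@dataclass(frozen=True)
class RrsResult:
    """The recurrent risk score: 15 condition votes and their signed sum."""

    gene: str
    cohort_id: str
    votes: tuple[ConditionVote, ...]
    total: int

    def __post_init__(self) -> None:
        if len(self.votes) != 15:
            raise ValidationError("an RRS is defined over exactly 15 conditions")
        if self.total != sum(v.vote for v in self.votes):
            raise ValidationError("total must equal the vote sum")
        if not -15 <= self.total <= 15:
            raise ValidationError("total out of [-15, 15]")


@dataclass(frozen=True)
class SignatureEntry:
    gene: str
    risk_direction: str  # low_value_at_risk | high_value_at_risk
    cutoff: float

    def __post_init__(self) -> None:
        if self.risk_direction not in {"low_value_at_risk", "high_value_at_risk"}:
            raise ValidationError(f"unknown risk direction {self.risk_direction!r}")


@dataclass(frozen=True)
class SignatureSpec:
    """A dichotomised multi-gene risk signature."""

    entries: tuple[SignatureEntry, ...]

    def __post_init__(self) -> None:
        genes = [e.gene for e in self.entries]
        if len(set(genes)) != len(genes):
            raise ValidationError("signature genes must be unique")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(e.gene for e in self.entries)


@dataclass(frozen=True)
class RiskAssignment:
    """A patient's count of signature genes at risk and derived group."""

    patient_id: str
    n_risk: int
    group: str

    def __post_init__(self) -> None:
        expected = risk_group_label(self.n_risk)
        if self.group != expected:
            raise ValidationError(
                f"group {self.group!r} inconsistent with n_risk={self.n_risk}"
            )


def risk_group_label(n_risk: int) -> str:
    """Map a risk-gene count to the three clinical strata 0-1 / 2 / >=3."""
    if n_risk < 0:
        raise ValidationError("n_risk must be non-negative")
    if n_risk <= 1:
        return "0-1"
    if n_risk == 2:
        return "2"
    return ">=3"


@dataclass(frozen=True)
class KmCurve:
    """Product-limit survival curve evaluated at the distinct event times."""

    event_times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    n: int = 0

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.event_times, self.event_times[1:])):
            raise ValidationError("event times must be strictly increasing")
        if any(b > a + 1e-12 for a, b in zip(self.survival, self.survival[1:])):
            raise ValidationError("survival must be non-increasing")
        if any(not 0 <= s <= 1 for s in self.survival):
            raise ValidationError("survival values must lie in [0, 1]")


@dataclass(frozen=True)
class CoxResult:
    """One term of a proportional-hazards fit (Wald CI and p)."""

    term: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    reference: bool = False

    def __post_init__(self) -> None:
        if not math.isnan(self.hr) and not (self.ci_low <= self.hr <= self.ci_high):
            raise ValidationError("CI must bracket the hazard ratio")


@dataclass
class ImmuneProfile:
    """Per-patient immune-infiltration scores (CTL, M1, M2, Tfh, CAF)."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        unknown = [c for c in self.scores.columns if c not in IMMUNE_CELL_TYPES]
        if unknown:
            raise ValidationError(f"unknown immune cell types: {unknown}")
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValidationError("immune scores must be finite")

    @property
    def cell_types(self) -> pd.Index:
        return self.scores.columns


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a simulation: which genes carry planted effects."""

    candidate_genes: tuple[tuple[str, str, str], ...] = ()  # (gene, phase, class)
    risk_genes: tuple[tuple[str, str, float], ...] = ()  # (gene, direction, HR)
    immune_links: tuple[tuple[str, str, str], ...] = ()  # (gene, cell_type, sign)
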