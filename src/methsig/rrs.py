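"""Recurrent risk score (RRS): quantile-grid survival vote counting.

For each gene the cohort is dichotomised at five quantile cutoffs of its
molecular values (25%, 33.3%, 50%, 66.7%, 75%) and survival between the
low and high arms is compared under three progression-free-survival
endpoints (censored at 18 months, at 36 months, and uncensored/overall):
15 conditions in total. A condition votes +1 when the low arm has
significantly inferior survival, -1 when the high arm does, 0 otherwise;
the RRS is the signed sum over the grid, an integer in [-15, 15]. A gene
is selected when its RRS is concordantly extreme in two independent
cohorts (default: >= +2 in both, or <= -2 in both).

The two-group log-rank test is implemented here directly because the vote
sign needs the per-arm observed-minus-expected event direction alongside
the chi-square p-value; the statistic uses the standard hypergeometric
variance with ties handled per distinct event time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ENDPOINTS,
    ConditionVote,
    CutoffGrid,
    EndpointSpec,
    InsufficientDataError,
    RrsResult,
    SurvivalCohort,
    ValidationError,
)

DEFAULT_ALPHA = 0.05

#: quartile / tertile / median probabilities of the cutoff grid
CUTOFF_PROBS = (0.25, 1.0 / 3.0, 0.50, 2.0 / 3.0, 0.75)
CUTOFF_IDS = ("q25", "q33", "q50", "q67", "q75")


def quantile_cutoffs(
    values: Sequence[float] | np.ndarray,
    probs: Sequence[float] = CUTOFF_PROBS,
    gene: str = "",
) -> CutoffGrid:
    """Sample quantiles (linear interpolation between order statistics).

    Requires at least 10 finite values; a constant input yields five equal
    thresholds and is flagged degenerate.
    """
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("non-finite values in quantile input")
    if arr.size < 10:
        raise InsufficientDataError(
            f"need >= 10 values for the cutoff grid, got {arr.size}"
        )
    thresholds = tuple(float(q) for q in np.quantile(arr, probs, method="linear"))
    degenerate = thresholds[0] == thresholds[-1]
    return CutoffGrid(
        gene=gene, thresholds=thresholds, probs=tuple(probs), degenerate=degenerate
    )


def dichotomize(values: np.ndarray | Sequence[float], threshold: float) -> np.ndarray:
    """Boolean low-arm mask: value <= threshold -> low, else high."""
    if not math.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    return np.asarray(values, dtype=float) <= threshold


def restrict_endpoint(cohort: SurvivalCohort, spec: EndpointSpec) -> SurvivalCohort:
    """Administratively censor follow-up at the endpoint horizon.

    Observations beyond the horizon become censored at the horizon; the
    overall endpoint (infinite horizon) is the identity.
    """
    if math.isinf(spec.horizon_months):
        return cohort
    out = cohort.copy()
    t = out.table["time_months"].to_numpy(dtype=float)
    e = out.table["event"].to_numpy(dtype=int)
    over = t > spec.horizon_months
    t[over] = spec.horizon_months
    e[over] = 0
    out.table["time_months"] = t
    out.table["event"] = e
    return out


def _restrict_arrays(
    times: np.ndarray, events: np.ndarray, horizon: float
) -> tuple[np.ndarray, np.ndarray]:
    if math.isinf(horizon):
        return times, events
    over = times > horizon
    return np.where(over, horizon, times), np.where(over, 0, events)


class LogrankOutcome(NamedTuple):
    statistic: float
    p: float
    inferior_group: str  # low | high | none
    observed_minus_expected_low: float


def logrank_test(
    times_low: np.ndarray,
    events_low: np.ndarray,
    times_high: np.ndarray,
    events_high: np.ndarray,
) -> LogrankOutcome:
    """Two-group log-rank test with the inferior arm identified.

    The chi-square statistic (1 df) is (O_low - E_low)^2 / V with O/E/V
    accumulated over distinct event times; ties use the hypergeometric
    variance. The inferior arm is the one with more observed than expected
    events. Degenerate inputs (an empty arm, or no events) return
    statistic 0, p = 1, inferior 'none'.
    """
    tl = np.asarray(times_low, dtype=float)
    th = np.asarray(times_high, dtype=float)
    el = np.asarray(events_low, dtype=int)
    eh = np.asarray(events_high, dtype=int)
    if tl.size + th.size == 0:
        raise ValidationError("empty pooled input")
    if tl.size == 0 or th.size == 0 or (el.sum() + eh.sum()) == 0:
        return LogrankOutcome(0.0, 1.0, "none", 0.0)

    all_sorted = np.sort(np.concatenate([tl, th]))
    low_sorted = np.sort(tl)
    ev_all = np.sort(np.concatenate([tl[el == 1], th[eh == 1]]))
    ev_low = np.sort(tl[el == 1])

    uniq = np.unique(ev_all)
    # events at each distinct event time, overall and in the low arm
    d = np.searchsorted(ev_all, uniq, "right") - np.searchsorted(ev_all, uniq, "left")
    d1 = np.searchsorted(ev_low, uniq, "right") - np.searchsorted(ev_low, uniq, "left")
    # numbers at risk (time >= t) just before each event time
    n = all_sorted.size - np.searchsorted(all_sorted, uniq, "left")
    n1 = low_sorted.size - np.searchsorted(low_sorted, uniq, "left")

    o_low = float(d1.sum())
    e_low = float((d * n1 / n).sum())
    frac = n1 / n
    with np.errstate(invalid="ignore"):
        v_terms = d * frac * (1.0 - frac) * (n - d) / (n - 1)
    var = float(v_terms[n > 1].sum())
    diff = o_low - e_low
    if var <= 0:
        return LogrankOutcome(0.0, 1.0, "none", diff)
    statistic = diff * diff / var
    p = float(stats.chi2.sf(statistic, df=1))
    if diff > 0:
        inferior = "low"
    elif diff < 0:
        inferior = "high"
    else:
        inferior = "none"
    return LogrankOutcome(float(statistic), p, inferior, float(diff))


def score_condition(
    times: np.ndarray,
    events: np.ndarray,
    low_mask: np.ndarray,
    gene: str = "",
    cutoff_id: str = "",
    endpoint_id: str = "",
    alpha: float = DEFAULT_ALPHA,
) -> ConditionVote:
    """Vote for one cutoff x endpoint condition.

    +1: low arm significantly inferior (p < alpha); -1: high arm; 0
    otherwise. Degenerate splits (an empty arm) vote 0.
    """
    low_mask = np.asarray(low_mask, dtype=bool)
    if low_mask.all() or (~low_mask).all():
        return ConditionVote(gene, cutoff_id, endpoint_id, 1.0, "none", 0)
    out = logrank_test(
        times[low_mask], events[low_mask], times[~low_mask], events[~low_mask]
    )
    vote = 0
    if out.p < alpha and out.inferior_group == "low":
        vote = 1
    elif out.p < alpha and out.inferior_group == "high":
        vote = -1
    return ConditionVote(gene, cutoff_id, endpoint_id, out.p, out.inferior_group, vote)


def compute_rrs(
    cohort: SurvivalCohort,
    gene: str,
    alpha: float = DEFAULT_ALPHA,
    endpoints: tuple[EndpointSpec, ...] = ENDPOINTS,
) -> RrsResult:
    """Enumerate the 15-condition grid for one gene and sum the votes.

    The grid is walked in fixed order: cutoffs ascending, endpoints 18m,
    36m, overall within each cutoff. Patients missing the gene's value are
    excluded; at least 10 analysable patients are required.
    """
    if gene not in cohort.values.columns:
        raise KeyError(f"gene {gene!r} not in cohort {cohort.cohort_id}")
    vals = cohort.values[gene]
    keep = vals.notna().to_numpy()
    vals = vals.to_numpy(dtype=float)[keep]
    if vals.size < 10:
        raise InsufficientDataError(
            f"only {vals.size} analysable patients for {gene}"
        )
    times = cohort.table["time_months"].to_numpy(dtype=float)[keep]
    events = cohort.table["event"].to_numpy(dtype=int)[keep]

    grid = quantile_cutoffs(vals, gene=gene)
    restricted = {
        ep.endpoint_id: _restrict_arrays(times, events, ep.horizon_months)
        for ep in endpoints
    }
    votes = []
    for cutoff_id, threshold in zip(CUTOFF_IDS, grid.thresholds):
        low = dichotomize(vals, threshold)
        for ep in endpoints:
            t_ep, e_ep = restricted[ep.endpoint_id]
            votes.append(
                score_condition(
                    t_ep, e_ep, low, gene, cutoff_id, ep.endpoint_id, alpha
                )
            )
    total = int(sum(v.vote for v in votes))
    return RrsResult(gene, cohort.cohort_id, tuple(votes), total)


def select_concordant(
    rrs_a: RrsResult, rrs_b: RrsResult, mode: str = "strict"
) -> str:
    """Dual-cohort concordance verdict for one gene.

    ``strict`` (default): hypomethylation-risk when both totals exceed +1
    (i.e. >= 2), hypermethylation-risk when both fall below -1.
    ``sign``: the looser reading — both totals strictly positive, or both
    strictly negative.
    """
    if rrs_a.gene != rrs_b.gene:
        raise ValidationError(
            f"gene mismatch: {rrs_a.gene!r} vs {rrs_b.gene!r}"
        )
    if mode == "strict":
        lo, hi = 1, -1
    elif mode == "sign":
        lo, hi = 0, 0
    else:
        raise ValidationError(f"unknown concordance mode {mode!r}")
    if rrs_a.total > lo and rrs_b.total > lo:
        return "selected_hypo_risk"
    if rrs_a.total < hi and rrs_b.total < hi:
        return "selected_hyper_risk"
    return "not_selected"


def compute_rrs_table(
    cohort_a: SurvivalCohort,
    cohort_b: SurvivalCohort,
    genes: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "strict",
) -> pd.DataFrame:
    """RRS totals and concordance verdicts for many genes over two cohorts.

    Returns one row per gene with the 15 per-condition votes of each
    cohort, both totals and the selection verdict.
    """
    if genes is None:
        genes = [g for g in cohort_a.values.columns if g in cohort_b.values.columns]
    rows = []
    for gene in genes:
        ra = compute_rrs(cohort_a, gene, alpha=alpha)
        rb = compute_rrs(cohort_b, gene, alpha=alpha)
        row: dict[str, object] = {"gene": gene}
        for tag, res in (("a", ra), ("b", rb)):
            for v in res.votes:
                row[f"vote_{tag}_{v.cutoff_id}_{v.endpoint_id}"] = v.vote
            row[f"total_{tag}"] = res.total
        row["verdict"] = select_concordant(ra, rb, mode=mode)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
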