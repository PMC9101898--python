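"""Multi-gene methylation risk signature: coding, KM/log-rank, Cox.

Each signature gene dichotomises a patient's molecular value at a
per-gene cutoff; the count of genes on the unfavourable side ("genes at
risk") stratifies patients into the three clinical groups 0-1 / 2 / >=3.
Group separation is evaluated with Kaplan-Meier curves, the k-sample
log-rank test and crude/adjusted Cox proportional-hazards models
(reference levels: 0-1 genes at risk, early stage, grade G1, optimal
debulking). Kaplan-Meier estimation, the multi-group log-rank test and
Cox fitting are delegated to lifelines (Efron tie handling, Wald CIs).
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .datatypes import (
    ENDPOINTS,
    CoxResult,
    InsufficientDataError,
    KmCurve,
    RiskAssignment,
    RrsResult,
    SignatureEntry,
    SignatureSpec,
    SurvivalCohort,
    ValidationError,
    risk_group_label,
)
from .rrs import dichotomize, logrank_test, quantile_cutoffs

RISK_GROUP_ORDER = ("0-1", "2", ">=3")

REFERENCE_LEVELS: dict[str, str] = {
    "risk_group": "0-1",
    "stage": "early",
    "grade": "G1",
    "debulk": "optimal",
}

LEVEL_ORDER: dict[str, tuple[str, ...]] = {
    "risk_group": RISK_GROUP_ORDER,
    "stage": ("early", "late"),
    "grade": ("G1", "G2", "G3"),
    "debulk": ("optimal", "suboptimal"),
}


def code_risk(
    values: Mapping[str, float], spec: SignatureSpec, patient_id: str = ""
) -> RiskAssignment | None:
    """Count a patient's signature genes at risk and derive the group.

    A gene counts as at risk when its value falls on the unfavourable side
    of its cutoff: <= cutoff for ``low_value_at_risk`` (ties at the cutoff
    count as at risk), > cutoff for ``high_value_at_risk``. Patients
    missing any signature gene are excluded (returns None with a warning).
    """
    n_risk = 0
    for entry in spec.entries:
        v = values.get(entry.gene)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            warnings.warn(
                f"patient {patient_id or '<unknown>'} missing value for "
                f"{entry.gene}; excluded from risk grouping",
                stacklevel=2,
            )
            return None
        if entry.risk_direction == "low_value_at_risk":
            at_risk = v <= entry.cutoff
        else:
            at_risk = v > entry.cutoff
        n_risk += int(at_risk)
    return RiskAssignment(patient_id, n_risk, risk_group_label(n_risk))


def assign_risk_groups(cohort: SurvivalCohort, spec: SignatureSpec) -> pd.DataFrame:
    """Risk counts and groups for every complete-case patient of a cohort.

    Returns a DataFrame indexed by patient id with columns ``n_risk`` and
    ``group``; patients missing any signature gene are dropped.
    """
    missing = [g for g in spec.genes if g not in cohort.values.columns]
    if missing:
        raise ValidationError(f"signature genes absent from cohort: {missing}")
    rows = {}
    for pid, vals in cohort.values[list(spec.genes)].iterrows():
        ra = code_risk(vals.to_dict(), spec, patient_id=str(pid))
        if ra is not None:
            rows[pid] = (ra.n_risk, ra.group)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["n_risk", "group"])
    df.index.name = "patient_id"
    return df


def km_estimate(
    times: Sequence[float] | np.ndarray, events: Sequence[int] | np.ndarray
) -> KmCurve:
    """Product-limit (Kaplan-Meier) survival estimate with right censoring.

    Censoring ties at an event time are processed after the event (the
    standard convention). The curve records survival at each distinct
    event time together with the number at risk just before it.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValidationError("empty survival input")
    if (t <= 0).any():
        raise ValidationError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    ev_rows = table[table["observed"] > 0]
    ev_times = [float(x) for x in ev_rows.index if x > 0]
    surv = [float(s) for s in kmf.survival_function_at_times(ev_times)]
    at_risk = [int(table.loc[x, "at_risk"]) for x in ev_times]
    return KmCurve(tuple(ev_times), tuple(surv), tuple(at_risk), n=int(t.size))


def survival_at(curve: KmCurve, t: float = 60.0) -> float:
    """Step-function value of a KM curve at time ``t`` (right-continuous).

    Returns 1 before the first event; at an event time, the post-step
    value; after the last event, the last step value.
    """
    if t <= 0:
        raise ValidationError("evaluation time must be positive")
    value = 1.0
    for et, s in zip(curve.event_times, curve.survival):
        if et <= t:
            value = s
        else:
            break
    return value


class MultiLogrankResult(NamedTuple):
    statistic: float
    df: int
    p: float


def multi_group_logrank(
    groups: Mapping[str, tuple[np.ndarray, np.ndarray]]
) -> MultiLogrankResult:
    """k-sample log-rank test over labelled (times, events) samples.

    Reduces to the two-sample statistic when k = 2. All-censored pooled
    data is degenerate and returns statistic 0, p = 1.
    """
    labels_nonempty = {k: v for k, v in groups.items() if len(v[0]) > 0}
    k = len(labels_nonempty)
    if k < 2:
        raise ValidationError("need at least two non-empty groups")
    times = np.concatenate([np.asarray(v[0], float) for v in labels_nonempty.values()])
    events = np.concatenate([np.asarray(v[1], int) for v in labels_nonempty.values()])
    labels = np.concatenate(
        [np.repeat(name, len(v[0])) for name, v in labels_nonempty.items()]
    )
    if events.sum() == 0:
        return MultiLogrankResult(0.0, k - 1, 1.0)
    res = multivariate_logrank_test(times, labels, events)
    return MultiLogrankResult(
        float(res.test_statistic), k - 1, float(res.p_value)
    )


def _fit_cox(
    df: pd.DataFrame, terms: Sequence[str], warn_epv: bool = True
) -> list[CoxResult]:
    """Shared Cox machinery: dummy-code terms against their reference levels,
    fit with Efron ties, report Wald CIs, flag non-estimable levels."""
    data = df[["time_months", "event"]].copy()
    results: list[CoxResult] = []
    colmap: list[tuple[str, str, str]] = []  # (column, term, level)
    for term in terms:
        ref = REFERENCE_LEVELS.get(term)
        levels = [
            lv for lv in LEVEL_ORDER.get(term, tuple(pd.unique(df[term])))
            if lv in set(df[term])
        ]
        if ref not in levels:
            raise ValidationError(f"reference level {ref!r} absent for term {term}")
        for lv in levels:
            if lv == ref:
                continue
            col = f"{term}[{lv}]"
            data[col] = (df[term] == lv).astype(float)
            colmap.append((col, term, lv))
    n_events = int(data["event"].sum())
    if n_events == 0:
        raise InsufficientDataError("no events; Cox model not estimable")
    if warn_epv and n_events < 10 * len(colmap):
        warnings.warn(
            f"{n_events} events for {len(colmap)} parameters: fewer than 10 "
            "events per parameter, estimates may be unstable",
            stacklevel=3,
        )
    cph = CoxPHFitter()
    cph.fit(data, duration_col="time_months", event_col="event")
    summ = cph.summary
    for term in terms:
        ref = REFERENCE_LEVELS.get(term)
        results.append(
            CoxResult(f"{term}={ref}", 1.0, 1.0, 1.0, math.nan, reference=True)
        )
        for col, tname, lv in colmap:
            if tname != term:
                continue
            row = summ.loc[col]
            hr = float(row["exp(coef)"])
            lo = float(row["exp(coef) lower 95%"])
            hi = float(row["exp(coef) upper 95%"])
            p = float(row["p"])
            if not (math.isfinite(hr) and math.isfinite(lo) and math.isfinite(hi)):
                results.append(
                    CoxResult(f"{term}={lv}", math.nan, math.nan, math.nan, math.nan)
                )
            else:
                results.append(CoxResult(f"{term}={lv}", hr, lo, hi, p))
    return results


def cox_univariate(table: pd.DataFrame, term: str) -> list[CoxResult]:
    """Crude (single-term) Cox proportional-hazards fit.

    ``table`` needs columns ``time_months``, ``event`` and the categorical
    ``term`` (risk_group, stage, grade or debulk). The reference level
    contributes a fixed HR of 1.
    """
    levels_with_events = table.loc[table["event"] == 1, term].nunique()
    if table[term].nunique() < 2 or levels_with_events < 1:
        raise InsufficientDataError(f"term {term!r} has fewer than 2 usable levels")
    return _fit_cox(table, [term])


def cox_multivariate(
    table: pd.DataFrame,
    terms: Sequence[str] = ("risk_group", "stage", "grade", "debulk"),
) -> list[CoxResult]:
    """Joint Cox fit adjusting simultaneously for risk group, stage, grade
    and debulking status; adjusted HRs per non-reference level."""
    for term in terms:
        if term not in table.columns:
            raise ValidationError(f"covariate {term!r} missing from table")
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            if (table.groupby(a, observed=True)[b].nunique() <= 1).all() and (
                table[a].nunique() > 1
            ):
                warnings.warn(
                    f"covariates {a!r} and {b!r} are perfectly nested; "
                    "adjusted estimates may be unstable",
                    stacklevel=2,
                )
    return _fit_cox(table, list(terms))


def derive_signature_from_rrs(
    rrs_pairs: Sequence[tuple[RrsResult, RrsResult]],
    cohort: SurvivalCohort,
    mode: str = "strict",
) -> SignatureSpec:
    """Bridge RRS selection to a dichotomised signature.

    For every concordantly selected gene the risk direction follows the
    RRS sign (positive totals mean low values at risk) and the per-gene
    cutoff is the grid threshold whose overall-endpoint log-rank p is
    smallest in ``cohort`` (ties break toward the lower cutoff).
    """
    from .rrs import select_concordant

    entries: list[SignatureEntry] = []
    for ra, rb in rrs_pairs:
        verdict = select_concordant(ra, rb, mode=mode)
        if verdict == "not_selected":
            continue
        direction = (
            "low_value_at_risk"
            if verdict == "selected_hypo_risk"
            else "high_value_at_risk"
        )
        vals = cohort.values[ra.gene].dropna()
        times = cohort.table.loc[vals.index, "time_months"].to_numpy(float)
        events = cohort.table.loc[vals.index, "event"].to_numpy(int)
        grid = quantile_cutoffs(vals.to_numpy(float), gene=ra.gene)
        best_cut, best_p = grid.thresholds[0], math.inf
        for thr in grid.thresholds:
            low = dichotomize(vals.to_numpy(float), thr)
            if low.all() or (~low).all():
                continue
            out = logrank_test(times[low], events[low], times[~low], events[~low])
            if out.p < best_p:
                best_p, best_cut = out.p, thr
        entries.append(SignatureEntry(ra.gene, direction, float(best_cut)))
    if not entries:
        raise ValidationError("no genes selected; cannot derive a signature")
    return SignatureSpec(tuple(entries))


def evaluate_signature(
    cohort: SurvivalCohort, spec: SignatureSpec, horizon_months: float = 60.0
) -> dict:
    """Full survival evaluation of a signature on one cohort.

    Returns risk assignments, per-group KM curves and survival at the
    horizon, the k-group log-rank test, and crude plus adjusted Cox
    tables (when the clinical covariates are present).
    """
    groups_df = assign_risk_groups(cohort, spec)
    table = cohort.table.loc[groups_df.index].copy()
    table["risk_group"] = groups_df["group"]

    km: dict[str, KmCurve] = {}
    surv_h: dict[str, float] = {}
    samples: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for grp in RISK_GROUP_ORDER:
        sub = table[table["risk_group"] == grp]
        if len(sub) == 0:
            continue
        t = sub["time_months"].to_numpy(float)
        e = sub["event"].to_numpy(int)
        samples[grp] = (t, e)
        km[grp] = km_estimate(t, e)
        surv_h[grp] = survival_at(km[grp], horizon_months)

    logrank = multi_group_logrank(samples) if len(samples) >= 2 else None
    out: dict = {
        "risk_groups": groups_df,
        "km": km,
        "survival_at_horizon": surv_h,
        "logrank": logrank,
        "cox_crude": None,
        "cox_adjusted": None,
    }
    try:
        out["cox_crude"] = cox_univariate(table, "risk_group")
    except (InsufficientDataError, ValidationError):
        pass
    if {"stage", "grade", "debulk"} <= set(table.columns):
        try:
            out["cox_adjusted"] = cox_multivariate(table)
        except (InsufficientDataError, ValidationError):
            pass
    return out
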