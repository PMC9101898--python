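import numpy as np
import pandas as pd
import pytest

from methsig import SimConfig, StageOmics, SurvivalCohort
from methsig.datatypes import STAGES


def make_stage_omics(meth_rows: dict, expr_rows: dict | None = None) -> StageOmics:
    """Build a StageOmics from per-gene stage dictionaries (test helper)."""
    genes = list(meth_rows)
    meth = pd.DataFrame(
        [[meth_rows[g][s] for s in STAGES] for g in genes],
        index=genes,
        columns=list(STAGES),
    )
    if expr_rows is None:
        expr = pd.DataFrame(100.0, index=genes, columns=list(STAGES))
    else:
        expr = pd.DataFrame(
            [[expr_rows[g][s] for s in STAGES] for g in genes],
            index=genes,
            columns=list(STAGES),
        )
    return StageOmics(methylation=meth, expression=expr)


def flat(value: float) -> dict:
    return {s: value for s in STAGES}


def make_cohort(times, events, values: dict[str, list] | None = None,
                cohort_id: str = "T") -> SurvivalCohort:
    n = len(times)
    idx = pd.Index([f"p{i}" for i in range(n)], name="patient_id")
    rng = np.random.default_rng(0)
    table = pd.DataFrame(
        {
            "time_months": times,
            "event": events,
            "stage": np.where(rng.random(n) < 0.5, "early", "late"),
            "grade": "G2",
            "debulk": "optimal",
        },
        index=idx,
    )
    vals = pd.DataFrame(values if values else {"gX": rng.uniform(0.2, 0.8, n)},
                        index=idx)
    return SurvivalCohort(cohort_id, table, vals)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=11,
        n_genes=100,
        planted_per_phase={"A": (2, 1), "B": (0, 0), "C": (0, 0)},
        n_patients_per_cohort=120,
    )


@pytest.fixture(scope="session")
def default_cohorts():
    from methsig import simulate_survival_cohorts

    cfg = SimConfig(seed=5, n_genes=50,
                    planted_per_phase={"A": (1, 0), "B": (0, 0), "C": (0, 0)},
                    n_patients_per_cohort=300, cohort_null_genes=3)
    return simulate_survival_cohorts(cfg)
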