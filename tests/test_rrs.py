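"""Quantile grid, directional log-rank, vote scoring and concordance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines.statistics import logrank_test as ll_logrank

from methsig import (
    ENDPOINTS,
    compute_rrs,
    dichotomize,
    logrank_test,
    quantile_cutoffs,
    restrict_endpoint,
    select_concordant,
)
from methsig.datatypes import (
    ConditionVote,
    EndpointSpec,
    InsufficientDataError,
    RrsResult,
    ValidationError,
)
from methsig.rrs import score_condition

from conftest import make_cohort


def quantile_oracle(values, p):
    """Independent linear-interpolation quantile from sorted order statistics."""
    x = sorted(values)
    h = (len(x) - 1) * p
    lo = math.floor(h)
    if lo == len(x) - 1:
        return x[-1]
    return x[lo] + (h - lo) * (x[lo + 1] - x[lo])


def logrank_oracle(times_low, events_low, times_high, events_high):
    """Brute-force log-rank: one 2x2 table per distinct event time."""
    pool = [(t, e, 0) for t, e in zip(times_low, events_low)]
    pool += [(t, e, 1) for t, e in zip(times_high, events_high)]
    event_times = sorted({t for t, e, _ in pool if e == 1})
    o = ex = v = 0.0
    for et in event_times:
        at_risk = [(t, e, g) for t, e, g in pool if t >= et]
        n = len(at_risk)
        n1 = sum(1 for _, _, g in at_risk if g == 0)
        d = sum(1 for t, e, _ in pool if t == et and e == 1)
        d1 = sum(1 for t, e, g in pool if t == et and e == 1 and g == 0)
        o += d1
        ex += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v == 0:
        return 0.0, o - ex
    return (o - ex) ** 2 / v, o - ex


class TestQuantileCutoffs:
    def test_median_of_symmetric_integer_grid(self):
        grid = quantile_cutoffs(list(range(1, 102)))
        assert grid.thresholds[2] == pytest.approx(51.0)
        assert len(grid.thresholds) == 5
        assert grid.probs == pytest.approx((0.25, 1 / 3, 0.5, 2 / 3, 0.75))

    def test_matches_order_statistics_oracle(self):
        rng = np.random.default_rng(42)
        values = rng.uniform(0, 1, 20)
        grid = quantile_cutoffs(values)
        for thr, p in zip(grid.thresholds, grid.probs):
            assert thr == pytest.approx(quantile_oracle(values, p))

    def test_constant_vector_flagged_degenerate(self):
        grid = quantile_cutoffs([3.0] * 12)
        assert grid.degenerate
        assert len(set(grid.thresholds)) == 1

    def test_too_few_values_rejected(self):
        with pytest.raises(InsufficientDataError):
            quantile_cutoffs([1.0] * 9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            quantile_cutoffs([1.0] * 11 + [math.nan])

    def test_thresholds_non_decreasing(self):
        rng = np.random.default_rng(7)
        grid = quantile_cutoffs(rng.normal(size=50))
        assert list(grid.thresholds) == sorted(grid.thresholds)


class TestDichotomize:
    def test_tie_goes_to_low_arm(self):
        low = dichotomize([1.0, 2.0, 3.0], 2.0)
        assert low.tolist() == [True, True, False]

    def test_partition_sizes_sum_to_n(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=37)
        low = dichotomize(v, float(np.median(v)))
        assert low.sum() + (~low).sum() == 37

    def test_degenerate_split_votes_zero(self):
        t = np.arange(1.0, 13.0)
        e = np.ones(12, int)
        vote = score_condition(t, e, np.ones(12, bool))
        assert vote.vote == 0 and vote.inferior_group == "none"


class TestRestrictEndpoint:
    def test_event_beyond_horizon_becomes_censored(self):
        c = make_cohort([40.0, 10.0], [1, 1])
        r = restrict_endpoint(c, EndpointSpec("36m", 36.0))
        assert r.table["time_months"].tolist() == [36.0, 10.0]
        assert r.table["event"].tolist() == [0, 1]

    def test_overall_is_identity(self):
        c = make_cohort([40.0, 10.0], [1, 0])
        r = restrict_endpoint(c, EndpointSpec("overall", math.inf))
        assert r.table.equals(c.table)

    def test_exactly_three_endpoints(self):
        assert [e.endpoint_id for e in ENDPOINTS] == ["18m", "36m", "overall"]
        assert [e.horizon_months for e in ENDPOINTS] == [18.0, 36.0, math.inf]


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2.0, 5.0])
        e = np.array([1, 0, 1])
        out = logrank_test(t, e, t, e)
        assert out.statistic == pytest.approx(0.0)
        assert out.p == pytest.approx(1.0)
        assert out.inferior_group == "none"

    def test_hand_computed_toy_tables(self):
        # low events at {1,2}, high at {5,6}: O_low=2, E_low=1/2+1/3,
        # V=1/4+2/9 -> statistic 49/17
        out = logrank_test([1.0, 2.0], [1, 1], [5.0, 6.0], [1, 1])
        assert out.observed_minus_expected_low == pytest.approx(7 / 6)
        assert out.statistic == pytest.approx(49 / 17)
        assert out.inferior_group == "low"

    def test_all_censored_is_degenerate(self):
        out = logrank_test([5.0, 6.0], [0, 0], [1.0, 2.0], [0, 0])
        assert (out.statistic, out.p, out.inferior_group) == (0.0, 1.0, "none")

    def test_early_event_group_is_inferior(self):
        out = logrank_test([1.0, 2.0, 3.0], [1, 1, 1], [50.0, 60.0, 70.0], [0, 0, 0])
        assert out.inferior_group == "low"
        assert out.p < 0.05

    def test_empty_pooled_input_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([], [], [], [])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_bruteforce_and_lifelines(self, seed):
        """On every small fixture (n <= 20, with ties) the statistic equals a
        per-event-time 2x2 oracle and lifelines' log-rank."""
        rng = np.random.default_rng(seed)
        n1 = rng.integers(1, 11)
        n2 = rng.integers(1, 11)
        tl = rng.integers(1, 8, n1).astype(float)  # integer times force ties
        th = rng.integers(1, 8, n2).astype(float)
        el = rng.integers(0, 2, n1)
        eh = rng.integers(0, 2, n2)
        out = logrank_test(tl, el, th, eh)
        stat_oracle, diff_oracle = logrank_oracle(tl, el, th, eh)
        assert out.statistic == pytest.approx(stat_oracle, abs=1e-10)
        assert out.observed_minus_expected_low == pytest.approx(diff_oracle, abs=1e-10)
        if el.sum() + eh.sum() > 0 and out.statistic > 0:
            ll = ll_logrank(tl, th, event_observed_A=el, event_observed_B=eh)
            assert out.statistic == pytest.approx(ll.test_statistic, rel=1e-8)
            assert out.p == pytest.approx(ll.p_value, rel=1e-8)


class TestScoreCondition:
    def _arms(self, inferior_low: bool):
        early = (np.arange(1.0, 21.0), np.ones(20, int))
        late = (np.arange(80.0, 100.0), np.zeros(20, int))
        if inferior_low:
            t = np.concatenate([early[0], late[0]])
            e = np.concatenate([early[1], late[1]])
        else:
            t = np.concatenate([late[0], early[0]])
            e = np.concatenate([late[1], early[1]])
        low = np.arange(40) < 20
        return t, e, low

    def test_low_arm_inferior_scores_plus_one(self):
        vote = score_condition(*self._arms(True))
        assert vote.vote == 1 and vote.inferior_group == "low"

    def test_high_arm_inferior_scores_minus_one(self):
        vote = score_condition(*self._arms(False))
        assert vote.vote == -1 and vote.inferior_group == "high"

    def test_non_significant_scores_zero(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(20, 40)
        e = np.ones(40, int)
        vote = score_condition(t, e, np.arange(40) % 2 == 0, alpha=1e-12)
        assert vote.vote == 0


class TestComputeRrs:
    def test_grid_has_fifteen_votes_in_fixed_order(self, default_cohorts):
        a, _, _ = default_cohorts
        res = compute_rrs(a, "GNPDA1")
        assert len(res.votes) == 15
        assert [(v.cutoff_id, v.endpoint_id) for v in res.votes] == [
            (c, e)
            for c in ("q25", "q33", "q50", "q67", "q75")
            for e in ("18m", "36m", "overall")
        ]
        assert -15 <= res.total <= 15
        assert res.total == sum(v.vote for v in res.votes)

    def test_strong_risk_gene_saturates_votes(self, default_cohorts):
        a, _, _ = default_cohorts
        res = compute_rrs(a, "GNPDA1")  # planted HR 2.5, n = 300
        assert res.total >= 2

    def test_antisymmetry_under_value_negation(self, default_cohorts):
        """Reversing the value order (v -> -v) swaps the arms of every
        condition, negating each vote and the total (tie-free data)."""
        a, _, _ = default_cohorts
        res = compute_rrs(a, "GNPDA1")
        flipped = a.copy()
        flipped.values["GNPDA1"] = -flipped.values["GNPDA1"]
        res_neg = compute_rrs(flipped, "GNPDA1")
        assert res_neg.total == -res.total
        # cutoff q_p of -v is -q_(1-p) of v: the grid mirrors across cutoffs
        for i in range(5):
            for j in range(3):
                v = res.votes[3 * i + j]
                vn = res_neg.votes[3 * (4 - i) + j]
                assert vn.endpoint_id == v.endpoint_id
                assert vn.vote == -v.vote

    def test_insufficient_patients_rejected(self):
        c = make_cohort([5.0] * 8, [1] * 8, {"g": list(range(8))})
        with pytest.raises(InsufficientDataError):
            compute_rrs(c, "g")

    def test_unknown_gene_rejected(self, default_cohorts):
        a, _, _ = default_cohorts
        with pytest.raises(KeyError):
            compute_rrs(a, "NOPE")


def _rrs_stub(gene, total):
    votes = []
    remaining = total
    for i in range(15):
        v = 1 if remaining > 0 else (-1 if remaining < 0 else 0)
        votes.append(ConditionVote(gene, f"q{i}", "overall", 0.01 if v else 0.5,
                                   "low" if v > 0 else "high" if v < 0 else "none", v))
        remaining -= v
    return RrsResult(gene, "X", tuple(votes), total)


class TestSelectConcordant:
    @pytest.mark.parametrize(
        "ta, tb, expected",
        [
            (5, 3, "selected_hypo_risk"),
            (5, -3, "not_selected"),
            (1, 1, "not_selected"),  # strict reading: totals must exceed +1
            (2, 2, "selected_hypo_risk"),
            (-3, -2, "selected_hyper_risk"),
            (-1, -1, "not_selected"),
            (0, 0, "not_selected"),
        ],
    )
    def test_strict_rule(self, ta, tb, expected):
        assert select_concordant(_rrs_stub("g", ta), _rrs_stub("g", tb)) == expected

    def test_sign_rule_is_looser(self):
        assert (
            select_concordant(_rrs_stub("g", 1), _rrs_stub("g", 1), mode="sign")
            == "selected_hypo_risk"
        )

    def test_gene_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            select_concordant(_rrs_stub("g1", 2), _rrs_stub("g2", 2))
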