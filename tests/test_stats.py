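"""Statistical layer: increase maps, Mann-Whitney, FDR, behavior, regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plvnet.simulate import BehavioralRecord
from plvnet.stats import (
    behavioral_summary,
    chi_square_proportions,
    efficiency_rt_regression,
    fdr_adjust,
    mann_whitney_compare,
    pointwise_increase_map,
)


class TestPointwiseIncreaseMap:
    def test_consistent_increase_is_strongly_significant(self, rng):
        vals = 0.3 + rng.normal(scale=0.01, size=(20, 21, 10))
        m = pointwise_increase_map(vals, np.arange(10.0))
        assert np.all(m.values > 3.0)

    def test_symmetric_null_median_near_half(self, rng):
        """Under a symmetric null the one-sided p is uniform; median ~ 0.5."""
        vals = rng.normal(size=(20, 21, 200))
        m = pointwise_increase_map(vals, np.arange(200.0))
        assert np.median(10.0 ** (-m.values)) == pytest.approx(0.5, abs=0.05)
        assert np.median(m.values) == pytest.approx(-np.log10(0.5), abs=0.07)

    def test_degenerate_zero_variance_maps_to_zero(self):
        vals = np.zeros((5, 3, 4))
        m = pointwise_increase_map(vals, np.arange(4.0))
        assert np.all(m.values == 0.0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            pointwise_increase_map(np.zeros((2, 3, 4)), np.arange(4.0))


def _exact_two_sided_p(a, b):
    """Enumerate all rank arrangements of the pooled sample (no ties)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        sel = np.zeros(len(pooled), bool)
        sel[list(comb)] = True
        aa, bb = pooled[sel], pooled[~sel]
        us.append(sum(1 for x in aa for y in bb if x > y))
    us = np.array(us)
    p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return min(1.0, p)


class TestMannWhitney:
    def test_complete_separation_small_sample(self):
        res = mann_whitney_compare([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.p == pytest.approx(0.1)

    def test_identical_groups(self):
        vals = np.arange(1.0, 7.0)
        res = mann_whitney_compare(vals, vals)
        assert res.u == pytest.approx(len(vals) ** 2 / 2)
        assert res.z == 0.0
        assert res.p == pytest.approx(1.0)

    def test_effect_size_matches_z_over_sqrt_n(self, rng):
        a = rng.normal(size=20)
        b = rng.normal(loc=1.0, size=20)
        res = mann_whitney_compare(a, b)
        assert res.r == pytest.approx(abs(res.z) / np.sqrt(40))
        # the reported Z/r pairing: |Z| = 2.76 with n=20+20 implies r ~ 0.44
        assert 2.76 / np.sqrt(40) == pytest.approx(0.44, abs=0.005)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 5), st.integers(2, 5))
    def test_exact_enumeration_equivalence(self, seed, n1, n2):
        """p matches exhaustive enumeration for tie-free samples of size <= 5."""
        rng = np.random.default_rng(seed)
        pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
        a, b = pooled[:n1], pooled[n1:]
        res = mann_whitney_compare(a, b)
        assert res.p == pytest.approx(_exact_two_sided_p(a, b), abs=1e-12)

    def test_medians_and_iqrs_reported(self):
        res = mann_whitney_compare([1.0, 2.0, 3.0, 10.0], [5.0, 6.0, 7.0, 8.0])
        assert res.median["TS"] == pytest.approx(2.5)
        assert res.n == {"TS": 4, "CO": 4}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_compare([], [1.0])


class TestFdr:
    def test_hand_computed_step_up(self):
        adj = fdr_adjust([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.037])[0] == pytest.approx(0.037)

    def test_all_equal_stay_equal(self):
        adj = fdr_adjust([0.02, 0.02, 0.02, 0.02])
        assert np.allclose(adj, 0.02)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=25))
    def test_adjustment_never_decreases_p(self, ps):
        adj = fdr_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=25))
    def test_rejects_superset_of_bonferroni(self, ps):
        ps = np.asarray(ps)
        q = 0.05
        bh = fdr_adjust(ps) <= q
        bonf = ps <= q / len(ps)
        assert np.all(bh[bonf])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.0, 0.5])


def _record(rts, sides=None, anticipatory=None, correct=None):
    n = len(rts)
    return BehavioralRecord(
        subject_id="s",
        group="CO",
        trials=pd.DataFrame(
            {
                "trial": np.arange(n),
                "side": sides or ["left"] * n,
                "rt_ms": rts,
                "anticipatory": anticipatory or [False] * n,
                "correct": correct if correct is not None else [True] * n,
            }
        ),
    )


class TestBehavioralSummary:
    def test_rt_filter_excludes_boundary_violations(self):
        rec = _record([100.0, 1600.0, 300.0, 150.0, 1500.0])
        summ = behavioral_summary(rec)
        assert summ.n_valid_rt == 1
        assert summ.median_rt["left"] == pytest.approx(300.0)

    def test_accuracy_and_anticipatory_counts(self):
        rec = _record(
            [300.0, 400.0, np.nan, 500.0],
            anticipatory=[False, False, True, False],
            correct=[True, True, False, False],
        )
        summ = behavioral_summary(rec)
        assert summ.accuracy_pct == pytest.approx(50.0)
        assert summ.anticipatory_count == 1

    def test_per_side_statistics(self):
        rec = _record(
            [300.0, 500.0, 320.0, 520.0],
            sides=["left", "right", "left", "right"],
        )
        summ = behavioral_summary(rec)
        assert summ.median_rt["left"] == pytest.approx(310.0)
        assert summ.median_rt["right"] == pytest.approx(510.0)

    def test_no_valid_trials_flagged(self):
        summ = behavioral_summary(_record([np.nan, 50.0]))
        assert not summ.valid


class TestRegression:
    def test_exact_linear_relation(self):
        x = np.linspace(0.2, 0.9, 10)
        res = efficiency_rt_regression(x, 500.0 - 300.0 * x)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(-300.0)
        assert res.df == (1, 8)

    def test_null_r_squared_expectation(self):
        """With independent noise, E[R^2] ~ 1/(n-1)."""
        rng = np.random.default_rng(9)
        n, reps = 20, 300
        r2 = [
            efficiency_rt_regression(rng.normal(size=n), rng.normal(size=n)).r_squared
            for _ in range(reps)
        ]
        assert np.mean(r2) == pytest.approx(1 / (n - 1), abs=0.02)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            efficiency_rt_regression(np.ones(10), np.arange(10.0))


class TestChiSquare:
    def test_equal_proportions_give_zero(self):
        chi2, p = chi_square_proportions(16, 20, 16, 20)
        assert chi2 == 0.0
        assert p == 1.0

    def test_unequal_proportions_positive(self):
        chi2, p = chi_square_proportions(18, 20, 8, 20)
        assert chi2 > 0
        assert p < 0.05
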