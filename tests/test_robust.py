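"""Trimmed-means inference battery and Cliff's rank-based method."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from microwear import (
    DegeneracyError,
    StatsConfig,
    ValidationError,
    cliff_delta,
    consensus,
    lincon_pairwise,
    trimmed_mean,
    welch_yuen_omnibus,
    winsorized_variance,
    yuen_two_sample,
)
from microwear.robust import CliffResult, PairwiseResult
from tests.oracles import cliff_delta_oracle, yuen_oracle

CFG = StatsConfig()


class TestTrimmedMean:
    def test_one_to_ten_with_15_percent_trim(self):
        assert trimmed_mean(range(1, 11), 0.15) == 5.5

    def test_constant_sample(self):
        assert np.isclose(trimmed_mean([3.3] * 7, 0.3), 3.3, rtol=1e-15)

    def test_gamma_zero_is_arithmetic_mean(self, rng):
        x = rng.standard_normal(13)
        assert np.isclose(trimmed_mean(x, 0.0), x.mean(), rtol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=30),
        st.floats(0.0, 0.3),
    )
    def test_matches_scipy_trim_mean(self, xs, gamma):
        if len(xs) - 2 * int(np.floor(gamma * len(xs))) < 1:
            return
        assert np.isclose(
            trimmed_mean(xs, gamma), stats.trim_mean(xs, gamma), rtol=1e-12, atol=1e-9
        )

    def test_overtrimming_degenerate(self):
        with pytest.raises(DegeneracyError):
            trimmed_mean([1.0, 2.0], 0.5)


class TestWinsorizedVariance:
    def test_gamma_zero_is_sample_variance(self, rng):
        x = rng.standard_normal(9)
        assert np.isclose(winsorized_variance(x, 0.0), x.var(ddof=1), rtol=1e-12)

    def test_constant_sample_is_zero(self):
        assert winsorized_variance([2.0] * 5, 0.2) == 0.0

    def test_outlier_clamped_to_order_statistic(self):
        assert winsorized_variance([0, 0, 0, 0, 100], 0.2) == 0.0


class TestOmnibus:
    def test_four_groups_three_numerator_df(self, rng):
        groups = [rng.standard_normal(n) for n in (19, 12, 3, 3)]
        res = welch_yuen_omnibus(groups, CFG)
        assert res.nu1 == 3
        assert res.Ft >= 0 and 0 <= res.P <= 1

    def test_three_groups_two_numerator_df(self, rng):
        res = welch_yuen_omnibus([rng.standard_normal(8) for _ in range(3)], CFG)
        assert res.nu1 == 2

    def test_reduces_to_welch_t_test(self, rng):
        cfg0 = StatsConfig(gamma=0.0)
        for _ in range(10):
            x = rng.normal(0, 1, rng.integers(5, 30))
            y = rng.normal(0.4, 2, rng.integers(5, 30))
            res = welch_yuen_omnibus([x, y], cfg0)
            t, p = stats.ttest_ind(x, y, equal_var=False)
            assert np.isclose(res.Ft, t**2, rtol=1e-10)
            assert np.isclose(res.P, p, atol=1e-8)

    def test_zero_variance_group_names_culprit(self, rng):
        with pytest.raises(DegeneracyError, match="flatgroup"):
            welch_yuen_omnibus(
                [rng.standard_normal(6), np.ones(6)], CFG, labels=["ok", "flatgroup"]
            )

    def test_shift_equivariance(self, rng):
        groups = [rng.normal(0, s, n) for s, n in ((1, 10), (2, 7), (0.5, 12))]
        a = welch_yuen_omnibus(groups, CFG)
        b = welch_yuen_omnibus([g + 17.3 for g in groups], CFG)
        assert np.isclose(a.Ft, b.Ft, rtol=1e-9)
        assert np.isclose(a.P, b.P, rtol=1e-9)


class TestPairwise:
    def test_identical_samples_no_effect(self, rng):
        x = rng.standard_normal(10)
        t, df, p = yuen_two_sample(x, x.copy(), CFG)
        assert t == 0.0 and p == 1.0

    def test_four_groups_give_six_pairs(self, rng):
        groups = {f"g{i}": rng.standard_normal(8) for i in range(4)}
        assert len(lincon_pairwise(groups, CFG)) == 6

    def test_each_pair_equals_standalone_yuen(self, rng):
        groups = {f"g{i}": rng.normal(i, 1 + i, 8 + 3 * i) for i in range(4)}
        for r in lincon_pairwise(groups, CFG):
            t, df, p = yuen_oracle(groups[r.pair[0]], groups[r.pair[1]], CFG.gamma)
            assert np.isclose(r.t, t, atol=1e-12)
            assert np.isclose(r.df, df, atol=1e-12)
            assert np.isclose(r.P, p, atol=1e-12)

    def test_family_wise_adjustment_is_conservative(self, rng):
        groups = {f"g{i}": rng.normal(0.3 * i, 1, 9) for i in range(4)}
        raw = lincon_pairwise(groups, CFG)
        adj = lincon_pairwise(groups, CFG, adjust=True)
        for a, b in zip(raw, adj):
            assert b.P >= a.P - 1e-15

    def test_monotone_separation(self, rng):
        x = rng.standard_normal(10)
        y0 = rng.standard_normal(12)
        # center the samples on equal trimmed means, then widen the gap
        y0 = y0 - (trimmed_mean(y0, CFG.gamma) - trimmed_mean(x, CFG.gamma))
        ts, deltas = [], []
        for gap in (0.0, 0.5, 1.0, 2.0, 4.0):
            ts.append(yuen_two_sample(x, y0 + gap, CFG)[0])
            deltas.append(cliff_delta(x, y0 + gap, CFG).delta)
        assert all(b >= a - 1e-12 for a, b in zip(ts, ts[1:]))
        # shifting y upward can only push dominance of x downward
        assert all(b <= a + 1e-12 for a, b in zip(deltas, deltas[1:]))


class TestCliffDelta:
    def test_complete_separation(self):
        res = cliff_delta([10, 11, 12], [1, 2, 3], CFG)
        assert res.delta == 1.0
        assert res.ci_high <= 1.0 and res.ci_low > 0 and res.significant

    def test_identical_samples(self):
        res = cliff_delta([1, 2, 3], [1, 2, 3], CFG)
        assert res.delta == 0.0 and not res.significant

    def test_small_sample_enumeration(self):
        res = cliff_delta([1, 2, 3], [2, 3, 4], CFG)
        assert np.isclose(res.delta, -5.0 / 9.0, rtol=1e-15)
        assert res.ci_low <= res.delta <= res.ci_high

    @settings(derandomize=True, max_examples=80)
    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=8),
        st.lists(st.integers(0, 5), min_size=2, max_size=8),
    )
    def test_antisymmetry_and_bounds(self, xs, ys):
        a = cliff_delta(xs, ys, CFG)
        b = cliff_delta(ys, xs, CFG)
        assert a.delta == -b.delta
        assert -1.0 <= a.delta <= 1.0
        assert -1.0 <= a.ci_low <= a.delta <= a.ci_high <= 1.0
        assert np.isclose(a.delta, cliff_delta_oracle(xs, ys), atol=1e-12)

    def test_shift_equivariance(self, rng):
        x, y = rng.standard_normal(9), rng.standard_normal(11)
        assert cliff_delta(x, y, CFG).delta == cliff_delta(x + 5, y + 5, CFG).delta

    def test_sample_too_small(self):
        with pytest.raises(ValidationError):
            cliff_delta([1.0], [1.0, 2.0], CFG)


class TestConsensus:
    def pair(self, P):
        return PairwiseResult(pair=("a", "b"), t=1.0, df=5.0, P=P)

    def test_both_criteria_met(self):
        merged, any_sig = consensus(
            [self.pair(0.003)],
            {("a", "b"): CliffResult(0.6, 0.2, 0.9, True)},
            CFG,
        )
        assert merged[0].consensus and any_sig

    def test_cliff_interval_covering_zero_vetoes(self):
        merged, any_sig = consensus(
            [self.pair(0.003)],
            {("a", "b"): CliffResult(0.4, -0.1, 0.9, False)},
            CFG,
        )
        assert not merged[0].consensus and not any_sig

    def test_non_significant_lincon_vetoes(self):
        merged, any_sig = consensus(
            [self.pair(0.08)],
            {("a", "b"): CliffResult(0.6, 0.2, 0.9, True)},
            CFG,
        )
        assert not merged[0].consensus

    def test_mismatched_pairs_rejected(self):
        with pytest.raises(ValidationError):
            consensus([self.pair(0.01)], {("a", "c"): CliffResult(0, 0, 0, False)}, CFG)
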