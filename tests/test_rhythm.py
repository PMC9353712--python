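import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhythmlayers.core import SamplingDesign, TimeCourseMatrix
from rhythmlayers.rhythm import (
    brute_force_null,
    call_rhythmic,
    default_period_grid,
    exact_null_distribution,
    jtk_scan,
    jtk_statistic,
    jtk_test,
    reference_waveforms,
)


class TestReferenceWaveforms:
    def test_period24_lag0_values_and_tie_structure(self, design, refs):
        ref = next(r for r in refs if r.period == 24.0 and r.lag == 0.0)
        t = design.sample_times
        np.testing.assert_allclose(ref.values, np.round(np.cos(2 * np.pi * t / 24), 9))
        # three tied pairs -> 25 of the 28 sample pairs have distinct values
        assert sum(v * (v - 1) // 2 for v in ref.tie_pattern) == 3
        n_pairs = math.comb(ref.n, 2)
        assert n_pairs - 3 == 25
        assert sum(ref.tie_pattern) == ref.n

    def test_lag_shifted_by_full_period_deduplicated(self, design):
        refs = reference_waveforms(design, period_grid=[24.0], lag_step=1.5)
        lags = [r.lag for r in refs]
        assert len(lags) == len(set(lags))
        assert all(lag < 24.0 for lag in lags)
        # a 24h period with 24h of lags at 1.5h: exactly 16 distinct templates
        assert len(refs) == 16

    def test_single_timepoint_design_rejected(self):
        with pytest.raises(ValueError):
            reference_waveforms(np.array([0.0]))

    def test_empty_or_out_of_range_period_grid_rejected(self, design):
        with pytest.raises(ValueError):
            reference_waveforms(design, period_grid=[])
        with pytest.raises(ValueError):
            reference_waveforms(design, period_grid=[16.0])

    def test_default_grid_keeps_periods_on_the_sampling_grid(self, design):
        assert default_period_grid(design.sample_times) == (21.0, 24.0, 27.0)
        assert default_period_grid([0, 1, 2, 3, 4, 5, 6, 7]) == (
            20.0, 21.0, 22.0, 23.0, 24.0, 25.0, 26.0, 27.0, 28.0,
        )


class TestJtkStatistic:
    def test_concordant_antisymmetric_and_tied_cases(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        assert jtk_statistic([1, 2, 3, 4], ref) == 6
        assert jtk_statistic([4, 3, 2, 1], ref) == -6
        assert jtk_statistic([5, 5, 5, 5], ref) == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jtk_statistic([1, 2, 3], np.array([1.0, 2.0]))


def enumeration_oracle(ref_values, n):
    """Independent exhaustive null of S: all n! orderings, vectorised."""
    ref = np.asarray(ref_values, dtype=float)
    i, j = np.triu_indices(n, k=1)
    rsign = np.sign(ref[j] - ref[i]).astype(np.int64)
    perms = np.array(list(permutations(range(n))), dtype=np.int64)
    dsign = np.sign(perms[:, j] - perms[:, i]).astype(np.int64)
    S = dsign @ rsign
    support, counts = np.unique(S, return_counts=True)
    return support, counts / counts.sum()


class TestExactNull:
    def test_untied_n4_uniform_over_permutations(self):
        dist = exact_null_distribution((1, 1, 1, 1), (1, 1, 1, 1))
        assert dist.sf(6) == pytest.approx(1 / 24)
        assert dist.sf(-6) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "ref_ties,data_ties",
        [((1, 1, 1, 1, 1), (1, 1, 1, 1, 1)), ((1, 2, 2, 2, 1), (1,) * 8),
         ((2, 2, 2), (2, 1, 1, 2)), ((1, 2, 1), (2, 1, 1)), ((3, 2), (1, 2, 2))],
    )
    def test_unit_mass_and_zero_mean(self, ref_ties, data_ties):
        dist = exact_null_distribution(ref_ties, data_ties)
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.dot(dist.support, dist.probs) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "ref_ties,data_ties",
        [((1, 1, 1, 1, 1), (1, 1, 1, 1, 1)), ((1, 2, 2, 2, 1), (1,) * 8),
         ((2, 2, 2), (2, 1, 1, 2)), ((1, 2, 1), (2, 2))],
    )
    def test_symmetric_for_palindromic_tie_patterns(self, ref_ties, data_ties):
        # cosine references always have palindromic tie patterns, for which
        # reversing the value order maps S -> -S within the same pattern
        dist = exact_null_distribution(ref_ties, data_ties)
        np.testing.assert_array_equal(dist.support, -dist.support[::-1])
        np.testing.assert_allclose(dist.probs, dist.probs[::-1], atol=1e-12)

    def test_asymmetric_pattern_still_matches_brute_force(self):
        bf = brute_force_null([1, 1, 1, 2, 2], [1, 2, 2, 3, 3])
        dp = exact_null_distribution((3, 2), (1, 2, 2))
        np.testing.assert_array_equal(bf.support, dp.support)
        np.testing.assert_allclose(bf.probs, dp.probs, atol=1e-12)

    def test_matches_brute_force_with_ties_in_both_vectors(self):
        bf = brute_force_null([1, 1, 2, 2, 3, 3], [5, 5, 6, 7, 8, 8])
        dp = exact_null_distribution((2, 2, 2), (2, 1, 1, 2))
        np.testing.assert_array_equal(bf.support, dp.support)
        np.testing.assert_allclose(bf.probs, dp.probs, atol=1e-12)

    def test_matches_enumeration_for_the_default_tie_patterns(self, refs):
        seen = set()
        for ref in refs:
            if ref.tie_pattern in seen:
                continue
            seen.add(ref.tie_pattern)
            support, probs = enumeration_oracle(ref.values, ref.n)
            dp = exact_null_distribution(ref.tie_pattern, (1,) * ref.n)
            np.testing.assert_array_equal(support, dp.support)
            np.testing.assert_allclose(probs, dp.probs, atol=1e-12)

    def test_inconsistent_patterns_rejected(self):
        with pytest.raises(ValueError):
            exact_null_distribution((1, 1, 1), (1, 1))

    def test_large_n_falls_back_to_flagged_normal(self):
        dist = exact_null_distribution((1,) * 30, (1,) * 30, exact_limit=25)
        assert dist.approx
        assert 0 < dist.sf(100) < dist.sf(0) <= 1


class TestJtkTest:
    def test_constant_series_not_rhythmic(self, design, refs):
        r = jtk_test(np.full(8, 3.0), refs, times=design.sample_times)
        assert r.raw_p == 1.0 and r.adj_p == 1.0 and not r.rhythmic

    def test_noiseless_grid_reference_recovered_with_oracle_raw_p(self, design, refs):
        t = design.sample_times
        y = 10 + 2 * np.cos(2 * np.pi * (t - 6.0) / 24)
        r = jtk_test(y, refs, times=t)
        assert r.best_period == 24.0
        assert r.best_lag == 6.0
        ref = next(x for x in refs if x.period == 24.0 and x.lag == 6.0)
        support, probs = enumeration_oracle(ref.values, 8)
        oracle_p = probs[support == support.max()].sum()
        assert r.raw_p == pytest.approx(oracle_p, abs=1e-12)
        assert r.rhythmic
        assert r.amplitude == pytest.approx(2.0, abs=1e-9)

    def test_rank_preserving_transform_leaves_pvalues_unchanged(self, design, refs):
        rng = np.random.default_rng(0)
        t = design.sample_times
        y = 10 + 2 * np.cos(2 * np.pi * (t - 9.0) / 24) + rng.normal(0, 0.5, 8)
        r1 = jtk_test(y, refs, times=t)
        r2 = jtk_test(y**3, refs, times=t)  # monotone on positive data
        assert r1.raw_p == r2.raw_p and r1.adj_p == r2.adj_p
        assert (r1.best_period, r1.best_lag) == (r2.best_period, r2.best_lag)

    def test_sign_flip_shifts_lag_by_half_period(self, design, refs):
        t = design.sample_times
        y = 10 + 2 * np.cos(2 * np.pi * (t - 3.0) / 24)
        r1 = jtk_test(y, refs, times=t)
        r2 = jtk_test(-y + 30, refs, times=t)
        assert r1.best_lag == 3.0
        assert r2.best_lag == pytest.approx((3.0 + 12.0) % 24)
        assert r1.raw_p == r2.raw_p

    def test_missing_values_drop_pairs_but_keep_test(self, design, refs):
        t = design.sample_times
        y = 10 + 3 * np.cos(2 * np.pi * (t - 6.0) / 24)
        y[2] = np.nan
        r = jtk_test(y, refs, times=t)
        assert np.isfinite(r.raw_p) and r.raw_p < 0.05

    def test_fewer_than_four_points_not_testable(self, design, refs):
        y = np.full(8, np.nan)
        y[:3] = [1.0, 2.0, 3.0]
        r = jtk_test(y, refs, times=design.sample_times)
        assert r.adj_p == 1.0 and not r.rhythmic


class TestAdjustment:
    def test_permutation_adjustment_dominates_raw_p(self, cosine_matrix):
        m, _ = cosine_matrix
        res = jtk_scan(m.subset(m.feature_ids[:100]))
        assert (res.adj_p >= res.raw_p - 1e-12).all()
        # monotone in raw_p
        s = res.sort_values("raw_p")
        assert (np.diff(s.adj_p.to_numpy()) >= -1e-12).all()

    def test_bonferroni_mode_uses_reference_count(self, design, refs, cosine_matrix):
        m, _ = cosine_matrix
        res = jtk_scan(m.subset(m.feature_ids[:50]), adjust="bonferroni")
        np.testing.assert_allclose(
            res.adj_p, np.minimum(1.0, res.raw_p * len(refs)), atol=1e-12
        )

    def test_across_feature_correction_available(self, cosine_matrix):
        m, _ = cosine_matrix
        sub = m.subset(m.feature_ids[:20])
        res = jtk_scan(sub, adjust="bonferroni", adjust_across_features=True)
        base = jtk_scan(sub, adjust="bonferroni")
        np.testing.assert_allclose(
            res.adj_p, np.minimum(1.0, base.adj_p * 20), atol=1e-12
        )

    def test_unknown_adjustment_rejected(self, cosine_matrix):
        m, _ = cosine_matrix
        with pytest.raises(ValueError):
            jtk_scan(m, adjust="fdr")


class TestCallRhythmic:
    def test_strict_threshold_comparison(self):
        assert call_rhythmic(0.04, 0.05) is True
        assert call_rhythmic(0.05, 0.05) is False
        assert call_rhythmic(0.08, 0.1) is True

    def test_threshold_must_be_a_probability(self):
        with pytest.raises(ValueError):
            call_rhythmic(0.04, 0.0)


class TestProperties:
    @settings(max_examples=25, deadline=None)
    @given(
        scale=st.floats(min_value=0.01, max_value=100.0, allow_nan=False),
        shift=st.floats(min_value=-50.0, max_value=50.0, allow_nan=False),
    )
    def test_positive_affine_invariance(self, scale, shift):
        design = SamplingDesign()
        refs = reference_waveforms(design)
        rng = np.random.default_rng(1234)
        y = 10 + 2 * np.cos(2 * np.pi * (design.sample_times - 5.0) / 24) + rng.normal(0, 1, 8)
        r1 = jtk_test(y, refs, times=design.sample_times)
        r2 = jtk_test(scale * y + shift, refs, times=design.sample_times)
        assert r1.raw_p == r2.raw_p
        assert r1.adj_p == r2.adj_p

    def test_single_template_pvalue_conservative_under_null(self, design, refs):
        """Per-template exact p on pure noise rejects at most at the nominal
        rate (discreteness makes it conservative)."""
        rng = np.random.default_rng(99)
        n = 1000
        ref = next(r for r in refs if r.period == 24.0 and r.lag == 0.0)
        dist = exact_null_distribution(ref.tie_pattern, (1,) * ref.n)
        i, j = np.triu_indices(ref.n, k=1)
        rsign = np.sign(ref.values[j] - ref.values[i]).astype(np.int64)
        y = rng.normal(size=(n, ref.n))
        S = (np.sign(y[:, j] - y[:, i]).astype(np.int64) @ rsign)
        for alpha in (0.01, 0.05, 0.1):
            rate = (dist.sf(S) < alpha).mean()
            assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / n)

    def test_detection_power_nondecreasing_in_amplitude(self, design, refs):
        rng = np.random.default_rng(7)
        n, t = 150, design.sample_times
        phases = rng.uniform(0, 24, n)
        noise = rng.normal(0, 1, (n, 8))  # shared noise couples the levels
        rates = []
        for amp in (0.0, 1.0, 2.0, 4.0):
            y = 10 + amp * np.cos(2 * np.pi * (t[None, :] - phases[:, None]) / 24) + noise
            m = TimeCourseMatrix(
                pd.DataFrame(y, columns=design.sample_labels), t
            )
            rates.append(jtk_scan(m, refs=refs).rhythmic.mean())
        assert all(b >= a for a, b in zip(rates, rates[1:]))
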