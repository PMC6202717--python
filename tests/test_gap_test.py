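"""Resampling, per-rank gap distributions, percentiles, detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ddetect import (
    bootstrap_gap_matrix,
    detect_discontinuities,
    gap_percentiles,
    observed_gaps,
    prepare_census,
    resample_null,
    select_null_bandwidth,
)
from ddetect.core_null import NeutralNull
from ddetect.gap_test import GapMatrix


def _manual_null(centers, h_star):
    centers = np.asarray(centers, dtype=float)
    return NeutralNull(centers=centers, h_star=h_star, density=None)


class TestObservedGaps:
    def test_even_spacing(self):
        c = prepare_census([10, 100, 1000])
        np.testing.assert_allclose(observed_gaps(c), [1, 1])

    def test_tie_gives_zero_gap(self):
        c = prepare_census([10.0, 10.0, 10 ** 5])
        np.testing.assert_allclose(observed_gaps(c), [0, 4])

    def test_hand_computed_differences(self):
        masses = [3.5, 5.1, 9.8, 21.0, 48.0, 110.0, 300.0, 750.0, 1900.0, 5200.0]
        c = prepare_census(masses)
        logs = np.log10(np.sort(masses))
        np.testing.assert_allclose(observed_gaps(c), logs[1:] - logs[:-1], atol=1e-14)

    def test_gaps_sum_to_range(self, two_cluster_census):
        assert observed_gaps(two_cluster_census).sum() == pytest.approx(
            two_cluster_census.range
        )


class TestResampleNull:
    def test_zero_noise_limit_is_permutation(self):
        null = _manual_null([1.0, 2.0, 3.0, 4.0], h_star=1e-12)
        x = resample_null(null, 4, seed=1)
        np.testing.assert_allclose(np.sort(x), [1, 2, 3, 4], atol=1e-9)

    def test_zero_noise_gaps_equal_observed(self, unimodal_census):
        null = _manual_null(unimodal_census.logmass, h_star=1e-15)
        x = np.sort(resample_null(null, unimodal_census.n, seed=3))
        np.testing.assert_allclose(
            np.diff(x), observed_gaps(unimodal_census), atol=1e-10
        )

    def test_every_center_used_once(self):
        null = _manual_null(np.arange(10.0), h_star=0.01)
        x = resample_null(null, 10, seed=5)
        # each resampled point is near exactly one distinct center
        nearest = np.round(np.sort(x)).astype(int)
        np.testing.assert_array_equal(nearest, np.arange(10))

    def test_oversized_draw_rejected(self):
        null = _manual_null([1.0, 2.0, 3.0], h_star=0.1)
        with pytest.raises(ValueError, match="without replacement"):
            resample_null(null, 4, mode="centers", seed=0)

    def test_iid_mode_allows_oversampling(self):
        null = _manual_null([1.0, 2.0, 3.0], h_star=0.1)
        assert resample_null(null, 10, mode="iid", seed=0).size == 10

    def test_unknown_mode_rejected(self):
        null = _manual_null([1.0, 2.0, 3.0], h_star=0.1)
        with pytest.raises(ValueError, match="mode"):
            resample_null(null, 3, mode="bogus", seed=0)

    def test_pooled_resamples_match_null_distribution(self, unimodal_null):
        """KS check: pooled resampled points follow the fitted KDE."""
        n = unimodal_null.centers.size
        pooled = np.concatenate(
            [resample_null(unimodal_null, n, seed=99, _b=b) for b in range(50_000 // n)]
        )
        grid = unimodal_null.density.grid
        dens = unimodal_null.density.density
        cdf_grid = np.concatenate([[0.0], np.cumsum(np.diff(grid) * 0.5 * (dens[1:] + dens[:-1]))])
        cdf_grid /= cdf_grid[-1]

        def null_cdf(x):
            return np.interp(x, grid, cdf_grid)

        d = stats.kstest(pooled, null_cdf).statistic
        # 1% critical value of the one-sample KS statistic
        crit = stats.kstwobign.ppf(0.99) / np.sqrt(pooled.size)
        assert d < crit


class TestBootstrapGapMatrix:
    def test_composition_of_resamples(self, unimodal_null):
        n = unimodal_null.centers.size
        m = bootstrap_gap_matrix(unimodal_null, n, B=100, seed=17)
        for b in range(3):
            x = np.sort(resample_null(unimodal_null, n, seed=17, _b=b))
            np.testing.assert_array_equal(m.gaps[b], np.diff(x))

    def test_rows_nonnegative_and_sum_to_range(self, unimodal_null):
        n = unimodal_null.centers.size
        m = bootstrap_gap_matrix(unimodal_null, n, B=100, seed=2)
        assert (m.gaps >= 0).all()
        for b in range(m.B):
            x = np.sort(resample_null(unimodal_null, n, seed=2, _b=b))
            assert m.gaps[b].sum() == pytest.approx(x.max() - x.min())

    def test_prefix_stability_when_B_grows(self, unimodal_null):
        n = unimodal_null.centers.size
        m1 = bootstrap_gap_matrix(unimodal_null, n, B=200, seed=4)
        m2 = bootstrap_gap_matrix(unimodal_null, n, B=400, seed=4)
        np.testing.assert_array_equal(m1.gaps, m2.gaps[:200])

    def test_too_few_resamples_rejected(self, unimodal_null):
        with pytest.raises(ValueError, match="at least 100"):
            bootstrap_gap_matrix(unimodal_null, 30, B=10, seed=0)

    def test_column_means_match_order_statistic_spacings(self):
        """For an iid single-Gaussian null, mean rank gaps should match
        normal order-statistic spacings from an independent simulation."""
        rng = np.random.default_rng(123)
        n, sigma = 20, 0.5
        null = _manual_null(np.full(n, 2.0), h_star=sigma)
        # centers all equal => resample is iid N(2, sigma^2)
        m = bootstrap_gap_matrix(null, n, B=5000, seed=8)
        sims = np.sort(rng.normal(2.0, sigma, size=(20000, n)), axis=1)
        expected = np.diff(sims, axis=1).mean(axis=0)
        got = m.gaps.mean(axis=0)
        se = np.diff(sims, axis=1).std(axis=0) / np.sqrt(5000)
        assert (np.abs(got - expected) < 5 * se + 1e-3).all()


class TestGapPercentiles:
    def test_extremes(self):
        m = GapMatrix(gaps=np.full((100, 2), 0.5), B=100, n=3, mode="centers", seed=0)
        np.testing.assert_allclose(gap_percentiles(np.array([0.0, 1.0]), m), [0.0, 1.0])

    def test_hand_computed_midrank(self):
        col = np.arange(0.1, 1.05, 0.1).reshape(-1, 1)
        m = GapMatrix(gaps=col, B=10, n=2, mode="centers", seed=0)
        assert gap_percentiles(np.array([0.55]), m)[0] == pytest.approx(0.5)

    def test_tie_gets_half_weight(self):
        col = np.array([[0.1], [0.2], [0.2], [0.3]])
        m = GapMatrix(gaps=col, B=4, n=2, mode="centers", seed=0)
        assert gap_percentiles(np.array([0.2]), m)[0] == pytest.approx((1 + 0.5 * 2) / 4)

    def test_dimension_mismatch_rejected(self):
        m = GapMatrix(gaps=np.zeros((100, 3)), B=100, n=4, mode="centers", seed=0)
        with pytest.raises(ValueError, match="columns"):
            gap_percentiles(np.zeros(2), m)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        B = int(rng.integers(1, 21))
        ncol = int(rng.integers(1, 8))
        # discrete values force ties to be exercised
        gaps = rng.integers(0, 5, size=(B, ncol)) / 4.0
        obs = rng.integers(0, 5, size=ncol) / 4.0
        m = GapMatrix(gaps=gaps, B=B, n=ncol + 1, mode="centers", seed=0)
        got = gap_percentiles(obs, m)
        for r in range(ncol):
            below = sum(1 for b in range(B) if gaps[b, r] < obs[r])
            tied = sum(1 for b in range(B) if gaps[b, r] == obs[r])
            assert got[r] == (below + 0.5 * tied) / B


class TestDetectDiscontinuities:
    def test_planted_gap_recovered(self, two_cluster_census):
        hits = 0
        for s in range(20):
            rep = detect_discontinuities(two_cluster_census, B=500, seed=s)
            flagged = rep.flagged
            if ((flagged["gap_log10"] > 1.0).any()):
                hits += 1
        assert hits >= 19  # the big between-cluster gap in >= 95% of runs

    def test_threshold_monotonicity(self, unimodal_census):
        counts = []
        for q in (0.8, 0.9, 0.95, 0.99):
            rep = detect_discontinuities(unimodal_census, threshold=q, B=300, seed=5)
            counts.append(rep.n_discontinuities)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_unreachable_threshold_flags_nothing(self, unimodal_census):
        rep = detect_discontinuities(unimodal_census, threshold=0.999999, B=500, seed=1)
        assert rep.n_discontinuities == 0

    def test_seed_determinism(self, unimodal_census):
        a = detect_discontinuities(unimodal_census, B=300, seed=9)
        b = detect_discontinuities(unimodal_census, B=300, seed=9)
        assert a.meta == b.meta
        assert a.table.equals(b.table)

    def test_invalid_threshold_rejected(self, unimodal_census):
        with pytest.raises(ValueError, match="threshold"):
            detect_discontinuities(unimodal_census, threshold=1.5, B=300, seed=0)

    def test_zero_gap_rank_never_flagged(self):
        c = prepare_census([10.0, 10.0, 100.0, 1000.0, 20.0, 300.0])
        rep = detect_discontinuities(c, B=300, seed=2)
        tied = rep.table[rep.table["gap_log10"] == 0.0]
        assert (tied["percentile"] <= 0.5).all()
        assert (tied["discontinuity"] == 0).all()
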