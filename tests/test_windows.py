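"""Window assignment, sparse-window merging, null bands and region calling."""

import numpy as np
import pandas as pd
import pytest

from bsaqtl.stats import compute_site_stats
from bsaqtl.windows import (
    ConfidenceBand,
    Region,
    assign_windows,
    call_regions,
    delta_null_sd_infinite_depth,
    intersect_methods,
    merge_sparse_windows,
    region_length,
    simulate_null_thresholds,
    window_profile,
    window_starts_containing,
)


class TestAssignWindows:
    def test_membership_example(self):
        starts = window_starts_containing(5_000, window=10_000, step=2_000)
        assert starts.tolist() == [1, 2_001, 4_001]

    def test_tiling_when_step_equals_window(self):
        win = assign_windows([500, 1_500, 2_500], window=1_000, step=1_000, chrom_length=3_000)
        assert win["n_snps"].tolist() == [1, 1, 1]

    def test_default_geometry_puts_each_site_in_100_windows(self):
        starts = window_starts_containing(10_000_000, window=2_000_000, step=20_000)
        assert starts.size == 100

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            assign_windows([100], window=10, step=20)

    def test_every_site_covered(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.integers(1, 100_000, size=200))
        win = assign_windows(pos, window=10_000, step=2_000, chrom_length=100_000)
        covered = np.zeros(pos.size, bool)
        for lo, hi in zip(win["lo"], win["hi"]):
            covered[lo:hi] = True
        assert covered.all()


class TestMergeSparseWindows:
    def make(self, counts):
        # tiling windows of width 100 with the requested site counts
        pos = []
        for i, c in enumerate(counts):
            pos.extend(range(i * 100 + 1, i * 100 + 1 + c))
        win = assign_windows(sorted(pos), window=100, step=100, chrom_length=100 * len(counts))
        assert win["n_snps"].tolist() == list(counts)
        return win

    def test_cascade_into_next_window(self):
        merged = merge_sparse_windows(self.make([12, 4, 9, 20]), 10)
        assert merged["n_snps"].tolist() == [12, 13, 20]

    def test_whole_chromosome_below_minimum(self):
        merged = merge_sparse_windows(self.make([3, 3]), 10)
        assert merged.empty

    def test_identity_when_all_dense(self):
        win = self.make([11, 12, 13])
        merged = merge_sparse_windows(win, 10)
        assert merged["n_snps"].tolist() == [11, 12, 13]

    def test_trailing_sparse_merges_backward_and_conserves_sites(self):
        merged = merge_sparse_windows(self.make([15, 4]), 10)
        assert merged["n_snps"].tolist() == [19]
        assert merged.iloc[0]["end"] == 200


def stats_frame(positions, deltas, depth=50):
    n = len(positions)
    return pd.DataFrame(
        dict(
            chrom="chr1",
            pos=positions,
            delta=deltas,
            ed=np.abs(deltas) * np.sqrt(2),
            g=np.ones(n),
            fisher_p=np.full(n, 0.5),
            depth_t=depth,
            depth_s=depth,
        )
    )


class TestWindowProfile:
    def test_single_site_window_equals_site(self):
        prof = window_profile(stats_frame([50], [0.4]), window=100, step=100, min_snps=1)
        assert prof.iloc[0]["mean_delta"] == pytest.approx(0.4)

    def test_mean_over_members(self):
        prof = window_profile(stats_frame([10, 20, 30], [0.2, 0.4, 0.6]),
                              window=100, step=100, min_snps=1)
        assert prof.iloc[0]["mean_delta"] == pytest.approx(0.4)

    def test_merged_window_averages_union_not_means(self):
        # windows [1,100] (1 site, delta 0.9) and [101,200] (3 sites, delta 0.1)
        prof = window_profile(
            stats_frame([50, 110, 120, 130], [0.9, 0.1, 0.1, 0.1]),
            window=100, step=100, min_snps=2,
        )
        assert len(prof) == 1
        assert prof.iloc[0]["mean_delta"] == pytest.approx((0.9 + 0.3) / 4)


class TestNullThresholds:
    def test_high_depth_matches_normal_theory(self):
        band = simulate_null_thresholds(30, 10_000, n_rep=10_000, statistics=("delta",), seed=5)
        q99 = band.threshold("delta", 0.99, 10_000)
        approx = 2.576 * delta_null_sd_infinite_depth(30)
        assert q99 == pytest.approx(approx, rel=0.10)

    def test_bands_nest_and_shrink_with_depth(self):
        band = simulate_null_thresholds(
            30, 50, n_rep=8_000, depth_classes=[20, 100], seed=6
        )
        for cls in (20, 100):
            for stat in ("delta", "ed", "g", "fisher"):
                assert band.quantiles[cls][stat][0.99] >= band.quantiles[cls][stat][0.95]
        assert band.threshold("delta", 0.99, 20) > band.threshold("delta", 0.99, 100)

    def test_unstable_replicate_count_warns(self):
        with pytest.warns(UserWarning):
            simulate_null_thresholds(10, 20, n_rep=500, statistics=("delta",))


def flat_band(thresholds: dict, depth=50) -> ConfidenceBand:
    q = {depth: {stat: {0.95: t * 0.8, 0.99: t} for stat, t in thresholds.items()}}
    return ConfidenceBand(bulk_size=30, levels=(0.95, 0.99), quantiles=q)


class TestCallRegions:
    band = flat_band({"delta": 0.3, "ed": 0.45, "g": 10.0, "fisher": 2.0})

    def profile(self, deltas):
        n = len(deltas)
        return pd.DataFrame(
            dict(
                chrom="chr1",
                start=1 + 100 * np.arange(n),
                end=100 * np.arange(1, n + 1),
                n_snps=10,
                mean_delta=deltas,
                mean_ed=np.zeros(n),
                mean_g=np.zeros(n),
                mean_neglog_p=np.zeros(n),
                mean_depth=np.full(n, 50.0),
            )
        )

    def test_no_exceedance_gives_no_regions(self):
        assert call_regions(self.profile([0.1, 0.2, 0.1]), self.band) == []

    def test_single_window_region(self):
        regions = call_regions(self.profile([0.1, 0.5, 0.1]), self.band, methods=("delta",))
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.peak) == (101, 200, pytest.approx(0.5))

    def test_sub_threshold_gap_splits_regions(self):
        regions = call_regions(self.profile([0.5, 0.1, 0.5]), self.band, methods=("delta",))
        assert len(regions) == 2
        bridged = call_regions(self.profile([0.5, 0.1, 0.5]), self.band, methods=("delta",), max_gap=1)
        assert len(bridged) == 1

    def test_negative_delta_judged_two_sided(self):
        regions = call_regions(self.profile([-0.6, 0.0, 0.0]), self.band, methods=("delta",))
        assert len(regions) == 1 and regions[0].peak == pytest.approx(-0.6)


class TestIntersectMethods:
    def region(self, method, start, end, chrom="chr6"):
        return Region(method=method, chrom=chrom, start=start, end=end, peak=1.0, peak_pos=start)

    def test_four_method_intersection_matches_reported_interval(self):
        regions = [
            self.region("delta", 28_000_000, 31_248_787),
            self.region("ed", 27_840_000, 31_248_787),
            self.region("g", 27_860_000, 31_248_787),
            self.region("fisher", 28_440_000, 31_040_000),
        ]
        calls = intersect_methods(regions)
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (28_440_000, 31_040_000)
        assert calls[0].length("Mb") == 2.60

    def test_disjoint_regions_give_no_call(self):
        regions = [
            self.region("delta", 1, 100),
            self.region("ed", 200, 300),
            self.region("g", 1, 300),
            self.region("fisher", 1, 300),
        ]
        assert intersect_methods(regions) == []

    def test_missing_method_gives_no_call(self):
        regions = [
            self.region("delta", 1, 100),
            self.region("ed", 1, 100),
            self.region("g", 1, 100),
        ]
        assert intersect_methods(regions) == []

    def test_call_contained_in_every_supporting_region(self):
        regions = [
            self.region("delta", 10, 90),
            self.region("ed", 20, 80),
            self.region("g", 5, 70),
            self.region("fisher", 30, 95),
        ]
        (call,) = intersect_methods(regions)
        for r in regions:
            assert r.start <= call.start and call.end <= r.end


class TestRegionLength:
    @pytest.mark.parametrize(
        "start,end,unit,expected",
        [
            (30_467_391, 30_563_973, "kb", 96.6),
            (28_440_000, 31_040_000, "Mb", 2.60),
            (1_500_000, 4_080_000, "Mb", 2.58),
            (500, 500, "kb", 0.0),
        ],
    )
    def test_printed_lengths(self, start, end, unit, expected):
        assert region_length(start, end, unit) == expected


class TestEndToEndProfile:
    def test_profile_from_real_site_stats(self, tiny_study):
        df = compute_site_stats(tiny_study["variants"][:500])
        prof = window_profile(df, window=200_000, step=50_000, min_snps=5)
        assert (prof["n_snps"] >= 5).all()
        assert prof["mean_depth"].between(20, 90).all()
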