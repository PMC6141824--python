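"""Scan statistics against brute-force oracles and definitional cases."""

import numpy as np
import pandas as pd
import pytest

from coldqtl.bsa import (
    ScanConfig,
    call_regions,
    call_threshold,
    compute_delta,
    compute_snp_index,
    filter_sites,
    scan,
    sliding_windows,
    window_starts,
)

# ---------------------------------------------------------------- oracles


def brute_window_starts(length, window, step):
    if length < window:
        return [1]
    starts = []
    s = 1
    while s + window - 1 <= length:
        starts.append(s)
        s += step
    final = length - window + 1
    if starts[-1] != final:
        starts.append(final)
    return starts


def brute_window_means(pos, delta, starts, window, length):
    out = []
    for s in starts:
        e = min(s + window - 1, length)
        member = [d for p, d in zip(pos, delta) if s <= p <= e]
        out.append((s, e, len(member), sum(member) / len(member) if member else None))
    return out


def brute_threshold(means, top_fraction):
    import math

    k = math.ceil(top_fraction * len(means))
    return sorted(means, reverse=True)[k - 1]


def brute_regions(flagged):
    """Interval union of flagged (start, end) windows, merging overlap/abut."""
    regions = []
    for s, e in sorted(flagged):
        if regions and s <= regions[-1][1] + 1:
            regions[-1][1] = max(regions[-1][1], e)
        else:
            regions.append([s, e])
    return [tuple(r) for r in regions]


def make_records(chrom, pos, delta):
    return pd.DataFrame({"chrom": chrom, "pos": pos, "delta": delta})


# ---------------------------------------------------------------- SNP-index


class TestSnpIndex:
    def test_definitions(self, wide_counts):
        rec = compute_snp_index(wide_counts)
        assert rec.loc[rec.pos == 100, "index_high"].item() == pytest.approx(0.8)
        # all reads from the inferior parent -> index 0
        assert rec.loc[rec.pos == 200, "index_high"].item() == 0.0
        # all reads from the superior parent -> index 1
        assert rec.loc[rec.pos == 300, "index_high"].item() == 1.0

    def test_zero_depth_dropped_and_accounted(self):
        counts = pd.DataFrame({
            "chrom": ["c", "c"], "pos": [1, 2],
            "high_ref": [0, 5], "high_alt": [0, 5],
            "low_ref": [10, 5], "low_alt": [0, 5],
        })
        rec = compute_snp_index(counts)
        assert list(rec.pos) == [2]
        assert rec.attrs["drops"]["zero_depth"] == 1

    def test_long_format_equivalent(self, wide_counts):
        long = pd.concat([
            wide_counts.assign(pool_id="HIGH",
                               high_reads=wide_counts.high_alt,
                               low_reads=wide_counts.high_ref),
            wide_counts.assign(pool_id="LOW",
                               high_reads=wide_counts.low_alt,
                               low_reads=wide_counts.low_ref),
        ])[["chrom", "pos", "pool_id", "high_reads", "low_reads"]]
        a = compute_snp_index(wide_counts)
        b = compute_snp_index(long)
        pd.testing.assert_frame_equal(
            a[["chrom", "pos", "index_high", "index_low"]],
            b[["chrom", "pos", "index_high", "index_low"]],
        )

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"chrom": ["c"], "pos": [1], "high_ref": [-1],
                               "high_alt": [2], "low_ref": [3], "low_alt": [4]})
        with pytest.raises(ValueError):
            compute_snp_index(counts)


class TestFilter:
    def _records(self, ih, il, depth=100):
        n = len(ih)
        return pd.DataFrame({
            "chrom": "c", "pos": np.arange(1, n + 1) * 10,
            "high_ref": [(1 - x) * depth for x in ih],
            "high_alt": [x * depth for x in ih],
            "low_ref": [(1 - x) * depth for x in il],
            "low_alt": [x * depth for x in il],
            "depth_high": depth, "depth_low": depth,
            "index_high": ih, "index_low": il,
        })

    def test_both_pool_rule(self):
        rec = self._records([0.2, 0.9, 0.9], [0.25, 0.5, 0.1])
        out = filter_sites(rec, ScanConfig())
        assert list(out.pos) == [20, 30]
        assert out.attrs["drops"]["index_below_cutoff_both_pools"] == 1
        assert list(out.putative) == [False, True]

    def test_putative_excludable(self):
        rec = self._records([0.9, 0.9], [0.5, 0.1])
        out = filter_sites(rec, ScanConfig(include_putative=False))
        assert list(out.pos) == [10]

    def test_min_depth(self):
        rec = self._records([0.9, 0.9], [0.5, 0.5])
        rec.loc[0, "depth_low"] = 5
        out = filter_sites(rec, ScanConfig(min_depth_per_pool=10))
        assert list(out.pos) == [20]
        assert out.attrs["drops"]["low_depth"] == 1


class TestDelta:
    @pytest.mark.parametrize("ih,il,expected", [(0.9, 0.1, 0.8), (0.5, 0.5, 0.0), (0.0, 1.0, -1.0)])
    def test_values(self, ih, il, expected):
        rec = pd.DataFrame({"index_high": [ih], "index_low": [il]})
        assert compute_delta(rec)["delta"].item() == pytest.approx(expected)

    def test_identical_pools_give_zero(self, wide_counts):
        counts = wide_counts.assign(low_ref=wide_counts.high_ref, low_alt=wide_counts.high_alt)
        rec = compute_delta(compute_snp_index(counts))
        assert np.allclose(rec["delta"], 0.0)

    def test_pool_swap_antisymmetry(self, wide_counts):
        rec = compute_delta(compute_snp_index(wide_counts))
        swapped = wide_counts.rename(columns={
            "high_ref": "low_ref", "high_alt": "low_alt",
            "low_ref": "high_ref", "low_alt": "high_alt",
        })
        rec_sw = compute_delta(compute_snp_index(swapped))
        assert np.allclose(rec["delta"].to_numpy(), -rec_sw["delta"].to_numpy())


# ---------------------------------------------------------------- windows


class TestWindows:
    def test_toy_grid_matches_enumeration(self):
        got = window_starts(1000, 500, 200)
        assert list(got) == brute_window_starts(1000, 500, 200) == [1, 201, 401, 501]

    @pytest.mark.parametrize("seed", range(30))
    def test_random_grids_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(50, 5000))
        window = int(rng.integers(10, 2000))
        step = int(rng.integers(1, window + 1))
        assert list(window_starts(length, window, step)) == brute_window_starts(length, window, step)

    def test_hand_mean(self):
        rec = make_records("c", [10, 20, 30], [0.2, 0.4, 0.9])
        win = sliding_windows(rec, {"c": 100}, ScanConfig(window_size=50, step=50))
        assert win.loc[0, "mean_delta"] == pytest.approx(0.5)

    def test_empty_window_has_no_mean(self):
        rec = make_records("c", [10], [0.5])
        win = sliding_windows(rec, {"c": 200}, ScanConfig(window_size=100, step=100))
        empty = win.loc[win.start == 101]
        assert empty.n_snps.item() == 0 and np.isnan(empty.mean_delta.item())

    def test_short_chromosome_clipped(self):
        rec = make_records("c", [10], [0.5])
        win = sliding_windows(rec, {"c": 60}, ScanConfig(window_size=100, step=10))
        assert len(win) == 1
        assert win.loc[0, ["start", "end"]].tolist() == [1, 60]
        assert bool(win.loc[0, "clipped"])

    def test_window_means_match_bruteforce_random(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            length = int(rng.integers(200, 3000))
            window = int(rng.integers(50, 800))
            step = int(rng.integers(10, window + 1))
            n = int(rng.integers(1, 60))
            pos = np.sort(rng.choice(length, size=min(n, length), replace=False) + 1)
            delta = rng.uniform(-1, 1, size=len(pos))
            rec = make_records("c", pos, delta)
            win = sliding_windows(rec, {"c": length}, ScanConfig(window_size=window, step=step))
            oracle = brute_window_means(pos, delta, brute_window_starts(length, window, step),
                                        window, length)
            assert len(win) == len(oracle)
            for row, (s, e, k, m) in zip(win.itertuples(), oracle):
                assert (row.start, row.end, row.n_snps) == (s, e, k)
                if m is None:
                    assert np.isnan(row.mean_delta)
                else:
                    assert abs(row.mean_delta - m) < 1e-12


class TestThreshold:
    def test_top_one_percent_of_300(self):
        means = np.arange(1, 301) / 300.0
        win = pd.DataFrame({"chrom": "c", "start": 1, "end": 2,
                            "n_snps": 1, "mean_delta": means})
        # top 1% of 300 windows = 3 windows; threshold is the 298th value
        assert call_threshold(win, 0.01) == pytest.approx(298 / 300.0)

    def test_single_window(self):
        win = pd.DataFrame({"chrom": ["c"], "start": [1], "end": [2],
                            "n_snps": [3], "mean_delta": [0.42]})
        assert call_threshold(win, 0.01) == pytest.approx(0.42)

    def test_ties_at_cut_all_included(self):
        means = [0.9, 0.5, 0.5, 0.5, 0.1] + [0.0] * 95
        win = pd.DataFrame({"chrom": "c",
                            "start": np.arange(100) * 10 + 1,
                            "end": np.arange(100) * 10 + 5,
                            "n_snps": 1, "mean_delta": means})
        thr = call_threshold(win, 0.01)  # k = 1 -> threshold 0.9
        assert thr == pytest.approx(0.9)
        thr2 = call_threshold(win, 0.02)  # k = 2 -> threshold 0.5; ties join at >=
        regions = call_regions(win, thr2)
        flagged_means = sorted(m for m in means if m >= thr2)
        assert regions.n_windows.sum() == len(flagged_means) == 4

    def test_empty_windows_rejected(self):
        win = pd.DataFrame({"chrom": ["c"], "start": [1], "end": [2],
                            "n_snps": [0], "mean_delta": [np.nan]})
        with pytest.raises(ValueError):
            call_threshold(win, 0.01)

    def test_matches_order_statistic_oracle_random(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(1, 400))
            means = rng.uniform(-1, 1, size=n)
            frac = float(rng.uniform(0.005, 0.3))
            win = pd.DataFrame({"chrom": "c", "start": 1, "end": 2,
                                "n_snps": 1, "mean_delta": means})
            assert call_threshold(win, frac) == pytest.approx(
                brute_threshold(list(means), frac), abs=1e-15)


class TestRegions:
    @staticmethod
    def _win(chrom, starts, window, means):
        return pd.DataFrame({
            "chrom": chrom, "start": starts,
            "end": np.asarray(starts) + window - 1,
            "n_snps": 1, "mean_delta": means,
        })

    def test_overlapping_windows_merge(self):
        win = self._win("c", [1, 201, 401], 500, [0.9, 0.8, 0.7])
        reg = call_regions(win, 0.5)
        assert len(reg) == 1
        assert reg.loc[0, ["start", "end"]].tolist() == [1, 900]
        assert reg.loc[0, "mean_delta"] == pytest.approx(np.mean([0.9, 0.8, 0.7]))

    def test_two_chromosomes_two_regions(self):
        win = pd.concat([self._win("c1", [1], 100, [0.9]), self._win("c2", [1], 100, [0.8])])
        reg = call_regions(win, 0.5)
        assert len(reg) == 2 and list(reg.chrom) == ["c1", "c2"]  # ranked by mean

    def test_gap_splits_regions(self):
        win = self._win("c", [1, 5001], 500, [0.9, 0.8])
        reg = call_regions(win, 0.5)
        assert len(reg) == 2

    def test_zero_regions_valid(self):
        win = self._win("c", [1], 100, [0.1])
        assert call_regions(win, 0.5).empty

    def test_interval_union_matches_oracle_random(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            n = int(rng.integers(1, 40))
            window = int(rng.integers(5, 100))
            starts = np.sort(rng.choice(2000, size=n, replace=False) + 1)
            win = self._win("c", starts, window, np.ones(n))
            reg = call_regions(win, 0.5)
            oracle = brute_regions([(s, s + window - 1) for s in starts])
            assert [(r.start, r.end) for r in reg.sort_values("start").itertuples()] == oracle


class TestScanPipeline:
    def test_indices_and_deltas_bounded(self, wide_counts):
        res = scan(wide_counts, {"chr1": 1000},
                   ScanConfig(window_size=500, step=100, min_depth_per_pool=0))
        assert res.sites.index_high.between(0, 1).all()
        assert res.sites.index_low.between(0, 1).all()
        assert res.sites.delta.between(-1, 1).all()

    def test_drop_accounting_conserves_sites(self, wide_counts):
        res = scan(wide_counts, {"chr1": 1000},
                   ScanConfig(window_size=500, step=100, min_depth_per_pool=0))
        assert len(wide_counts) == len(res.sites) + sum(res.drops.values())
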