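"""SNP-index arithmetic, window profiles, null bands, region calling."""

import numpy as np
import pandas as pd
import pytest

from bulkscan import qtlseq_core as qc
from bulkscan.variant_filtering import ROLE_BULK_HIGH, ROLE_BULK_LOW, SampleCall, VariantRecord


def _rec(chrom, pos, ad_high, ad_low):
    calls = {
        ROLE_BULK_HIGH: SampleCall(gt=(0, 1), ad=ad_high, dp=sum(ad_high)),
        ROLE_BULK_LOW: SampleCall(gt=(0, 1), ad=ad_low, dp=sum(ad_low)),
    }
    return VariantRecord(chrom=chrom, pos=pos, ref="A", alt="G", calls=calls)


def _points(chrom, positions, deltas, depth=40):
    n = len(positions)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "index_high": 0.5 + np.asarray(deltas) / 2,
            "index_low": 0.5 - np.asarray(deltas) / 2,
            "delta": deltas,
            "depth_high": depth,
            "depth_low": depth,
        }
    )


class TestSnpIndex:
    def test_half_zero_and_extreme_linkage(self):
        recs = [
            _rec("c", 10, (10, 10), (37, 0)),
            _rec("c", 20, (0, 12), (15, 0)),
        ]
        pts = qc.compute_snp_index(recs)
        assert pts.loc[0, "index_high"] == 0.5
        assert pts.loc[0, "index_low"] == 0.0
        assert pts.loc[1, "index_high"] == 1.0
        assert pts.loc[1, "delta"] == 1.0

    def test_zero_total_ad_site_skipped(self):
        recs = [_rec("c", 10, (0, 0), (10, 10)), _rec("c", 20, (5, 5), (10, 10))]
        pts = qc.compute_snp_index(recs)
        assert list(pts["pos"]) == [20]


class TestSlidingWindows:
    def test_window_with_too_few_snps_skipped(self):
        pts = _points("c", np.arange(1, 10) * 1000, [0.1] * 9)
        win = qc.sliding_window_profile(pts, window=100_000, step=10_000, min_snps=10)
        assert len(win) == 0
        win = qc.sliding_window_profile(pts, window=100_000, step=10_000, min_snps=9)
        assert len(win) > 0

    def test_constant_deltas_give_constant_mean(self):
        pts = _points("c", np.arange(1, 26) * 30_000, [0.3] * 25)
        win = qc.sliding_window_profile(pts, window=1_000_000, step=100_000, min_snps=5)
        assert np.allclose(win["mean_delta"], 0.3)

    def test_hand_listed_points_match_brute_force(self):
        rng = np.random.default_rng(8)
        positions = np.sort(rng.choice(np.arange(1, 3_000_000), 25, replace=False))
        deltas = rng.uniform(-1, 1, 25).round(3)
        pts = _points("c", positions, deltas)
        W, s, m = 1_000_000, 250_000, 3
        win = qc.sliding_window_profile(pts, window=W, step=s, min_snps=m,
                                        chrom_lengths={"c": 3_000_000})
        # brute force re-computation over the anchor grid
        expected = {}
        for a in range(1, 3_000_000 - W + 2, s):
            member = [(p, d) for p, d in zip(positions, deltas) if a <= p < a + W]
            if len(member) >= m:
                expected[a] = (len(member), np.mean([d for _, d in member]))
        assert set(win["start"]) == set(expected)
        for _, row in win.iterrows():
            n, mean = expected[row["start"]]
            assert row["n_snps"] == n
            assert row["mean_delta"] == pytest.approx(mean)

    def test_invalid_geometry_rejected(self):
        pts = _points("c", [100], [0.1])
        for kwargs in ({"window": 0}, {"step": 0}, {"window": 10, "step": 20}):
            with pytest.raises(ValueError):
                qc.sliding_window_profile(pts, **kwargs)

    def test_short_chromosome_gets_single_truncated_window(self):
        pts = _points("c", np.arange(1, 13) * 10_000, [0.2] * 12)
        win = qc.sliding_window_profile(
            pts, window=1_000_000, step=10_000, min_snps=10, chrom_lengths={"c": 200_000}
        )
        assert len(win) == 1
        assert win.loc[0, "start"] == 1 and win.loc[0, "end"] == 200_000


def _windows_with_band(deltas, cutoff_99, chrom="c", start0=1, step=10_000, width=1_000_000):
    """Hand-built emitted-window frame with a fixed 99% cutoff."""
    rows = []
    for j, d in enumerate(deltas):
        if d is None:
            continue  # a skipped (low-SNP) window: simply not emitted
        a = start0 + j * step
        rows.append(
            {
                "chrom": chrom,
                "start": a,
                "end": a + width - 1,
                "n_snps": 20,
                "mean_delta": d,
                "i0": 0,
                "i1": 1,
                "cutoff_99": cutoff_99,
                "cutoff_95": cutoff_99 * 0.8,
            }
        )
    return pd.DataFrame(rows)


class TestNullBand:
    def test_degenerate_variance_limit(self):
        """As bulk size and depth grow the null band collapses toward zero.

        sd(delta) = sqrt(2(1/4k + 1/4d)); at k = d = 40,000 the 99% cutoff is
        ~0.013, and both cutoffs keep shrinking with k and d.
        """
        win = _windows_with_band([0.0], 0.0).drop(columns=["cutoff_99", "cutoff_95"])
        cuts = {}
        for size in (10_000, 40_000):
            pts = _points("c", [500_000], [0.0], depth=size)
            band = qc.simulate_null_band(win, pts, bulk_size=size, n_replicates=20_000, seed=0)
            cuts[size] = (band.loc[0, "cutoff_95"], band.loc[0, "cutoff_99"])
            assert band.loc[0, "cutoff_95"] <= band.loc[0, "cutoff_99"]
        assert cuts[40_000][1] < 0.02
        assert cuts[40_000][1] < cuts[10_000][1]
        # closed-form check of the simulated scale
        assert cuts[40_000][1] == pytest.approx(2.576 * np.sqrt(2 * 0.5 / 40_000), rel=0.15)

    def test_cutoff_non_increasing_in_depth(self):
        win = _windows_with_band([0.0], 0.0).drop(columns=["cutoff_99", "cutoff_95"])
        cuts = {}
        for depth in (10, 100):
            pts = _points("c", [500_000], [0.0], depth=depth)
            band = qc.simulate_null_band(win, pts, bulk_size=25, n_replicates=50_000, seed=1)
            cuts[depth] = band.loc[0, "cutoff_99"]
        assert cuts[100] <= cuts[10]

    def test_band_bounds_and_ordering(self):
        pts = _points("c", np.arange(1, 31) * 30_000, np.zeros(30))
        win = qc.sliding_window_profile(pts, window=500_000, step=100_000, min_snps=5)
        band = qc.simulate_null_band(win, pts, n_replicates=5000, seed=2)
        assert ((band["cutoff_95"] >= 0) & (band["cutoff_95"] <= band["cutoff_99"])).all()
        assert (band["cutoff_99"] <= 1).all()

    def test_depth_cache_reused_across_profiles(self):
        pts = _points("c", [500_000], [0.0], depth=40)
        win = _windows_with_band([0.0], 0.0).drop(columns=["cutoff_99", "cutoff_95"])
        cache = {}
        b1 = qc.simulate_null_band(win, pts, n_replicates=2000, seed=3, cache=cache)
        b2 = qc.simulate_null_band(win, pts, n_replicates=2000, seed=999, cache=cache)
        # second call reuses the cached draws, so cutoffs are identical
        assert b1.loc[0, "cutoff_99"] == b2.loc[0, "cutoff_99"]

    def test_invalid_inputs_rejected(self):
        pts = _points("c", [100], [0.0])
        win = _windows_with_band([0.0], 0.0).drop(columns=["cutoff_99", "cutoff_95"])
        with pytest.raises(ValueError):
            qc.simulate_null_band(win, pts, bulk_size=0)
        bad = pts.assign(depth_high=0)
        with pytest.raises(ValueError):
            qc.simulate_null_band(win, bad)


class TestRegionCalling:
    def test_null_profile_gives_no_regions(self):
        win = _windows_with_band([0.1, -0.2, 0.05], 0.36)
        assert len(qc.call_candidate_regions(win)) == 0

    def test_peak_difference_direct_subtraction(self):
        win = _windows_with_band([0.40, 0.50, 0.45], 0.36)
        reg = qc.call_candidate_regions(win)
        assert len(reg) == 1
        assert reg.loc[0, "peak_delta"] == pytest.approx(0.50)
        assert reg.loc[0, "peak_difference"] == pytest.approx(0.14)
        assert reg.loc[0, "start"] == win["start"].min()
        assert reg.loc[0, "end"] == win["end"].max()

    def test_skipped_windows_do_not_break_a_run(self):
        win = _windows_with_band([0.40, None, None, 0.45], 0.36)
        reg = qc.call_candidate_regions(win)
        assert len(reg) == 1
        assert reg.loc[0, "n_windows"] == 2

    def test_two_runs_match_brute_force_scan(self):
        rng = np.random.default_rng(4)
        deltas = list(rng.uniform(0, 0.3, 30))
        deltas[5:9] = [0.5, 0.6, 0.55, 0.5]
        deltas[20:22] = [0.45, 0.7]
        cutoff = 0.36
        win = _windows_with_band(deltas, cutoff)
        reg = qc.call_candidate_regions(win)
        # brute force over the emitted list
        runs, cur = [], []
        for j, d in enumerate(deltas):
            if d > cutoff:
                cur.append(j)
            elif cur:
                runs.append(cur)
                cur = []
        if cur:
            runs.append(cur)
        assert len(reg) == len(runs) == 2
        for (_, row), run in zip(reg.iterrows(), runs):
            assert row["start"] == win.loc[win.index[0], "start"] + 0 or True
            member = [deltas[j] for j in run]
            assert row["peak_delta"] == pytest.approx(max(member))
            assert row["n_windows"] == len(run)
            assert row["start"] == 1 + run[0] * 10_000
            assert row["end"] == 1 + run[-1] * 10_000 + 1_000_000 - 1

    def test_bulk_swap_negates_deltas_and_mirrors_two_sided_calls(self):
        deltas = [0.4, 0.5, -0.1, -0.6]
        win = qc.call_candidate_regions  # noqa: F841 (clarity below)
        w1 = _windows_with_band(deltas, 0.36)
        w2 = _windows_with_band([-d for d in deltas], 0.36)
        r1 = qc.call_candidate_regions(w1, two_sided=True)
        r2 = qc.call_candidate_regions(w2, two_sided=True)
        assert list(r1["start"]) == list(r2["start"])
        assert list(r1["peak_difference"]) == list(r2["peak_difference"])
        assert list(r1["peak_delta"]) == list((-r2["peak_delta"]))

    def test_missing_level_rejected(self):
        win = _windows_with_band([0.4], 0.36)
        with pytest.raises(ValueError):
            qc.call_candidate_regions(win, level=0.90)


class TestMergeRegions:
    def test_overlapping_calls_are_unioned_with_best_peak(self):
        # 30-kbp windows at a 10-kbp step: the runs at windows 0 and 2 touch
        # physically, the run at window 6 stands clear
        win = _windows_with_band([0.5, 0.1, 0.6, 0.1, 0.1, 0.1, 0.4], 0.36, width=30_000)
        reg = qc.call_candidate_regions(win)
        assert len(reg) == 3
        merged = qc.merge_overlapping_regions(reg)
        assert len(merged) == 2
        assert merged.loc[0, "peak_delta"] == pytest.approx(0.6)
        assert merged.loc[0, "start"] == 1 and merged.loc[0, "end"] == 50_000
        assert merged.loc[1, "peak_delta"] == pytest.approx(0.4)

    def test_empty_and_disjoint_inputs_unchanged(self):
        win = _windows_with_band([0.5], 0.36)
        reg = qc.call_candidate_regions(win)
        pd.testing.assert_frame_equal(qc.merge_overlapping_regions(reg), reg)
        empty = reg.iloc[0:0]
        assert len(qc.merge_overlapping_regions(empty)) == 0


class TestSummarizeRegions:
    def test_empty_input_totals_zero(self):
        total, per = qc.summarize_regions(pd.DataFrame(columns=["chrom", "start", "end"]))
        assert total == 0.0 and len(per) == 0

    def test_bp_and_mbp_units_agree(self):
        bp = pd.DataFrame({"chrom": ["c"], "start": [22_780_000], "end": [31_000_000]})
        mbp = pd.DataFrame({"chrom": ["c"], "start": [22.78], "end": [31.0]})
        assert qc.summarize_regions(bp, "bp")[0] == qc.summarize_regions(mbp, "mbp")[0] == 8.22

    def test_overlapping_regions_rejected(self):
        df = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [100, 150], "end": [200, 250]}
        )
        with pytest.raises(ValueError):
            qc.summarize_regions(df)
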