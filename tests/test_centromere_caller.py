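import numpy as np
import pytest

from cenland.centromere_caller import (
    arm_ratio,
    arm_scaled_metaprofile,
    bpm_normalize,
    call_centromeres,
    classify_cluster_binding,
    ratio_track,
)
from cenland.core_io import BinnedTrack, GenomicInterval, PipelineConfig
from cenland.synthetic_data import simulate_enrichment_tracks


def flat_ratio(values, bin_size=500, chrom="chr1"):
    from cenland.centromere_caller import RatioTrack

    return RatioTrack(chrom, bin_size, np.asarray(values, float), "ratio",
                      len(values) * bin_size, 1.0)


class TestBpmNormalize:
    def test_direct_formula(self):
        t = BinnedTrack("chr1", 500, [1.0, 3.0])
        out = bpm_normalize(t)
        np.testing.assert_allclose(out.values, [250_000, 750_000])

    def test_sums_to_one_million(self, rng):
        tracks = {
            f"chr{i}": BinnedTrack(f"chr{i}", 500, rng.poisson(20, 100).astype(float))
            for i in range(3)
        }
        out = bpm_normalize(tracks)
        total = sum(t.values.sum() for t in out.values())
        assert total == pytest.approx(1e6, rel=1e-9)

    def test_scale_invariance(self, rng):
        vals = rng.poisson(30, 50).astype(float) + 1
        a = bpm_normalize(BinnedTrack("c", 500, vals))
        b = bpm_normalize(BinnedTrack("c", 500, vals * 10))
        np.testing.assert_allclose(a.values, b.values)

    def test_all_zero_error(self):
        with pytest.raises(ValueError):
            bpm_normalize(BinnedTrack("c", 500, [0.0, 0.0]))


class TestRatioTrack:
    def test_equal_tracks_give_unit_ratio(self, rng):
        vals = rng.poisson(50, 200).astype(float)
        t = BinnedTrack("c", 500, vals)
        r = ratio_track(t, BinnedTrack("c", 500, vals.copy()))
        np.testing.assert_allclose(r.values, 1.0)

    def test_doubled_counts_near_two(self):
        # high-coverage bins: pseudocount distortion < 1%
        n = 100
        inp = BinnedTrack("c", 500, np.full(n, 100.0))
        cut = BinnedTrack("c", 500, np.full(n, 200.0))
        r = ratio_track(cut, inp)
        # equal library normalization makes both BPM equal -> ratio 1 here;
        # use two chromosomes so library sizes differ as in the contract
        inp2 = {"a": BinnedTrack("a", 500, np.full(n, 100.0)),
                "b": BinnedTrack("b", 500, np.full(n, 100.0))}
        cut2 = {"a": BinnedTrack("a", 500, np.full(n, 200.0)),
                "b": BinnedTrack("b", 500, np.full(n, 100.0))}
        r2 = ratio_track(cut2, inp2)
        bpm_a_cut = 200 / (300 * n) * 1e6
        bpm_a_inp = 100 / (200 * n) * 1e6
        expected = (bpm_a_cut + 1) / (bpm_a_inp + 1)
        np.testing.assert_allclose(r2["a"].values, expected)
        assert abs(expected - bpm_a_cut / bpm_a_inp) / (bpm_a_cut / bpm_a_inp) < 0.01

    def test_zero_bins_ratio_one(self):
        inp = BinnedTrack("c", 500, [0.0, 10.0])
        cut = BinnedTrack("c", 500, [0.0, 10.0])
        r = ratio_track(cut, inp)
        assert r.values[0] == pytest.approx(1.0)

    def test_bin_size_mismatch_error(self):
        with pytest.raises(ValueError, match="bin size"):
            ratio_track(BinnedTrack("c", 500, [1.0]), BinnedTrack("c", 1000, [1.0]))


class TestCallCentromeres:
    def test_flat_track_no_calls(self):
        assert call_centromeres(flat_ratio([1.0] * 2000)) == []

    def test_single_block_recovered_within_one_bin(self):
        vals = np.ones(4000)
        vals[1000:1400] = 5.0  # 200 kb block at ratio 5
        calls = call_centromeres(flat_ratio(vals))
        assert len(calls) == 1
        c = calls[0]
        assert c.is_primary
        assert abs(c.region.start - 500_000) <= 500
        assert abs(c.region.end - 700_000) <= 500
        assert c.mean_ratio > 1

    def test_merge_rule_100kb(self):
        # two 50-kb blocks, 50 kb apart -> one call
        vals = np.ones(4000)
        vals[1000:1100] = 5.0
        vals[1200:1300] = 5.0
        assert len(call_centromeres(flat_ratio(vals))) == 1
        # moved to 150 kb apart -> two calls
        vals = np.ones(4000)
        vals[1000:1100] = 5.0
        vals[1400:1500] = 5.0
        assert len(call_centromeres(flat_ratio(vals))) == 2

    def test_blocks_disjoint_sorted_above_mean(self, rng):
        vals = np.ones(4000)
        for s in (200, 900, 1600, 2500, 3300):
            vals[s : s + 40] = rng.uniform(4, 8)
        calls = call_centromeres(flat_ratio(vals))
        assert calls
        mean = vals.mean()
        regions = [c.region for c in calls]
        assert all(a.end <= b.start for a, b in zip(regions, regions[1:]))
        assert all(c.mean_ratio > mean for c in calls)
        assert sum(c.is_primary for c in calls) == 1

    def test_min_length_filter(self):
        vals = np.ones(4000)
        vals[1000:1010] = 5.0  # 5 kb < min_cen_len 10 kb
        assert call_centromeres(flat_ratio(vals)) == []

    def test_empty_track_error(self):
        with pytest.raises(ValueError):
            call_centromeres({})

    def test_merge_rule_matches_interval_union_oracle(self, rng):
        """Block boundaries equal an independent interval-union computation
        with the same <100 kb gap rule on random candidate sets."""
        config = PipelineConfig(min_cen_len=500)
        for _ in range(30):
            cand = np.sort(rng.choice(2000, size=rng.integers(1, 40), replace=False))
            vals = np.ones(2000)
            vals[cand] = 50.0
            calls = call_centromeres(flat_ratio(vals), config)
            got = [(c.region.start, c.region.end) for c in calls]
            # oracle: union candidate bin intervals, join gaps < 100 kb
            ivs = [(int(b) * 500, int(b) * 500 + 500) for b in cand]
            merged = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s - merged[-1][1] < 100_000:
                    merged[-1][1] = e
                else:
                    merged.append([s, e])
            expected = [tuple(m) for m in merged if m[1] - m[0] >= 500]
            assert got == expected

    def test_planted_centromere_jaccard(self):
        cen = GenomicInterval("chr1", 750_000, 1_250_000)
        hits = 0
        for rep in range(20):
            cut, inp = simulate_enrichment_tracks(2_000_000, cen, 5, 50, 500, rep)
            calls = call_centromeres(ratio_track(cut, inp))
            pri = next(c for c in calls if c.is_primary)
            inter = max(0, min(pri.region.end, cen.end) - max(pri.region.start, cen.start))
            union = max(pri.region.end, cen.end) - min(pri.region.start, cen.start)
            hits += inter / union >= 0.9
        assert hits >= 19


class TestClusterBinding:
    def test_ratio_three_binds(self):
        assert classify_cluster_binding(300, 100, 1_000_000, 1_000_000)

    def test_exactly_two_not_binding(self):
        assert not classify_cluster_binding(200, 100, 1_000_000, 1_000_000)

    def test_unit_ratio_not_binding(self):
        assert not classify_cluster_binding(100, 100, 1_000_000, 1_000_000)

    def test_zero_input_uses_pseudocount(self):
        assert classify_cluster_binding(300, 0, 1_000_000, 1_000_000)


class TestArmRatio:
    def test_central_midpoint(self):
        assert arm_ratio(GenomicInterval("c", 4_900_000, 5_100_000), 10_000_000) == 1.0

    def test_quarter_position(self):
        assert arm_ratio(GenomicInterval("c", 2_400_000, 2_600_000), 10_000_000) == 3.0

    def test_nine_tenths(self):
        assert arm_ratio(GenomicInterval("c", 8_900_000, 9_100_000), 10_000_000) == 9.0

    def test_zero_arm_error(self):
        with pytest.raises(ValueError):
            arm_ratio(GenomicInterval("c", 0, 1), 100)


class TestMetaprofile:
    def test_constant_track(self):
        t = BinnedTrack("c", 500, np.full(2000, 3.0))
        prof = arm_scaled_metaprofile(t, {"c": 500_000}, 50)
        np.testing.assert_allclose(prof, 3.0)

    def test_enriched_centromere_monotone_toward_cen(self):
        vals = np.ones(2000)
        vals[900:1100] = 5.0  # 100 kb around the midpoint
        t = BinnedTrack("c", 500, vals)
        prof = arm_scaled_metaprofile(t, {"c": 500_000}, 20)
        assert prof[-1] > prof[0]
        assert np.all(np.diff(prof) >= -1e-12)

    def test_symmetric_arms_identical(self):
        vals = np.concatenate([np.linspace(1, 5, 1000), np.linspace(5, 1, 1000)])
        t = BinnedTrack("c", 500, vals)
        prof_one = arm_scaled_metaprofile(t, {"c": 500_000}, 25)
        # profile equals each arm's own profile when arms are mirror images
        half = BinnedTrack("h", 500, vals[:1000])
        prof_half = arm_scaled_metaprofile(half, {"h": 500_000}, 25)
        np.testing.assert_allclose(prof_one, prof_half)

    def test_missing_midpoint_skipped_with_warning(self):
        t1 = BinnedTrack("a", 500, np.full(100, 2.0))
        t2 = BinnedTrack("b", 500, np.full(100, 4.0))
        with pytest.warns(UserWarning, match="no centromere midpoint"):
            prof = arm_scaled_metaprofile({"a": t1, "b": t2}, {"a": 25_000}, 10)
        np.testing.assert_allclose(prof, 2.0)
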