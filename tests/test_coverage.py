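"""Coverage binning, normalization, masking, smoothing, log2 and CNV calls.

The binned implementation is checked against an independent per-base
brute-force oracle; smoothing against a brute-force sliding median.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import matepairsv as m
from matepairsv.coverage import CoverageTrack, MASK_REPEAT, MASK_ZERO_NORMAL


def _frag(i, pos1, pos2, contig="c1", read_len=100, sample="tumor"):
    return m.FragmentAlignment(
        fragment_id=f"f{i}", contig1=contig, pos1=pos1, strand1="+",
        contig2=contig, pos2=pos2, strand2="-", read_len=read_len, sample=sample,
    )


def _random_fragments(n, contig_len, rng, read_len=100):
    frags = []
    for i in range(n):
        length = int(rng.integers(2 * read_len, 2_000))
        start = int(rng.integers(0, max(1, contig_len - length)))
        frags.append(_frag(i, start, start + length - read_len, read_len=read_len))
    return frags


def perbase_coverage_oracle(frags, contig_len, bin_width):
    """Brute force: accumulate every fragment span base by base, then
    average per bin (padding the final partial bin with zeros)."""
    base = np.zeros(contig_len)
    for f in frags:
        lo, hi = f.span()
        base[lo:min(hi, contig_len)] += 1
    n_bins = -(-contig_len // bin_width)
    padded = np.zeros(n_bins * bin_width)
    padded[:contig_len] = base
    return padded.reshape(n_bins, bin_width).sum(axis=1) / bin_width


class TestPhysicalCoverage:
    def test_single_fragment_identity(self):
        # one 1 kb fragment tiles ten 100 bp bins at exactly 1.0
        frags = [_frag(0, 0, 900)]
        track = m.physical_coverage(frags, {"c1": 1_000}, bin_width=100)["c1"]
        assert track.n_bins == 10
        np.testing.assert_array_equal(track.values, np.ones(10))

    def test_default_bin_width_is_100(self):
        track = m.physical_coverage([_frag(0, 0, 900)], {"c1": 1_000})["c1"]
        assert track.bin_width == 100

    def test_matches_perbase_oracle_exactly(self):
        rng = np.random.default_rng(42)
        frags = _random_fragments(500, 50_000, rng)
        track = m.physical_coverage(frags, {"c1": 50_000}, bin_width=100)["c1"]
        oracle = perbase_coverage_oracle(frags, 50_000, 100)
        np.testing.assert_allclose(track.values, oracle, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.sampled_from([73, 100, 250]))
    def test_oracle_equivalence_property(self, seed, bin_width):
        rng = np.random.default_rng(seed)
        contig_len = int(rng.integers(5_000, 20_000))
        frags = _random_fragments(60, contig_len, rng)
        track = m.physical_coverage(frags, {"c1": contig_len}, bin_width)["c1"]
        oracle = perbase_coverage_oracle(frags, contig_len, bin_width)
        np.testing.assert_allclose(track.values, oracle, atol=1e-9)

    def test_coverage_conservation(self):
        rng = np.random.default_rng(3)
        frags = _random_fragments(200, 30_000, rng)
        track = m.physical_coverage(frags, {"c1": 30_000}, bin_width=100)["c1"]
        total_span = sum(f.span()[1] - f.span()[0] for f in frags)
        assert track.values.sum() * 100 == pytest.approx(total_span, abs=1e-6)

    def test_fragment_past_contig_end_clipped_with_warning(self, caplog):
        frags = [_frag(0, 500, 1_400)]  # span [500, 1500) on a 1 kb contig
        with caplog.at_level("WARNING"):
            track = m.physical_coverage(frags, {"c1": 1_000}, 100)["c1"]
        assert "clipped" in caplog.text
        assert track.values.sum() * 100 == pytest.approx(500)


class TestNormalize:
    def _tracks(self, tvals, nvals):
        t = {"c1": CoverageTrack("c1", 100, np.array(tvals, float), "tumor")}
        n = {"c1": CoverageTrack("c1", 100, np.array(nvals, float), "normal")}
        return t, n

    def test_identical_tracks_stay_identical(self):
        t, n = self._tracks([2, 4, 6, 8], [2, 4, 6, 8])
        tn, nn = m.normalize(t, n)
        np.testing.assert_array_equal(tn["c1"].values, nn["c1"].values)

    def test_global_scaling_removed(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        t, n = self._tracks([2 * v for v in vals], vals)
        tn, nn = m.normalize(t, n)
        np.testing.assert_allclose(tn["c1"].values, nn["c1"].values)

    def test_post_normalization_median_is_one(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(5, 2, size=501)
        t, n = self._tracks(vals, rng.gamma(5, 2, size=501))
        tn, nn = m.normalize(t, n)
        assert np.median(tn["c1"].values) == pytest.approx(1.0)
        assert np.median(nn["c1"].values) == pytest.approx(1.0)

    def test_known_median_division(self):
        t, n = self._tracks([1, 2, 3], [10, 20, 30])
        tn, nn = m.normalize(t, n)
        np.testing.assert_allclose(tn["c1"].values, [0.5, 1.0, 1.5])
        np.testing.assert_allclose(nn["c1"].values, [0.5, 1.0, 1.5])

    def test_zero_median_is_degenerate(self):
        t, n = self._tracks([0, 0, 0, 1], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="median"):
            m.normalize(t, n)

    def test_geometry_mismatch_rejected(self):
        t = {"c1": CoverageTrack("c1", 100, np.ones(5), "tumor")}
        n = {"c1": CoverageTrack("c1", 100, np.ones(6), "normal")}
        with pytest.raises(ValueError, match="geometry"):
            m.normalize(t, n)


class TestRepeatMask:
    def test_uniform_track_unmasked(self):
        n = {"c1": CoverageTrack("c1", 100, np.ones(100), "normal")}
        mask = m.repeat_mask(n, quantile_hi=0.99)["c1"]
        assert not mask.any()

    def test_extreme_bin_masked(self):
        vals = np.ones(200)
        vals[17] = 50.0
        n = {"c1": CoverageTrack("c1", 100, vals, "normal")}
        mask = m.repeat_mask(n)["c1"]
        assert mask[17] and mask.sum() == 1

    def test_zero_bins_masked_unless_allowed(self):
        vals = np.ones(50)
        vals[3] = 0.0
        n = {"c1": CoverageTrack("c1", 100, vals, "normal")}
        assert m.repeat_mask(n)["c1"][3]
        assert not m.repeat_mask(n, zero_ok=True)["c1"][3]

    def test_planted_repeat_region_recovered(self):
        """A 10x repeat-like region is >= 95% masked across 20 seeds."""
        lo, hi = 20_000, 24_000
        masked = total = 0
        for seed in range(20):
            config = m.SimulationConfig(
                contigs=[("c1", 60_000)],
                haploid_depth=20.0,
                repeat_specs=[m.RepeatSpec("c1", lo, hi, 10.0)],
                seed=seed,
            )
            frags, _ = m.simulate_sample(config, "normal")
            track = m.physical_coverage(frags, {"c1": 60_000})
            mask = m.repeat_mask(track, quantile_hi=0.92)["c1"]
            masked += mask[lo // 100 : hi // 100].sum()
            total += (hi - lo) // 100
        assert masked / total >= 0.95


def sliding_median_oracle(values, window, mask):
    """Brute-force centered moving median over unmasked neighbours."""
    half = window // 2
    out = values.copy()
    for i in range(len(values)):
        if mask[i]:
            continue
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        win = [v for v, mk in zip(values[lo:hi], mask[lo:hi]) if not mk]
        out[i] = np.median(win)
    return out


class TestSmooth:
    def test_window_one_is_identity(self):
        track = CoverageTrack("c1", 100, np.arange(10, dtype=float), "t")
        out = m.smooth(track, 1)
        np.testing.assert_array_equal(out.values, track.values)

    def test_even_window_rejected(self):
        track = CoverageTrack("c1", 100, np.ones(10), "t")
        with pytest.raises(ValueError, match="odd"):
            m.smooth(track, 4)

    def test_spike_removed(self):
        vals = np.ones(21)
        vals[10] = 40.0
        out = m.smooth(CoverageTrack("c1", 100, vals, "t"), 5)
        assert out.values[10] == 1.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.sampled_from([3, 5, 9]))
    def test_matches_sliding_median_oracle(self, seed, window):
        rng = np.random.default_rng(seed)
        vals = rng.gamma(4, 1, size=80)
        mask = rng.random(80) < 0.1
        out = m.smooth(CoverageTrack("c1", 100, vals, "t"), window, mask)
        oracle = sliding_median_oracle(vals, window, mask)
        np.testing.assert_allclose(out.values, oracle)


class TestLog2Ratio:
    def _norm(self, vals, sample="t"):
        return CoverageTrack("c1", 100, np.array(vals, float), sample)

    def test_identical_inputs_give_zero(self):
        t = self._norm([1, 2, 3, 4])
        track = m.log2_ratio(t, self._norm([1, 2, 3, 4]))
        np.testing.assert_array_equal(track.ratio, np.zeros(4))

    def test_doubled_window_gives_one(self):
        t = self._norm([1, 2, 2, 1])
        n = self._norm([1, 1, 1, 1])
        track = m.log2_ratio(t, n)
        np.testing.assert_allclose(track.ratio, [0, 1, 1, 0])

    def test_zero_normal_bins_masked(self):
        track = m.log2_ratio(self._norm([1, 1]), self._norm([1, 0]))
        assert not track.mask[0] and track.mask[1]
        assert track.mask_reason[1] == MASK_ZERO_NORMAL

    def test_repeat_mask_reason_propagated(self):
        track = m.log2_ratio(
            self._norm([1, 1]), self._norm([1, 1]), mask=np.array([True, False])
        )
        assert track.mask_reason[0] == MASK_REPEAT

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            m.log2_ratio(self._norm([1, 1]), self._norm([1, 1, 1]))

    def test_antisymmetry_under_sample_swap(self):
        rng = np.random.default_rng(5)
        a = self._norm(rng.gamma(5, 1, 50))
        b = self._norm(rng.gamma(5, 1, 50))
        fwd = m.log2_ratio(a, b)
        rev = m.log2_ratio(b, a)
        np.testing.assert_allclose(fwd.ratio, -rev.ratio, atol=1e-12)

    def test_scale_invariance_through_normalization(self):
        """Multiplying one sample's raw coverage by c > 0 leaves the
        log2 track unchanged after median normalization."""
        rng = np.random.default_rng(8)
        tvals = rng.gamma(5, 2, 301)
        nvals = rng.gamma(5, 2, 301)
        def pipeline(scale):
            t = {"c1": CoverageTrack("c1", 100, tvals * scale, "t")}
            n = {"c1": CoverageTrack("c1", 100, nvals, "n")}
            tn, nn = m.normalize(t, n)
            return m.log2_ratio(tn["c1"], nn["c1"]).ratio
        np.testing.assert_allclose(pipeline(1.0), pipeline(7.3), atol=1e-12)

    def test_planted_ratio_recovered_within_tolerance(self):
        """Mean log2 over a planted 1.5x segment lands within 0.1 of
        log2(1.5), averaging segment means over 5 seeds at depth 60."""
        lo, hi = 40_000, 60_000
        means = []
        for seed in range(5):
            config = m.SimulationConfig(
                contigs=[("c1", 100_000)],
                haploid_depth=60.0,
                cnv_specs=[m.CnvSpec("c1", lo, hi, 1.5)],
                seed=seed,
            )
            t, _ = m.simulate_sample(config, "tumor")
            n, _ = m.simulate_sample(config, "normal")
            tn, nn = m.normalize(
                m.physical_coverage(t, config.contig_lengths),
                m.physical_coverage(n, config.contig_lengths),
            )
            track = m.log2_ratio(tn["c1"], nn["c1"])
            means.append(np.nanmean(track.ratio[lo // 100 : hi // 100]))
        assert abs(np.mean(means) - np.log2(1.5)) < 0.1


class TestCnvSegments:
    def _track(self, ratio, mask=None):
        ratio = np.array(ratio, float)
        if mask is None:
            mask = np.zeros(ratio.size, bool)
        ratio = ratio.copy()
        ratio[mask] = np.nan
        return m.Log2RatioTrack("c1", 100, ratio, mask)

    def test_flat_track_is_single_neutral_segment(self):
        segs = m.call_cnv_segments(self._track(np.zeros(50)))
        assert len(segs) == 1
        assert segs[0].state == "neutral"
        assert (segs[0].start, segs[0].end) == (0, 5_000)

    def test_short_excursion_below_min_bins_ignored(self):
        ratio = np.zeros(30)
        ratio[10:13] = 1.0  # 3 bins < min_bins=5
        segs = m.call_cnv_segments(self._track(ratio))
        assert all(s.state == "neutral" for s in segs)

    def test_masked_bins_break_runs(self):
        ratio = np.ones(12)
        mask = np.zeros(12, bool)
        mask[6] = True  # splits a 12-bin gain into 6 + 5
        segs = m.call_cnv_segments(self._track(ratio, mask), min_bins=5)
        gains = [s for s in segs if s.state == "gain"]
        assert len(gains) == 2

    def test_segments_tile_contig_sorted_nonoverlapping(self):
        rng = np.random.default_rng(2)
        segs = m.call_cnv_segments(self._track(rng.normal(0, 0.5, 200)))
        assert segs[0].start == 0 and segs[-1].end == 20_000
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start

    def test_planted_gain_recovered(self):
        """A 30-bin 2.0-ratio segment yields a gain call overlapping
        >= 90% of the planted interval at depth 30 (fixed seeds)."""
        lo, hi = 20_000, 23_000
        for seed in range(5):
            config = m.SimulationConfig(
                contigs=[("c1", 50_000)],
                haploid_depth=30.0,
                cnv_specs=[m.CnvSpec("c1", lo, hi, 2.0)],
                seed=seed,
            )
            t, _ = m.simulate_sample(config, "tumor")
            n, _ = m.simulate_sample(config, "normal")
            tn, nn = m.normalize(
                m.physical_coverage(t, config.contig_lengths),
                m.physical_coverage(n, config.contig_lengths),
            )
            mask = m.repeat_mask(nn)["c1"]
            ts = m.smooth(tn["c1"], 5, mask)
            ns = m.smooth(nn["c1"], 5, mask)
            track = m.log2_ratio(ts, ns, mask)
            gains = [s for s in m.call_cnv_segments(track) if s.state == "gain"]
            overlap = max(
                (min(s.end, hi) - max(s.start, lo) for s in gains), default=0
            )
            assert overlap >= 0.9 * (hi - lo), f"seed {seed}"

    def test_loss_is_reciprocal_of_gain_under_swap(self):
        """Swapping tumor and normal turns the planted gain into a loss
        over the same interval (antisymmetry of the log2 track)."""
        ratio = np.zeros(60)
        ratio[20:50] = 1.0
        gains = [s for s in m.call_cnv_segments(self._track(ratio)) if s.state != "neutral"]
        losses = [s for s in m.call_cnv_segments(self._track(-ratio)) if s.state != "neutral"]
        assert [s.state for s in gains] == ["gain"]
        assert [s.state for s in losses] == ["loss"]
        assert [(s.start, s.end) for s in gains] == [(s.start, s.end) for s in losses]
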