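import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipdelta.core import (
    CoverageTrack,
    GenomicInterval,
    ParseError,
    Peak,
    coverage_from_fragments,
    mean_signal,
    overlaps,
    read_bed,
    read_bedgraph,
    read_chrom_sizes,
    read_narrowpeak,
    rpkm_normalize,
    summit_window,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
    write_narrowpeak,
)

CHROM_SIZES = {"chr2L": 10_000}


class TestGenomicInterval:
    def test_length(self):
        assert GenomicInterval("chr2L", 100, 350).length == 250

    @pytest.mark.parametrize("start,end", [(350, 100), (100, 100), (-1, 50)])
    def test_invalid_coordinates(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr2L", start, end)


class TestOverlaps:
    def test_one_bp_overlap(self):
        assert overlaps(
            GenomicInterval("c", 100, 200), GenomicInterval("c", 199, 300)
        )

    def test_half_open_abutment(self):
        assert not overlaps(
            GenomicInterval("c", 100, 200), GenomicInterval("c", 200, 300)
        )

    def test_min_overlap_not_met(self):
        # overlap length 10 < 20
        assert not overlaps(
            GenomicInterval("c", 100, 200),
            GenomicInterval("c", 150, 160),
            min_overlap=20,
        )

    def test_different_chromosomes(self):
        assert not overlaps(
            GenomicInterval("a", 0, 100), GenomicInterval("b", 0, 100)
        )

    def test_min_overlap_validation(self):
        with pytest.raises(ValueError):
            overlaps(
                GenomicInterval("c", 0, 10), GenomicInterval("c", 0, 10),
                min_overlap=0,
            )


class TestSummitWindow:
    def test_plain_window(self):
        peak = Peak(GenomicInterval("chr3R", 9_000, 11_000), 1_000, 5.0, 1e-3)
        w = summit_window(peak, flank=250)
        assert (w.chrom, w.start, w.end) == ("chr3R", 9_750, 10_250)

    def test_left_clip(self):
        peak = Peak(GenomicInterval("c", 0, 200), 100, 5.0, 1e-3)
        w = summit_window(peak, flank=250)
        assert (w.start, w.end) == (0, 350)

    def test_right_clip(self):
        peak = Peak(GenomicInterval("c", 9_800, 10_000), 150, 5.0, 1e-3)
        w = summit_window(peak, flank=250, chrom_sizes={"c": 10_000})
        assert (w.start, w.end) == (9_700, 10_000)

    def test_zero_flank_rejected(self):
        peak = Peak(GenomicInterval("c", 0, 200), 100, 5.0, 1e-3)
        with pytest.raises(ValueError):
            summit_window(peak, flank=0)

    @given(summit=st.integers(0, 9_999), flank=st.integers(1, 5_000))
    def test_window_within_bounds(self, summit, flank):
        peak = Peak(GenomicInterval("c", summit, summit + 1), 0, 1.0, 0.5)
        w = summit_window(peak, flank=flank, chrom_sizes={"c": 10_000})
        assert 0 <= w.start < w.end <= 10_000
        assert w.length <= 2 * flank


class TestBed:
    def test_roundtrip_and_order(self, tmp_path):
        path = tmp_path / "a.bed"
        ivs = [GenomicInterval("chr2L", 100, 350), GenomicInterval("chr2L", 10, 20)]
        write_bed(ivs, str(path))
        assert read_bed(str(path)) == ivs

    def test_simple_line(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr2L\t100\t350\n")
        assert read_bed(str(path)) == [GenomicInterval("chr2L", 100, 350)]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("")
        assert read_bed(str(path)) == []

    def test_inverted_coordinates(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr2L\t350\t100\n")
        with pytest.raises(ParseError, match="a.bed:1"):
            read_bed(str(path))

    def test_wrong_column_count(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("ok\t1\t2\nchr2L\t100\n")
        with pytest.raises(ParseError, match=":2"):
            read_bed(str(path))

    def test_headers_skipped(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("track name=x\n# comment\nchr2L\t1\t2\n")
        assert len(read_bed(str(path))) == 1


class TestNarrowPeak:
    def _peaks(self):
        return [
            Peak(GenomicInterval("c", 0, 500), 125, 7.25, 1e-5, name="p1"),
            Peak(GenomicInterval("c", 600, 1_100), 499, 3.0, 0.004321, name="p2"),
            Peak(GenomicInterval("d", 10, 400), 0, 0.5, 1.0, name="p3"),
        ]

    def test_roundtrip(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        peaks = self._peaks()
        write_narrowpeak(peaks, str(path))
        back = read_narrowpeak(str(path))
        assert len(back) == len(peaks)
        for a, b in zip(peaks, back):
            assert a.interval == b.interval
            assert a.summit_offset == b.summit_offset
            assert a.score == b.score
            # p-value travels as -log10; identical up to float log/pow noise
            assert b.p_value == pytest.approx(a.p_value, rel=1e-12)

    def test_summit_column(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("c\t0\t500\tp\t100\t.\t7.0\t2.0\t-1\t125\n")
        assert read_narrowpeak(str(path))[0].summit_offset == 125

    def test_summit_minus_one_maps_to_midpoint(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("c\t0\t500\tp\t100\t.\t7.0\t2.0\t-1\t-1\n")
        assert read_narrowpeak(str(path))[0].summit_offset == 250

    def test_summit_outside_interval(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("c\t0\t500\tp\t100\t.\t7.0\t2.0\t-1\t500\n")
        with pytest.raises(ParseError):
            read_narrowpeak(str(path))

    def test_wrong_columns(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("c\t0\t500\tp\t100\t.\t7.0\t2.0\t-1\n")
        with pytest.raises(ParseError):
            read_narrowpeak(str(path))


class TestBedGraph:
    def test_full_bin(self, tmp_path):
        path = tmp_path / "a.bedgraph"
        path.write_text("c\t0\t100\t7\n")
        track = read_bedgraph(str(path), bin_width=100)
        assert track.values["c"][0] == 7.0

    def test_partial_bin_weighted_mean(self, tmp_path):
        # 50 bp at value 4 inside a 100 bp bin, rest uncovered -> 2.0
        path = tmp_path / "a.bedgraph"
        path.write_text("c\t20\t70\t4\n")
        track = read_bedgraph(str(path), bin_width=100)
        assert track.values["c"][0] == pytest.approx(2.0)

    def test_roundtrip_constant(self, tmp_path):
        track = CoverageTrack(
            bin_width=100,
            values={"c": np.full(7, 3.5)},
            chrom_sizes={"c": 700},
        )
        path = tmp_path / "a.bedgraph"
        write_bedgraph(track, str(path))
        back = read_bedgraph(str(path), bin_width=100, chrom_sizes={"c": 700})
        np.testing.assert_allclose(back.values["c"], track.values["c"])

    def test_roundtrip_general(self, tmp_path, rng):
        values = np.round(rng.uniform(0, 9, size=31), 3)
        track = CoverageTrack(
            bin_width=50, values={"c": values}, chrom_sizes={"c": 1_540}
        )
        path = tmp_path / "a.bedgraph"
        write_bedgraph(track, str(path))
        back = read_bedgraph(str(path), bin_width=50, chrom_sizes={"c": 1_540})
        np.testing.assert_allclose(back.values["c"], values, rtol=1e-12)

    def test_overlapping_records_rejected(self, tmp_path):
        path = tmp_path / "a.bedgraph"
        path.write_text("c\t0\t100\t1\nc\t50\t150\t2\n")
        with pytest.raises(ParseError):
            read_bedgraph(str(path))


class TestCoverage:
    def test_one_fragment_one_bin(self):
        track = coverage_from_fragments(
            [GenomicInterval("chr2L", 200, 300)], CHROM_SIZES, bin_width=100
        )
        assert track.values["chr2L"][2] == 1.0
        assert track.values["chr2L"].sum() == 1.0
        assert track.total_mapped == 1

    def test_additivity_of_duplicates(self):
        frag = GenomicInterval("chr2L", 200, 300)
        track = coverage_from_fragments([frag, frag], CHROM_SIZES, bin_width=100)
        assert track.values["chr2L"][2] == 2.0

    def test_half_covered_bin(self):
        track = coverage_from_fragments(
            [GenomicInterval("chr2L", 200, 250)], CHROM_SIZES, bin_width=100
        )
        assert track.values["chr2L"][2] == pytest.approx(0.5)

    def test_unknown_chromosome(self):
        with pytest.raises(ValueError, match="unknown chromosome"):
            coverage_from_fragments(
                [GenomicInterval("nope", 0, 10)], CHROM_SIZES
            )

    def test_bin_count(self):
        track = coverage_from_fragments([], {"c": 1_050}, bin_width=100)
        assert len(track.values["c"]) == 11

    def test_additive_over_fragment_lists(self, rng):
        frags = [
            GenomicInterval("chr2L", int(s), int(s) + int(l))
            for s, l in zip(
                rng.integers(0, 9_000, 50), rng.integers(50, 300, 50)
            )
        ]
        t_all = coverage_from_fragments(frags, CHROM_SIZES)
        t_a = coverage_from_fragments(frags[:20], CHROM_SIZES)
        t_b = coverage_from_fragments(frags[20:], CHROM_SIZES)
        np.testing.assert_allclose(
            t_all.values["chr2L"], t_a.values["chr2L"] + t_b.values["chr2L"]
        )


class TestRpkm:
    def test_closed_form(self):
        track = CoverageTrack(
            bin_width=100, values={"c": np.array([1.0])}, total_mapped=10**6
        )
        assert rpkm_normalize(track).values["c"][0] == pytest.approx(10.0)

    def test_all_zero(self):
        track = CoverageTrack(
            bin_width=100, values={"c": np.zeros(5)}, total_mapped=100
        )
        assert rpkm_normalize(track).values["c"].sum() == 0.0

    def test_doubling_depth_halves_values(self):
        v = np.array([2.0, 4.0])
        t1 = CoverageTrack(bin_width=100, values={"c": v}, total_mapped=1_000)
        t2 = CoverageTrack(bin_width=100, values={"c": v}, total_mapped=2_000)
        np.testing.assert_allclose(
            rpkm_normalize(t1).values["c"], 2 * rpkm_normalize(t2).values["c"]
        )

    def test_linearity(self, rng):
        v = rng.uniform(0, 5, 20)
        a = 3.7
        t = CoverageTrack(bin_width=100, values={"c": v}, total_mapped=500)
        ta = CoverageTrack(bin_width=100, values={"c": a * v}, total_mapped=500)
        np.testing.assert_allclose(
            rpkm_normalize(ta).values["c"], a * rpkm_normalize(t).values["c"]
        )

    def test_zero_depth_rejected(self):
        track = CoverageTrack(bin_width=100, values={"c": np.zeros(1)})
        with pytest.raises(ValueError):
            rpkm_normalize(track)

    def test_double_normalization_rejected(self):
        track = CoverageTrack(
            bin_width=100, values={"c": np.zeros(1)}, total_mapped=10
        )
        with pytest.raises(ValueError):
            rpkm_normalize(rpkm_normalize(track))


class TestMeanSignal:
    def test_two_bins_equal_weight(self):
        track = CoverageTrack(bin_width=100, values={"c": np.array([2.0, 4.0])})
        assert mean_signal(track, GenomicInterval("c", 50, 150)) == pytest.approx(3.0)

    def test_within_one_bin(self):
        track = CoverageTrack(bin_width=100, values={"c": np.array([7.0])})
        assert mean_signal(track, GenomicInterval("c", 10, 60)) == pytest.approx(7.0)

    def test_missing_chromosome(self):
        track = CoverageTrack(bin_width=100, values={"c": np.array([1.0])})
        with pytest.raises(ValueError):
            mean_signal(track, GenomicInterval("d", 0, 10))

    @settings(max_examples=50, deadline=None)
    @given(
        start=st.integers(0, 1_900),
        length=st.integers(1, 99),
        value=st.floats(0, 100, allow_nan=False),
    )
    def test_constant_track(self, start, length, value):
        track = CoverageTrack(bin_width=100, values={"c": np.full(20, value)})
        got = mean_signal(track, GenomicInterval("c", start, start + length))
        assert got == pytest.approx(value)


class TestChromSizes:
    def test_roundtrip(self, tmp_path):
        path = tmp_path / "chrom.sizes"
        write_chrom_sizes({"a": 100, "b": 250}, str(path))
        assert read_chrom_sizes(str(path)) == {"a": 100, "b": 250}
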