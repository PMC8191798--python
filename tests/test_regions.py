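import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ubiprom.regions import (
    GenomicInterval,
    MetaProfile,
    SignalTrack,
    average_signal_over_regions,
    length_matched_sample,
    oriented_flanks,
    read_bed6,
    read_bedgraph,
    read_metaprofile,
    resize_center,
    shift_reads_3prime,
    write_bed6,
    write_bedgraph,
    write_metaprofile,
)


class TestGenomicInterval:
    def test_rejects_degenerate_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 10, "x")

    def test_center_is_floor_midpoint(self):
        assert GenomicInterval("c", 100, 400).center == 250
        assert GenomicInterval("c", 100, 401).center == 250


class TestResizeCenter:
    @pytest.mark.parametrize(
        "start,end,width,exp_start,exp_end",
        [
            (100, 400, 345, 78, 423),  # median promoter-element width
            (100, 400, 300, 100, 400),  # identity when width equals length
            (100, 400, 1, 250, 251),
        ],
    )
    def test_examples(self, start, end, width, exp_start, exp_end):
        out = resize_center(GenomicInterval("c", start, end), width)
        assert (out.start, out.end) == (exp_start, exp_end)

    def test_clips_at_origin_with_warning(self):
        with pytest.warns(UserWarning):
            out = resize_center(GenomicInterval("c", 0, 100), 500)
        assert out.start == 0

    @given(
        start=st.integers(0, 10_000),
        length=st.integers(1, 500),
        width=st.integers(1, 500),
    )
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_center_within_1bp(self, start, length, width):
        """Resizing out and back moves the center by at most 1 bp."""
        iv = GenomicInterval("c", start + 600, start + 600 + length)
        back = resize_center(resize_center(iv, width), length)
        assert abs(back.center - iv.center) <= 1


class TestOrientedFlanks:
    def test_plus_strand(self):
        up, down = oriented_flanks(GenomicInterval("c", 3000, 3300, "+"), 2000)
        assert (up.start, up.end) == (1000, 3000)
        assert (down.start, down.end) == (3300, 5300)

    def test_minus_strand_mirrors(self):
        up, down = oriented_flanks(GenomicInterval("c", 5000, 5300, "-"), 2000)
        assert (up.start, up.end) == (5300, 7300)
        assert (down.start, down.end) == (3000, 5000)

    def test_unstranded_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            oriented_flanks(GenomicInterval("c", 100, 200, "."), 50)

    def test_origin_clip_warns(self):
        with pytest.warns(UserWarning):
            up, _ = oriented_flanks(GenomicInterval("c", 1000, 1300, "+"), 2000)
        assert (up.start, up.end) == (0, 1000)


class TestSignalTrack:
    def test_mean_with_implicit_zero(self):
        track = SignalTrack({"c": [(0, 100, 2.0)]})
        assert track.mean("c", 0, 100) == 2.0
        assert track.mean("c", 50, 150) == 1.0  # half covered
        assert track.mean("c", 200, 300) == 0.0
        assert track.mean("other", 0, 10) == 0.0

    def test_rejects_overlapping_runs(self):
        with pytest.raises(ValueError):
            SignalTrack({"c": [(0, 100, 1.0), (50, 150, 2.0)]})


class TestMetaProfiles:
    def test_constant_track_gives_flat_profile(self):
        track = SignalTrack({"c": [(0, 100_000, 1.0)]})
        regions = [GenomicInterval("c", 10_000 + i * 5000, 10_300 + i * 5000, "+")
                   for i in range(5)]
        prof = average_signal_over_regions(track, regions, 2000, 100)
        assert np.allclose(prof.mean_signal, 1.0)

    def test_partial_overlap_hand_integration(self):
        # value 2.0 on [0,100); one + region centered at 50; window 100, bin 50
        track = SignalTrack({"c": [(0, 100, 2.0)]})
        prof = average_signal_over_regions(
            track, [GenomicInterval("c", 0, 100, "+")], 100, 50
        )
        assert prof.mean_signal.tolist() == [0.0, 2.0, 2.0, 0.0]

    def test_strand_flip_reverses_profile(self):
        """An asymmetric track seen from the minus strand is the mirror."""
        track = SignalTrack({"c": [(10_000, 10_500, 3.0)]})
        plus = [GenomicInterval("c", 10_400, 10_700, "+")]
        minus = [GenomicInterval("c", 10_400, 10_700, "-")]
        p1 = average_signal_over_regions(track, plus, 1000, 50)
        p2 = average_signal_over_regions(track, minus, 1000, 50)
        assert np.allclose(p1.mean_signal, p2.mean_signal[::-1])

    def test_empty_regions_error(self):
        with pytest.raises(ValueError):
            average_signal_over_regions(SignalTrack(), [], 100, 10)

    def test_n_regions_must_be_positive(self):
        with pytest.raises(ValueError):
            MetaProfile(np.array([0]), np.array([0.0]), 0)


class TestLengthMatchedSample:
    def _pool(self, lengths, tag):
        return [
            GenomicInterval("c", 1000 * i, 1000 * i + L, ".", f"{tag}{i}")
            for i, L in enumerate(lengths)
        ]

    def test_only_matching_lengths_selected(self):
        ref = self._pool([300] * 10, "r")
        pool = self._pool([300] * 10 + [600] * 10, "p")
        out = length_matched_sample(pool, ref, 25, seed=0)
        assert {len(x) for x in out} == {300}
        assert len(out) == 10

    def test_self_match_returns_everything(self):
        ref = self._pool([150, 200, 250, 300, 350], "r")
        out = length_matched_sample(ref, ref, 25, seed=1)
        assert sorted(x.id for x in out) == sorted(x.id for x in ref)

    def test_deterministic_given_seed(self):
        ref = self._pool([300] * 8, "r")
        pool = self._pool([300] * 30, "p")
        a = length_matched_sample(pool, ref, 25, seed=42)
        b = length_matched_sample(pool, ref, 25, seed=42)
        assert [x.id for x in a] == [x.id for x in b]

    def test_histogram_matches_reference_distribution(self):
        """Binned KS distance between sample and reference lengths is within
        one bin's mass of zero."""
        rng = np.random.default_rng(3)
        ref = self._pool(rng.integers(150, 350, 200), "r")
        pool = self._pool(rng.integers(150, 350, 2000), "p")
        out = length_matched_sample(pool, ref, 25, seed=5)
        bins = np.arange(150, 400, 25)
        h_ref, _ = np.histogram([len(x) for x in ref], bins=bins)
        h_out, _ = np.histogram([len(x) for x in out], bins=bins)
        f_ref = np.cumsum(h_ref) / h_ref.sum()
        f_out = np.cumsum(h_out) / h_out.sum()
        assert np.max(np.abs(f_ref - f_out)) <= 1.0 / len(bins)

    def test_unservable_bin_warns(self):
        ref = self._pool([300] * 5 + [600] * 5, "r")
        pool = self._pool([300] * 20, "p")
        with pytest.warns(UserWarning):
            out = length_matched_sample(pool, ref, 25, seed=0)
        assert {len(x) for x in out} == {300}


class TestShiftReads:
    @pytest.mark.parametrize(
        "reads,shift,expected,dropped",
        [
            ([(100, "+")], 55, [155], 0),  # half a core nucleosome, 3'-ward
            ([(100, "-")], 55, [45], 0),
            ([(100, "+"), (100, "-")], 0, [100, 100], 0),
            ([(10, "-")], 55, [], 1),
        ],
    )
    def test_shift(self, reads, shift, expected, dropped):
        out, n_drop = shift_reads_3prime(reads, shift)
        assert out == expected
        assert n_drop == dropped


class TestIO:
    def test_bed6_round_trip(self, tmp_path):
        regions = [
            GenomicInterval("chr1", 0, 100, "+", "a"),
            GenomicInterval("chr2", 50, 500, "-", None),
        ]
        path = tmp_path / "r.bed"
        write_bed6(str(path), regions)
        assert read_bed6(str(path)) == regions

    def test_bedgraph_round_trip(self, tmp_path):
        track = SignalTrack({"c": [(0, 10, 1.5), (20, 30, 2.0)]})
        path = tmp_path / "t.bedGraph"
        write_bedgraph(str(path), track)
        back = read_bedgraph(str(path))
        assert back.mean("c", 0, 10) == 1.5
        assert back.mean("c", 10, 20) == 0.0

    def test_metaprofile_round_trip(self, tmp_path):
        prof = MetaProfile(np.arange(-100, 100, 50), np.array([0.5, 1.0, 2.0, 0.25]),
                           7, 50)
        path = tmp_path / "p.tsv"
        write_metaprofile(str(path), prof)
        back = read_metaprofile(str(path))
        assert np.array_equal(back.bin_offsets, prof.bin_offsets)
        assert np.allclose(back.mean_signal, prof.mean_signal)
        assert back.n_regions == 7
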