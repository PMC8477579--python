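"""Tag extension, coverage tracks, track formats and metagene profiles."""

import gzip

import numpy as np
import pytest

from slabir.core import ExonRecord, GenomicInterval
from slabir.coverage import (
    CoverageTrack,
    TagLibrary,
    TagRecord,
    anchor_window,
    build_coverage,
    exon_enrichment,
    extend_tag,
    load_bedgraph,
    load_tags,
    load_wiggle,
    metagene_profile,
    write_track,
)

from conftest import make_models, make_transcript


def _exon(start, end, strand="+", **kw):
    defaults = dict(
        gene_id="G", transcript_id="T", exon_index=2,
        n_exons_in_transcript=3, biotype="lncRNA",
    )
    defaults.update(kw)
    return ExonRecord(interval=GenomicInterval("chr1", start, end, strand), **defaults)


class TestLoadTags:
    def test_bed6_and_tagalign_parse_identically(self, tmp_path):
        bed = tmp_path / "t.bed"
        bed.write_text(
            "chr1\t100\t125\tr1\t0\t+\n"
            "chr1\t200\t225\tr2\t0\t-\n"
            "chr2\t50\t75\tr3\t0\t+\n"
        )
        ta = tmp_path / "t.tagAlign"
        ta.write_text(
            "chr1\t100\t125\tACGTACGTACGTACGTACGTACGTA\t1000\t+\n"
            "chr1\t200\t225\tTTTTACGTACGTACGTACGTACGTA\t1000\t-\n"
            "chr2\t50\t75\tACGTACGTACGTACGTACGTACGTA\t1000\t+\n"
        )
        lib_bed = load_tags(bed, dialect="BED6")
        lib_ta = load_tags(ta, dialect="tagAlign")
        assert lib_bed.total_tags == lib_ta.total_tags == 3
        assert lib_bed.tags == lib_ta.tags

    def test_gzip_transparency(self, tmp_path):
        content = "chr1\t100\t125\tr1\t0\t+\n"
        plain = tmp_path / "t.bed"
        plain.write_text(content)
        zipped = tmp_path / "t.bed.gz"
        with gzip.open(zipped, "wt") as fh:
            fh.write(content)
        assert load_tags(plain).tags == load_tags(zipped).tags

    def test_missing_strand_and_empty_file_raise(self, tmp_path):
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t100\t125\tr1\t0\t.\n")
        with pytest.raises(ValueError, match="strand"):
            load_tags(bad)
        empty = tmp_path / "empty.bed"
        empty.write_text("")
        with pytest.raises(ValueError, match="no tag records"):
            load_tags(empty)


class TestExtendTag:
    def test_plus_strand_extends_rightward_to_150(self):
        iv = extend_tag(TagRecord("chr1", 1000, 1025, "+"), chrom_len=10_000)
        assert (iv.start, iv.end) == (1000, 1150)

    def test_minus_strand_extends_leftward_from_end(self):
        iv = extend_tag(TagRecord("chr1", 2000, 2025, "-"), chrom_len=10_000)
        assert (iv.start, iv.end) == (1875, 2025)

    def test_clipping_at_chromosome_boundaries(self):
        iv = extend_tag(TagRecord("chr1", 50, 75, "-"), chrom_len=10_000)
        assert (iv.start, iv.end) == (0, 75)
        iv = extend_tag(TagRecord("chr1", 9950, 9975, "+"), chrom_len=10_000)
        assert (iv.start, iv.end) == (9950, 10_000)


class TestBuildCoverage:
    def test_single_tag_covers_extended_interval(self):
        lib = TagLibrary([TagRecord("chr1", 10, 35, "+")])
        track = build_coverage(lib, {"chr1": 1000})
        arr = track.values("chr1")
        assert np.all(arr[10:160] == 1) and arr.sum() == 150

    def test_identical_tags_are_additive(self):
        lib = TagLibrary([TagRecord("chr1", 10, 35, "+")] * 2)
        track = build_coverage(lib, {"chr1": 1000})
        assert np.all(track.values("chr1")[10:160] == 2)

    def test_mass_equals_bruteforce_per_tag_sum(self, rng):
        chrom_len = 5000
        tags = [
            TagRecord(
                "chr1",
                int(s),
                int(s) + 25,
                "+" if rng.random() < 0.5 else "-",
            )
            for s in rng.integers(0, chrom_len - 25, size=1000)
        ]
        track = build_coverage(TagLibrary(tags), {"chr1": chrom_len})
        expected = sum(
            extend_tag(t, 150, chrom_len).length for t in tags
        )
        assert track.mass() == expected

    def test_unknown_chromosome_dropped_with_warning(self):
        lib = TagLibrary(
            [TagRecord("chr1", 10, 35, "+"), TagRecord("chrUn", 10, 35, "+")]
        )
        with pytest.warns(UserWarning, match="dropped 1 tags"):
            track = build_coverage(lib, {"chr1": 1000})
        assert track.mass() == 150


class TestTrackFormats:
    def test_bedgraph_basics(self, tmp_path):
        path = tmp_path / "a.bedgraph"
        path.write_text("chr1\t0\t10\t2.5\n")
        track = load_bedgraph(path, {"chr1": 100})
        assert np.all(track.values("chr1")[:10] == 2.5)
        assert track.values("chr1")[10:].sum() == 0

    def test_empty_bedgraph_is_zero_track(self, tmp_path):
        path = tmp_path / "e.bedgraph"
        path.write_text("")
        assert load_bedgraph(path, {"chr1": 100}).mass() == 0

    def test_overlapping_intervals_raise(self, tmp_path):
        path = tmp_path / "o.bedgraph"
        path.write_text("chr1\t0\t10\t1\nchr1\t5\t15\t2\n")
        with pytest.raises(ValueError, match="overlapping"):
            load_bedgraph(path, {"chr1": 100})

    @pytest.mark.parametrize("dialect", ["bedGraph", "wiggle"])
    def test_round_trip_on_step_function(self, tmp_path, dialect, rng):
        values = np.repeat(
            rng.integers(0, 4, size=40).astype(float), rng.integers(1, 30, size=40)
        )
        track = CoverageTrack({"chr1": values})
        path = tmp_path / "t.out"
        write_track(track, path, dialect=dialect)
        loader = load_bedgraph if dialect == "bedGraph" else load_wiggle
        reloaded = loader(path, {"chr1": len(values)})
        np.testing.assert_array_equal(reloaded.values("chr1"), values)

    def test_constant_track_writes_single_bedgraph_line(self, tmp_path):
        track = CoverageTrack({"chr1": np.ones(100)})
        path = tmp_path / "c.bedgraph"
        write_track(track, path)
        assert path.read_text() == "chr1\t0\t100\t1\n"

    def test_zero_runs_are_omitted(self, tmp_path):
        arr = np.zeros(10)
        arr[2:4] = 1
        arr[6:7] = 1
        path = tmp_path / "z.bedgraph"
        write_track(CoverageTrack({"chr1": arr}), path)
        assert len(path.read_text().splitlines()) == 2


class TestAnchorWindow:
    def test_plus_strand_upstream_positions(self):
        window = anchor_window(_exon(1000, 1200), "upstream")
        assert list(window[:3]) == [500, 501, 502]
        assert window[499] == 999 and window[500] == 1000
        assert window[-1] == 1079 and len(window) == 580

    def test_minus_strand_upstream_is_hand_mirror(self):
        window = anchor_window(_exon(1000, 1200, strand="-"), "upstream")
        assert window[0] == 1699 and window[499] == 1200
        assert window[500] == 1199 and window[-1] == 1120

    def test_minus_strand_downstream(self):
        window = anchor_window(_exon(1000, 1200, strand="-"), "downstream")
        assert window[0] == 1079 and window[79] == 1000
        assert window[80] == 999 and window[-1] == 500

    def test_short_exon_and_out_of_bounds_are_excluded(self):
        assert anchor_window(_exon(1000, 1079), "upstream") is None
        assert anchor_window(_exon(100, 300), "upstream") is None  # lo < 0
        assert (
            anchor_window(_exon(800, 1000), "downstream", chrom_len=1200) is None
        )


class TestMetageneProfile:
    def test_uniform_track_gives_constant_profile(self, uniform_track):
        track = uniform_track(value=3.0)
        prof = metagene_profile(
            track, [_exon(10_000, 10_200)], "upstream", library_size=2_000_000
        )
        np.testing.assert_allclose(prof.values, 3.0 / 2.0)
        assert prof.n_windows == 1

    def test_single_tag_on_exon_edge_only(self):
        # extended tag covering exactly the exon's first 150 bp
        lib = TagLibrary([TagRecord("chr1", 10_000, 10_025, "+")])
        track = build_coverage(lib, {"chr1": 100_000})
        prof = metagene_profile(
            track, [_exon(10_000, 10_200)], "upstream", library_size=1
        )
        assert np.all(prof.values[:500] == 0)
        np.testing.assert_allclose(prof.values[500:], 1e6 / 1)

    def test_library_depth_invariance(self, rng):
        tags = [
            TagRecord("chr1", int(s), int(s) + 25, "+")
            for s in rng.integers(9000, 11_000, size=200)
        ]
        exons = [_exon(10_000, 10_200)]
        t1 = build_coverage(TagLibrary(tags), {"chr1": 100_000})
        t2 = build_coverage(TagLibrary(tags * 2), {"chr1": 100_000})
        p1 = metagene_profile(t1, exons, "upstream", library_size=len(tags))
        p2 = metagene_profile(t2, exons, "upstream", library_size=2 * len(tags))
        np.testing.assert_allclose(p1.values, p2.values)

    def test_exon_count_invariance(self, uniform_track):
        track = uniform_track(value=1.0)
        exons = [_exon(10_000, 10_200), _exon(50_000, 50_300)]
        p1 = metagene_profile(track, exons, "downstream", library_size=1000)
        p2 = metagene_profile(track, exons * 2, "downstream", library_size=1000)
        assert p2.n_windows == 2 * p1.n_windows
        np.testing.assert_allclose(p1.values, p2.values)

    def test_strand_mirror_symmetry(self, rng):
        """Mirroring the genome and flipping all strands leaves profiles unchanged."""
        chrom_len = 50_000
        tags = [
            TagRecord("chr1", int(s), int(s) + 25, "+" if rng.random() < 0.5 else "-")
            for s in rng.integers(0, chrom_len - 200, size=2000)
        ]
        exons = [_exon(10_000, 10_300), _exon(30_000, 30_150, strand="+")]
        mirrored_tags = [
            TagRecord(
                "chr1",
                chrom_len - t.end,
                chrom_len - t.start,
                "-" if t.strand == "+" else "+",
            )
            for t in tags
        ]
        mirrored_exons = [
            _exon(
                chrom_len - e.interval.end,
                chrom_len - e.interval.start,
                strand="-" if e.interval.strand == "+" else "+",
            )
            for e in exons
        ]
        for side in ("upstream", "downstream"):
            p = metagene_profile(
                build_coverage(TagLibrary(tags), {"chr1": chrom_len}),
                exons, side, library_size=len(tags),
            )
            pm = metagene_profile(
                build_coverage(TagLibrary(mirrored_tags), {"chr1": chrom_len}),
                mirrored_exons, side, library_size=len(tags),
            )
            np.testing.assert_allclose(p.values, pm.values)

    def test_position_randomized_library_is_flat(self, rng):
        """A shuffled library has no positional structure at the anchors."""
        chrom_len = 200_000
        n = 20_000
        tags = [
            TagRecord("chr1", int(s), int(s) + 25, "+")
            for s in rng.integers(0, chrom_len - 150, size=n)
        ]
        track = build_coverage(TagLibrary(tags), {"chr1": chrom_len})
        exons = [_exon(s, s + 300) for s in range(20_000, 180_000, 8000)]
        prof = metagene_profile(track, exons, "upstream", library_size=n)
        mean = prof.values.mean()
        # per-position SE of a mean of n_windows Poisson-ish coverage values
        se = prof.values.std() / 1.0
        assert np.all(np.abs(prof.values - mean) < 5 * se + 1e-9)

    def test_zero_windows_raises(self, uniform_track):
        with pytest.raises(ValueError, match="admissible"):
            metagene_profile(
                uniform_track(), [_exon(100, 300)], "upstream", library_size=10
            )


class TestExonEnrichment:
    def _profile(self, side, exonic_value, intronic_value):
        from slabir.coverage import MetaProfile

        values = np.full(580, float(intronic_value))
        if side == "upstream":
            values[500:] = exonic_value
        else:
            values[:80] = exonic_value
        return MetaProfile(side=side, values=values, n_windows=5, library_size=100)

    def test_flat_profiles_give_zero(self):
        up = self._profile("upstream", 2.0, 2.0)
        down = self._profile("downstream", 2.0, 2.0)
        assert exon_enrichment(up, down) == 0.0

    def test_programmed_ratio_recovers_percent(self):
        up = self._profile("upstream", 1.28, 1.0)
        down = self._profile("downstream", 1.28, 1.0)
        assert exon_enrichment(up, down) == pytest.approx(28.0)

    def test_zero_intronic_mean_raises(self):
        up = self._profile("upstream", 1.0, 0.0)
        down = self._profile("downstream", 1.0, 0.0)
        with pytest.raises(ValueError, match="undefined"):
            exon_enrichment(up, down)
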