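"""I/O round trips, coordinate conventions, and input validation."""

import io
import logging

import pytest
from hypothesis import given, settings, strategies as st

from hfrscan import Interval, Probe, ProbeTrack
from hfrscan.io import (
    ParseError,
    read_assay_table,
    read_features,
    read_gene_models,
    read_probe_track,
    write_gene_models_gff3,
    write_intervals_bed,
    write_probe_track,
)

from conftest import make_track


class TestProbeTrackParsing:
    def test_two_line_bedgraph(self):
        text = "chr6 52100000 52100060 0.8\nchr6 52100050 52100110 -0.3\n"
        track = read_probe_track(io.StringIO(text))
        assert len(track) == 2
        assert [p.nlr for p in track] == [0.8, -0.3]
        assert track.probes[0].start == 52100000

    def test_empty_file_warns_and_returns_empty_track(self, caplog):
        with caplog.at_level(logging.WARNING):
            track = read_probe_track(io.StringIO(""))
        assert len(track) == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_header_and_comment_lines_skipped(self):
        text = "track type=bedGraph\n# comment\nchr1 0 60 1.0\n"
        assert len(read_probe_track(io.StringIO(text))) == 1

    def test_malformed_line_reports_line_number(self):
        text = "chr1 0 60 1.0\nchr1 50 110\n"
        with pytest.raises(ParseError, match="line 2"):
            read_probe_track(io.StringIO(text))

    def test_non_numeric_nlr_rejected(self):
        with pytest.raises(ParseError, match="non-numeric NLR"):
            read_probe_track(io.StringIO("chr1 0 60 high\n"))

    def test_duplicate_probe_coordinates_rejected(self):
        text = "chr1 0 60 1.0\nchr1 0 60 -1.0\n"
        with pytest.raises(ValueError, match="duplicate|non-increasing"):
            read_probe_track(io.StringIO(text))

    def test_unsorted_input_is_sorted_on_read(self):
        text = "chr1 100 160 1.0\nchr1 0 60 2.0\n"
        track = read_probe_track(io.StringIO(text))
        assert [p.start for p in track] == [0, 100]

    def test_one_based_tsv_shifts_start_down(self):
        track = read_probe_track(
            io.StringIO("chr1\t1\t60\t1.0\n"), format="tsv", one_based=True
        )
        assert (track.probes[0].start, track.probes[0].end) == (0, 60)

    def test_roundtrip_preserves_probes_to_six_decimals(self):
        import numpy as np

        rng = np.random.default_rng(42)
        track = make_track(np.round(rng.normal(0, 1, size=100), 6))
        buf = io.StringIO()
        write_probe_track(track, buf)
        buf.seek(0)
        back = read_probe_track(buf)
        assert [(p.chrom, p.start, p.end) for p in back] == [
            (p.chrom, p.start, p.end) for p in track
        ]
        for a, b in zip(track, back):
            assert b.nlr == pytest.approx(a.nlr, abs=1e-6)


class TestProbeInvariants:
    def test_probe_rejects_empty_interval(self):
        with pytest.raises(ValueError):
            Probe("chr1", 100, 100, 0.5)

    def test_probe_rejects_non_finite_nlr(self):
        with pytest.raises(ValueError, match="finite"):
            Probe("chr1", 0, 60, float("nan"))

    def test_probes_in_uses_half_open_overlap(self):
        track = make_track([1.0, -1.0, 1.0])
        assert [p.start for p in track.probes_in("chrT", 60, 100)] == [50]
        assert track.probes_in("chrT", 160, 200) == []


class TestFeatureReading:
    def test_bed_line_kept_as_is(self):
        fs = read_features(io.StringIO("chr6\t100\t200\tpeak1\n"), format="bed")
        assert fs.intervals == (Interval("chr6", 100, 200, name="peak1"),)

    def test_gff3_converts_to_zero_based_half_open(self):
        line = "chr6\tsrc\tregion\t101\t200\t.\t+\t.\tID=x\n"
        fs = read_features(io.StringIO(line), format="gff3")
        assert (fs.intervals[0].start, fs.intervals[0].end) == (100, 200)

    def test_overlapping_bed_records_not_merged(self):
        text = "chr1\t0\t100\n" "chr1\t50\t150\n" "chr1\t90\t200\n"
        fs = read_features(io.StringIO(text), format="bed")
        assert [(iv.start, iv.end) for iv in fs] == [(0, 100), (50, 150), (90, 200)]

    def test_bad_line_names_offender(self):
        with pytest.raises(ParseError, match="line 1"):
            read_features(io.StringIO("chr1\tnotanumber\t5\n"), format="bed")


class TestBedWriting:
    def test_bed6_rendering(self):
        buf = io.StringIO()
        write_intervals_bed([Interval("chrA", 1000, 1510, name="A_1-2.1")], buf)
        assert buf.getvalue() == "chrA\t1000\t1510\tA_1-2.1\t.\t.\n"

    def test_empty_list_yields_empty_file(self):
        buf = io.StringIO()
        write_intervals_bed([], buf)
        assert buf.getvalue() == ""

    def test_unsorted_input_rejected(self):
        ivs = [Interval("chr1", 100, 200), Interval("chr1", 0, 50)]
        with pytest.raises(ValueError, match="sorted"):
            write_intervals_bed(ivs, io.StringIO())

    def test_write_read_roundtrip_exact(self):
        ivs = [
            Interval("chr1", 0, 510, name="x", strand="+"),
            Interval("chr1", 1000, 1860, name="y", strand="-"),
            Interval("chr2", 5, 900, name="z"),
        ]
        buf = io.StringIO()
        write_intervals_bed(ivs, buf)
        buf.seek(0)
        back = read_features(buf, format="bed")
        assert [(v.chrom, v.start, v.end, v.name) for v in back] == [
            (v.chrom, v.start, v.end, v.name) for v in ivs
        ]


class TestGeneModels:
    def test_gff3_roundtrip_with_ordinals(self):
        from hfrscan import GeneModel

        genes = [
            GeneModel("hoxa1", "A", 1, "-", "chr6", 1000, 4000),
            GeneModel("hoxa2", "A", 2, "-", "chr6", 9000, 12000),
        ]
        buf = io.StringIO()
        write_gene_models_gff3(genes, buf)
        buf.seek(0)
        back = read_gene_models(buf)
        assert [(g.name, g.ordinal, g.start, g.end, g.strand) for g in back] == [
            ("hoxa1", 1, 1000, 4000, "-"),
            ("hoxa2", 2, 9000, 12000, "-"),
        ]

    def test_strand_resolved_tss_and_tes(self):
        from hfrscan import GeneModel

        plus = GeneModel("g+", "A", 1, "+", "chr1", 100, 500)
        minus = GeneModel("g-", "A", 2, "-", "chr1", 100, 500)
        assert (plus.tss, plus.tes) == (100, 500)
        assert (minus.tss, minus.tes) == (500, 100)


class TestAssayTable:
    @staticmethod
    def _table(rows):
        header = "construct\tbatch\treplicate\tcolonies\n"
        return io.StringIO(header + "".join(f"{c}\t{b}\t{r}\t{n}\n" for c, b, r, n in rows))

    def test_full_design_parses(self):
        rows = [
            (c, b, r, 100)
            for b in ("b1", "b2")
            for c in ("vector", "hfr1", "hfr2")
            for r in (1, 2, 3)
        ]
        assert len(read_assay_table(self._table(rows))) == 18

    def test_batch_missing_vector_names_batch(self):
        rows = [("vector", "b1", 1, 100), ("hfr1", "b2", 1, 50)]
        with pytest.raises(ValueError, match="b2"):
            read_assay_table(self._table(rows))

    def test_duplicate_record_rejected(self):
        rows = [("vector", "b1", 1, 100), ("vector", "b1", 1, 90)]
        with pytest.raises(ValueError, match="duplicate"):
            read_assay_table(self._table(rows))

    def test_negative_count_rejected(self):
        rows = [("vector", "b1", 1, -5)]
        with pytest.raises(ValueError, match="negative"):
            read_assay_table(self._table(rows))


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(
        st.floats(min_value=-5, max_value=5, allow_nan=False, width=32),
        min_size=1,
        max_size=60,
    )
)
def test_probe_track_roundtrip_property(nlrs):
    """write then read reproduces any synthetic track to 6 decimals."""
    track = make_track(nlrs)
    buf = io.StringIO()
    write_probe_track(track, buf)
    buf.seek(0)
    back = read_probe_track(buf)
    assert len(back) == len(track)
    for a, b in zip(track, back):
        assert (a.chrom, a.start, a.end) == (b.chrom, b.start, b.end)
        assert b.nlr == pytest.approx(a.nlr, abs=1e-6)
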