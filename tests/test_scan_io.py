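"""End-to-end scanning and file I/O, anchored on the CB1 validation case."""

import json

import pytest

from mirrorcode import (
    FormatError,
    MotifKind,
    ProteinRecord,
    ScanConfig,
    NTermLocation,
    TMSegment,
    TMStatus,
    build_records,
    read_fasta,
    read_tm_annotations,
    report_from_json,
    report_to_json,
    scan_protein,
    write_report,
)
from mirrorcode.reference import cb1_record


@pytest.fixture(scope="module")
def cb1_report():
    return scan_protein(cb1_record())


class TestReadFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">prot1 desc\nACDEF\nGHIKL\n")
        assert read_fasta(p) == [("prot1", "ACDEFGHIKL")]

    def test_lowercase_and_gaps_normalized(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">p\nac-de f\n")
        assert read_fasta(p) == [("p", "ACDEF")]

    def test_multi_record(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">a\nAAA\n>b\nCCC\n")
        assert [pid for pid, _ in read_fasta(p)] == ["a", "b"]

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text("")
        with pytest.raises(FormatError, match="empty"):
            read_fasta(p)

    def test_text_before_header_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text("ACDEF\n>p\nAAA\n")
        with pytest.raises(FormatError, match="line 1"):
            read_fasta(p)


class TestReadTMAnnotations:
    def test_unsorted_rows_sorted(self, tmp_path):
        p = tmp_path / "tm.tsv"
        p.write_text(
            "protein_id\ttm_index\tstart\tend\ttopology\n"
            "p\t2\t40\t60\textracellular\n"
            "p\t1\t10\t30\textracellular\n"
        )
        topo, segs = read_tm_annotations(p)["p"]
        assert topo is NTermLocation.EXTRACELLULAR
        assert [(s.index, s.start, s.end) for s in segs] == [(1, 10, 30), (2, 40, 60)]

    def test_overlap_rejected(self, tmp_path):
        p = tmp_path / "tm.tsv"
        p.write_text(
            "protein_id\ttm_index\tstart\tend\ttopology\n"
            "p\t1\t10\t30\textracellular\n"
            "p\t2\t25\t45\textracellular\n"
        )
        with pytest.raises(FormatError, match="overlap"):
            read_tm_annotations(p)

    def test_bad_topology_rejected(self, tmp_path):
        p = tmp_path / "tm.tsv"
        p.write_text(
            "protein_id\ttm_index\tstart\tend\ttopology\np\t1\t10\t30\tsideways\n"
        )
        with pytest.raises(FormatError, match="sideways"):
            read_tm_annotations(p)

    def test_start_not_before_end_rejected(self, tmp_path):
        p = tmp_path / "tm.tsv"
        p.write_text(
            "protein_id\ttm_index\tstart\tend\ttopology\np\t1\t30\t30\textracellular\n"
        )
        with pytest.raises(FormatError):
            read_tm_annotations(p)

    def test_tm_beyond_sequence_rejected_at_record_build(self, tmp_path):
        fa = tmp_path / "x.fasta"
        fa.write_text(">p\n" + "A" * 20 + "\n")
        tm = tmp_path / "tm.tsv"
        tm.write_text(
            "protein_id\ttm_index\tstart\tend\ttopology\np\t1\t10\t30\textracellular\n"
        )
        with pytest.raises(ValueError, match="exceeds"):
            build_records(fa, tm)

    def test_protein_without_annotation_rejected(self, tmp_path):
        fa = tmp_path / "x.fasta"
        fa.write_text(">p\nAAAA\n>q\nCCCC\n")
        tm = tmp_path / "tm.tsv"
        tm.write_text(
            "protein_id\ttm_index\tstart\tend\ttopology\np\t1\t1\t3\textracellular\n"
        )
        with pytest.raises(FormatError, match="no TM annotation"):
            build_records(fa, tm)


class TestCB1Scan:
    """The seven-TM worked example: mirror duet in TM3 and TM7."""

    def test_per_tm_statuses(self, cb1_report):
        expected = {
            1: TMStatus.NONE,
            2: TMStatus.NONE,
            3: TMStatus.DUAL_MIRROR,
            4: TMStatus.CARC_ONLY,
            5: TMStatus.CRAC_ONLY,
            6: TMStatus.NONE,
            7: TMStatus.DUAL_MIRROR,
        }
        assert {c.tm_index: c.status for c in cb1_report.classifications} == expected

    def test_summary_counts(self, cb1_report):
        assert cb1_report.summary == {
            "n_dual": 2, "n_carc_only": 1, "n_crac_only": 1, "n_none": 3
        }

    def test_tm3_extended_to_186_214(self, cb1_report):
        tm3 = next(t for t in cb1_report.tms if t.index == 3)
        assert (tm3.extended_start, tm3.extended_end) == (186, 214)

    def test_tm3_motif_coordinates(self, cb1_report):
        motifs = {
            (lm.kind, lm.match.start, lm.match.end): lm.leaflet.value
            for lm in cb1_report.motifs_of(3)
        }
        assert motifs == {
            (MotifKind.CARC, 186, 196): "outer",
            (MotifKind.CRAC, 204, 214): "inner",
        }

    def test_tm4_carc_232_239_inner(self, cb1_report):
        (lm,) = cb1_report.motifs_of(4)
        assert (lm.kind, lm.match.start, lm.match.end) == (MotifKind.CARC, 232, 239)
        assert lm.leaflet.value == "inner"  # TM4 is even: CARC sits in the inner leaflet

    def test_tm5_crac_in_inner_leaflet_ending_at_lys300(self, cb1_report):
        (lm,) = cb1_report.motifs_of(5)
        assert lm.kind is MotifKind.CRAC
        assert lm.match.pos_basic == 300
        assert lm.leaflet.value == "inner"

    def test_zero_tm_protein_scans_empty(self):
        rec = ProteinRecord(
            id="p", sequence="ACDEF" * 10,
            topology=NTermLocation.EXTRACELLULAR, tm_segments=(),
        )
        report = scan_protein(rec)
        assert report.classifications == ()
        assert report.summary == {
            "n_dual": 0, "n_carc_only": 0, "n_crac_only": 0, "n_none": 0
        }

    def test_summary_counts_sum_to_n_tms(self, cb1_report):
        assert sum(cb1_report.summary.values()) == len(cb1_report.tms) == 7


class TestReportWriters:
    def test_tsv_contains_printed_tm3_motifs(self, cb1_report, tmp_path):
        path = write_report(cb1_report, tmp_path / "r.tsv", "tsv")
        lines = path.read_text().splitlines()
        assert lines[0].startswith("protein_id\ttm_index\tkind")
        rows = [l.split("\t") for l in lines[1:]]
        assert ["P21554", "3", "CARC", "186", "196"] == rows[0][:5] or any(
            r[2] == "CARC" and r[3] == "186" and r[4] == "196" for r in rows
        )
        assert any(r[2] == "CRAC" and r[3] == "204" and r[4] == "214" for r in rows)

    def test_bed_uses_zero_based_half_open(self, cb1_report, tmp_path):
        path = write_report(cb1_report, tmp_path / "r.bed", "bed")
        rows = [l.split("\t") for l in path.read_text().splitlines()]
        carc_tm3 = next(r for r in rows if r[3] == "CARC:outer" and r[2] == "196")
        assert carc_tm3[1] == "185"  # [185, 196) == 1-based 186..196

    def test_tsv_bed_coordinate_round_trip(self, cb1_report, tmp_path):
        tsv = write_report(cb1_report, tmp_path / "r.tsv", "tsv").read_text()
        bed = write_report(cb1_report, tmp_path / "r.bed", "bed").read_text()
        tsv_intervals = {
            (r.split("\t")[0], int(r.split("\t")[3]), int(r.split("\t")[4]))
            for r in tsv.splitlines()[1:]
        }
        bed_intervals = {
            (r.split("\t")[0], int(r.split("\t")[1]) + 1, int(r.split("\t")[2]))
            for r in bed.splitlines()
        }
        assert tsv_intervals == bed_intervals

    def test_json_round_trip(self, cb1_report):
        assert report_from_json(report_to_json(cb1_report)) == cb1_report

    def test_writers_are_byte_stable(self, cb1_report, tmp_path):
        for fmt in ("tsv", "bed", "json"):
            a = write_report(cb1_report, tmp_path / f"a.{fmt}", fmt).read_bytes()
            b = write_report(
                scan_protein(cb1_record()), tmp_path / f"b.{fmt}", fmt
            ).read_bytes()
            assert a == b

    def test_unsupported_format_rejected(self, cb1_report, tmp_path):
        with pytest.raises(ValueError, match="format"):
            write_report(cb1_report, tmp_path / "r.xml", "xml")


class TestConfigSwitches:
    def test_all_matches_mode_reports_non_maximal_rows(self):
        report = scan_protein(cb1_record(), ScanConfig(maximal_only=False))
        rows = report.motif_rows()
        tm3_carc = [r for r in rows if r["tm_index"] == 3 and r["kind"] == "CARC"]
        assert len(tm3_carc) > 1
        assert sum(r["maximal"] for r in tm3_carc) == 1

    def test_every_motif_within_extended_tm(self):
        report = scan_protein(cb1_record(), ScanConfig(maximal_only=False))
        bounds = {t.index: (t.extended_start, t.extended_end) for t in report.tms}
        for row in report.motif_rows():
            lo, hi = bounds[row["tm_index"]]
            assert lo <= row["start"] <= row["end"] <= hi
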