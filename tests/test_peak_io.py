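"""Format readers/writers: coordinate conventions, round trips, settings."""

import pytest

from consensuspeaks import peak_io
from consensuspeaks.core import MergedPeak, PeakRecord
from consensuspeaks.peak_io import (
    DEFAULT_SETTINGS,
    PeakParseError,
    SettingsError,
    SettingsTable,
    default_settings_path,
    parse_settings_table,
    read_bed,
    read_gem_event,
    read_homer_pos,
    read_narrowpeak,
    read_integrated_table,
    write_bed,
    write_homer_pos,
    write_integrated_table,
    write_narrowpeak,
)


class TestNarrowPeak:
    def test_empty_file_gives_empty_set(self, tmp_path):
        p = tmp_path / "empty.narrowPeak"
        p.write_text("")
        assert len(read_narrowpeak(p, "m")) == 0

    def test_direct_column_mapping(self, tmp_path):
        p = tmp_path / "one.narrowPeak"
        p.write_text("chr1\t100\t200\tp1\t0\t.\t5.0\t3.0\t2.5\t50\n")
        (peak,) = read_narrowpeak(p, "m").peaks
        assert (peak.chrom, peak.start, peak.end) == ("chr1", 100, 200)
        assert peak.summit_offset == 50
        assert peak.score == 5.0
        assert peak.source_caller == "m"

    def test_track_and_comment_lines_skipped(self, tmp_path):
        p = tmp_path / "t.narrowPeak"
        p.write_text(
            "track name=peaks\n# comment\nbrowser position chr1\n"
            "chr1\t10\t20\tp\t0\t+\t1\t-1\t-1\t5\n"
        )
        assert len(read_narrowpeak(p, "m")) == 1

    @pytest.mark.parametrize(
        "line",
        ["chr1\tx\t200\tp", "chr1\t300\t200\tp", "chr1\t200\t200\tp"],
    )
    def test_malformed_coordinates_name_line(self, tmp_path, line):
        p = tmp_path / "bad.narrowPeak"
        p.write_text("chr1\t1\t2\tok\n" + line + "\n")
        with pytest.raises(PeakParseError, match="line 2"):
            read_narrowpeak(p, "m")

    def test_roundtrip_against_generator(self, tmp_path, small_landscape):
        caller = next(iter(small_landscape.caller_sets))
        original = small_landscape.caller_sets[caller]
        path = tmp_path / "rt.narrowPeak"
        write_narrowpeak(original, path)
        reread = read_narrowpeak(path, caller)
        assert len(reread) == len(original)
        for a, b in zip(original, reread):
            assert (a.chrom, a.start, a.end, a.name) == (b.chrom, b.start, b.end, b.name)
            assert a.summit_offset == b.summit_offset
            assert b.score == pytest.approx(a.score, rel=1e-5)


class TestHomerPos:
    def test_one_based_inclusive_conversion(self, tmp_path):
        p = tmp_path / "h.pos"
        p.write_text("#PeakID\tchr\tstart\tend\tstrand\np1\tchr1\t101\t200\t+\n")
        (peak,) = read_homer_pos(p, "h").peaks
        assert (peak.start, peak.end) == (100, 200)

    def test_header_only_file(self, tmp_path):
        p = tmp_path / "h.pos"
        p.write_text("#PeakID\tchr\tstart\tend\tstrand\n# another header\n")
        assert len(read_homer_pos(p, "h")) == 0

    def test_widths_match_inclusive_definition(self, tmp_path):
        rows = [(11, 30), (5, 5), (100, 250), (42, 43), (7, 1006)]
        p = tmp_path / "h.pos"
        p.write_text(
            "#id\tchr\ts\te\tstrand\n"
            + "".join(f"p{i}\tchr2\t{s}\t{e}\t+\n" for i, (s, e) in enumerate(rows))
        )
        peaks = read_homer_pos(p, "h").peaks
        assert [pk.width for pk in peaks] == [e - s + 1 for s, e in rows]

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "h.pos"
        p.write_text("p1\tchr1\t200\t100\t+\n")
        with pytest.raises(PeakParseError):
            read_homer_pos(p, "h")

    def test_write_read_roundtrip(self, tmp_path):
        peaks = [
            PeakRecord("chr1", 99, 220, "a_1", 3.5, "+", -1, "a"),
            PeakRecord("chr3", 0, 10, "a_2", 1.0, "-", -1, "a"),
        ]
        path = tmp_path / "rt.pos"
        write_homer_pos(peaks, path)
        reread = read_homer_pos(path, "a").peaks
        assert [(p.chrom, p.start, p.end, p.strand) for p in reread] == [
            (p.chrom, p.start, p.end, p.strand) for p in peaks
        ]


class TestGemEvent:
    def test_symmetric_expansion(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("chr2:5000\t12.5\n")
        (peak,) = read_gem_event(p, "g", expand_bp=100).peaks
        assert (peak.start, peak.end, peak.summit_offset) == (4900, 5100, 100)
        assert peak.score == 12.5

    def test_clamped_at_chromosome_start(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("chr1:50\t1\n")
        (peak,) = read_gem_event(p, "g", expand_bp=100).peaks
        assert (peak.start, peak.end) == (0, 150)
        assert peak.summit_offset == 50  # summit still at the event position

    def test_widths_equal_twice_halfwidth_except_clamped(self, tmp_path):
        positions = [40, 150, 99, 5000, 202, 100, 77, 303, 1000, 64]
        p = tmp_path / "g.txt"
        p.write_text("".join(f"chr1:{pos}\t2\n" for pos in positions))
        peaks = read_gem_event(p, "g", expand_bp=100).peaks
        for pos, peak in zip(positions, peaks):
            expected_start = max(0, pos - 100)
            assert (peak.start, peak.end) == (expected_start, pos + 100)
            assert peak.start + peak.summit_offset == pos

    def test_unparseable_coordinate(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("chr1-500\t1\n")
        with pytest.raises(PeakParseError):
            read_gem_event(p, "g")


class TestBed:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chrX\t0\t10\n")
        (peak,) = read_bed(p, "b").peaks
        assert (peak.chrom, peak.start, peak.end, peak.strand) == ("chrX", 0, 10, ".")
        assert peak.name == "b_1"

    def test_browser_track_lines_skipped(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("browser position chr1:1-100\ntrack name=x\nchr1\t5\t9\n")
        assert len(read_bed(p, "b")) == 1

    def test_too_few_columns(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t100\n")
        with pytest.raises(PeakParseError):
            read_bed(p, "b")

    def test_roundtrip(self, tmp_path):
        peaks = [
            PeakRecord("chr1", 5, 50, "b_1", 7.0, "+", -1, "b"),
            PeakRecord("chr2", 0, 9, "b_2", 0.0, ".", -1, "b"),
        ]
        path = tmp_path / "rt.bed"
        write_bed(peaks, path)
        reread = read_bed(path, "b").peaks
        assert [(p.chrom, p.start, p.end, p.name, p.score, p.strand) for p in reread] \
            == [(p.chrom, p.start, p.end, p.name, p.score, p.strand) for p in peaks]


class TestSettingsTable:
    def test_default_file_reproduces_builtin_defaults(self):
        table = parse_settings_table(default_settings_path())
        assert list(table.entries.items()) == list(DEFAULT_SETTINGS.items())

    def test_tab_separated_argument_string(self, tmp_path):
        p = tmp_path / "st.tsv"
        p.write_text("samtools_view\t-q 20\n")
        assert parse_settings_table(p)["samtools_view"] == "-q 20"

    def test_blank_argument_allowed(self, tmp_path):
        p = tmp_path / "st.tsv"
        p.write_text("macs2_callpeak\n")
        assert parse_settings_table(p)["macs2_callpeak"] == ""

    def test_unknown_program_rejected(self, tmp_path):
        p = tmp_path / "st.tsv"
        p.write_text("bowtie2\t-x idx\n")
        with pytest.raises(SettingsError, match="bowtie2"):
            parse_settings_table(p)

    def test_duplicate_program_rejected(self, tmp_path):
        p = tmp_path / "st.tsv"
        p.write_text("gem\t-a\ngem\t-b\n")
        with pytest.raises(SettingsError, match="duplicate"):
            parse_settings_table(p)

    def test_absent_programs_take_defaults(self, tmp_path):
        p = tmp_path / "st.tsv"
        p.write_text("genrich\t-q 0.01\n")
        table = parse_settings_table(p)
        assert table["genrich"] == "-q 0.01"
        assert table["samtools_view"] == DEFAULT_SETTINGS["samtools_view"]

    @pytest.mark.parametrize(
        "row,expected",
        [("", "given"), ("-d 1500", 1500), ("-d given", "given")],
    )
    def test_merge_gap_from_mergepeaks_row(self, row, expected):
        table = SettingsTable({"homer_mergePeaks": row})
        assert table.merge_gap() == expected


class TestIntegratedTable:
    def _make_peaks(self):
        p1 = MergedPeak(
            "peak_1", "chr1", 100, 400,
            {"a": ["a_1"], "b": ["b_1"], "c": ["c_2"], "d": ["d_9"]},
        )
        p1.fold_change = 7.25
        p1.weighted_center = 260
        p1.neg_log10_idr_by_caller = {"a": 2.0, "b": 1.5, "c": 3.0, "d": 0.5}
        p1.final_idr = 10 ** -7.0
        p2 = MergedPeak("peak_2", "chr1", 900, 1000, {"b": ["b_7"]})
        return [p1, p2]

    def test_empty_collection_gives_header_only(self, tmp_path):
        path = tmp_path / "it.tsv"
        write_integrated_table([], path, callers=["a", "b"])
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("peak_id\t")

    def test_caller_count_matches_provenance(self, tmp_path):
        path = tmp_path / "it.tsv"
        write_integrated_table(self._make_peaks(), path)
        row = path.read_text().splitlines()[1].split("\t")
        assert row[5] == "4"
        assert row[6] == "a,b,c,d"

    def test_numeric_roundtrip(self, tmp_path):
        peaks = self._make_peaks()
        path = tmp_path / "it.tsv"
        write_integrated_table(peaks, path)
        reread = read_integrated_table(path)
        assert len(reread) == 2
        r1, r2 = reread
        assert (r1.start, r1.end, r1.n_callers) == (100, 400, 4)
        assert r1.fold_change == pytest.approx(7.25, rel=1e-6)
        assert r1.weighted_center == 260
        assert r1.final_idr == pytest.approx(1e-7, rel=1e-5)
        assert r1.neg_log10_idr_by_caller == pytest.approx(
            {"a": 2.0, "b": 1.5, "c": 3.0, "d": 0.5}
        )
        assert r2.fold_change is None and r2.final_idr is None
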