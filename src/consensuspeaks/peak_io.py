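"""Readers and writers for peak, settings-table and integrated-table formats.

Supported peak dialects
-----------------------
``narrowpeak``  ENCODE BED6+4; column 10 is the summit offset.
``broadpeak``   ENCODE BED6+3 (no summit column).
``bed``         BED3-BED6.
``homer_pos``   Tab-separated position file with ``#`` headers and 1-based
                inclusive coordinates (converted to 0-based half-open on read).
``gem_event``   Single-coordinate binding events (``chrom:position``),
                expanded to fixed-width intervals on read.

All readers emit :class:`~consensuspeaks.core.PeakRecord` objects in the
internal 0-based half-open convention and auto-generate missing peak names
as ``<caller>_<ordinal>`` so provenance joins downstream are well defined.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core import CallerPeakSet, MergedPeak, PeakRecord, chrom_sort_key

__all__ = [
    "PeakParseError",
    "SettingsError",
    "SettingsTable",
    "DEFAULT_SETTINGS",
    "SETTINGS_PROGRAMS",
    "read_narrowpeak",
    "read_broadpeak",
    "read_bed",
    "read_homer_pos",
    "read_gem_event",
    "read_peaks",
    "write_narrowpeak",
    "write_bed",
    "write_homer_pos",
    "default_settings_path",
    "parse_settings_table",
    "write_settings_table",
    "write_integrated_table",
    "read_integrated_table",
    "INTEGRATED_FIXED_COLUMNS",
]


class PeakParseError(ValueError):
    """Raised when a peak file line cannot be parsed; names the line number."""


class SettingsError(ValueError):
    """Raised on unknown or duplicated settings-table program names."""


# --------------------------------------------------------------------------
# settings table
# --------------------------------------------------------------------------

#: Fixed program vocabulary and default argument strings of the pipeline's
#: default settings table.  Programs absent from a user-provided table fall
#: back to these values.
DEFAULT_SETTINGS: "OrderedDict[str, str]" = OrderedDict(
    [
        ("fastqc1", "-q"),
        ("clumpify", "dedupe spany addcount qout=33 fixjunk"),
        ("bbduk", "ktrim=l hdist=2"),
        ("trimmomatic", "LEADING:20 SLIDINGWINDOW:4:20 TRAILING:20 MINLEN:20"),
        ("fastqc2", "-q"),
        ("bwa_mem", ""),
        ("samtools_view", "-q 20"),
        ("plotfingerprint", ""),
        ("fastqc3", "-q"),
        ("macs2_callpeak", ""),
        ("gem", "-Xmx10G --k_min 8 --k_max 12"),
        ("sicer2", ""),
        ("homer_findPeaks", ""),
        ("genrich", "--adjustp -v"),
        ("homer_mergePeaks", ""),
        ("homer_annotatePeaks", ""),
        ("fold_change_calculator", "--normfactor uniquely_mapped"),
        ("homer_findMotifsGenome", "-size given -mask"),
        ("meme_chip", "-meme-nmotifs 25"),
    ]
)

SETTINGS_PROGRAMS: frozenset[str] = frozenset(DEFAULT_SETTINGS)


class SettingsTable:
    """Ordered mapping from pipeline program name to its argument string.

    The program vocabulary is fixed; unknown names are rejected.  A table is
    a complete reproducibility record: programs the user did not mention are
    present with their default arguments.
    """

    def __init__(self, entries: Mapping[str, str] | None = None):
        merged: "OrderedDict[str, str]" = OrderedDict(DEFAULT_SETTINGS)
        if entries:
            for program, args in entries.items():
                if program not in SETTINGS_PROGRAMS:
                    raise SettingsError(f"unknown program name: {program!r}")
                merged[program] = args
        self.entries: "OrderedDict[str, str]" = merged

    def __getitem__(self, program: str) -> str:
        return self.entries[program]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, SettingsTable) and self.entries == other.entries

    def items(self):
        return self.entries.items()

    def merge_gap(self) -> str | int:
        """Merge mode implied by the ``homer_mergePeaks`` row.

        A ``-d <int>`` argument selects center-distance clustering with that
        window; a blank row (or ``-d given``) selects literal-overlap mode.
        """
        args = self.entries["homer_mergePeaks"].split()
        if "-d" in args:
            value = args[args.index("-d") + 1] if args.index("-d") + 1 < len(args) else ""
            if value == "given":
                return "given"
            try:
                return int(value)
            except ValueError:
                raise SettingsError(
                    f"homer_mergePeaks -d expects an integer or 'given', got {value!r}"
                )
        return "given"


def default_settings_path() -> Path:
    """Path to the bundled default settings table file."""
    return Path(__file__).parent / "data" / "default_settings.tsv"


def parse_settings_table(path: str | Path) -> SettingsTable:
    """Parse a two-column (program, argument-string) settings table.

    Any run of whitespace separates the program name from its argument
    string; everything after the first separator is kept verbatim.  Unknown
    or duplicated program names raise :class:`SettingsError`.
    """
    entries: "OrderedDict[str, str]" = OrderedDict()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            stripped = line.strip()
            parts = stripped.split(None, 1)
            program = parts[0]
            args = parts[1].strip() if len(parts) > 1 else ""
            if program == "Program" and args == "Argument":
                continue  # column header row
            if program not in SETTINGS_PROGRAMS:
                raise SettingsError(
                    f"line {lineno}: unknown program name: {program!r}"
                )
            if program in entries:
                raise SettingsError(
                    f"line {lineno}: duplicate program name: {program!r}"
                )
            entries[program] = args
    return SettingsTable(entries)


def write_settings_table(table: SettingsTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for program, args in table.items():
            fh.write(f"{program}\t{args}\n")


# --------------------------------------------------------------------------
# peak readers
# --------------------------------------------------------------------------

def _data_lines(path: str | Path):
    """Yield (lineno, fields) for tab-separated data lines, skipping
    track/browser/comment lines and blank lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            lstripped = line.lstrip()
            if lstripped.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _parse_int(token: str, what: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise PeakParseError(f"line {lineno}: non-integer {what}: {token!r}")


def _parse_float(token: str, default: float = 0.0) -> float:
    try:
        return float(token)
    except ValueError:
        return default


def read_narrowpeak(path: str | Path, caller: str) -> CallerPeakSet:
    """Read an ENCODE narrowPeak (BED6+4) file.

    Accepts 6-10 tab-separated columns.  Column 7 (signalValue) is used as
    the peak score when present, falling back to column 5; column 10 is the
    summit offset (-1 = absent).
    """
    peaks: list[PeakRecord] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise PeakParseError(f"line {lineno}: expected >= 3 columns")
        chrom = fields[0]
        start = _parse_int(fields[1], "start", lineno)
        end = _parse_int(fields[2], "end", lineno)
        if start >= end or start < 0:
            raise PeakParseError(
                f"line {lineno}: invalid interval {start}-{end}"
            )
        name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else (
            f"{caller}_{len(peaks) + 1}"
        )
        if len(fields) > 6:
            score = _parse_float(fields[6])
        elif len(fields) > 4:
            score = _parse_float(fields[4])
        else:
            score = 0.0
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
        summit = -1
        if len(fields) > 9:
            summit = _parse_int(fields[9], "summit offset", lineno)
            if summit >= end - start:
                raise PeakParseError(
                    f"line {lineno}: summit offset {summit} outside peak"
                )
            if summit < 0:
                summit = -1
        peaks.append(
            PeakRecord(chrom, start, end, name, score, strand, summit, caller)
        )
    return CallerPeakSet(caller, peaks, "narrowpeak")


def read_broadpeak(path: str | Path, caller: str) -> CallerPeakSet:
    """Read an ENCODE broadPeak (BED6+3) file; identical to narrowPeak minus
    the summit column."""
    out = read_narrowpeak(path, caller)
    return CallerPeakSet(caller, out.peaks, "broadpeak")


def read_bed(path: str | Path, caller: str) -> CallerPeakSet:
    """Read BED3-BED6.  Missing name/score/strand take defaults
    (auto-ID, 0, '.')."""
    peaks: list[PeakRecord] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise PeakParseError(f"line {lineno}: expected >= 3 columns")
        chrom = fields[0]
        start = _parse_int(fields[1], "start", lineno)
        end = _parse_int(fields[2], "end", lineno)
        if start >= end or start < 0:
            raise PeakParseError(f"line {lineno}: invalid interval {start}-{end}")
        name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else (
            f"{caller}_{len(peaks) + 1}"
        )
        score = _parse_float(fields[4]) if len(fields) > 4 else 0.0
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
        peaks.append(PeakRecord(chrom, start, end, name, score, strand, -1, caller))
    return CallerPeakSet(caller, peaks, "bed")


def read_homer_pos(path: str | Path, caller: str) -> CallerPeakSet:
    """Read a HOMER-style position file.

    Tab-separated with ``#`` header lines; columns are peak-ID, chrom,
    start, end, strand, [score...].  Input coordinates are 1-based
    inclusive and are converted to 0-based half-open (start-1, end).
    """
    peaks: list[PeakRecord] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise PeakParseError(f"line {lineno}: expected >= 4 columns")
        name = fields[0] if fields[0] not in (".", "") else f"{caller}_{len(peaks) + 1}"
        chrom = fields[1]
        start1 = _parse_int(fields[2], "start", lineno)
        end1 = _parse_int(fields[3], "end", lineno)
        start, end = start1 - 1, end1
        if end <= start or start < 0:
            raise PeakParseError(
                f"line {lineno}: invalid 1-based interval {start1}-{end1}"
            )
        strand = fields[4] if len(fields) > 4 and fields[4] in ("+", "-") else "."
        score = _parse_float(fields[5]) if len(fields) > 5 else 0.0
        peaks.append(PeakRecord(chrom, start, end, name, score, strand, -1, caller))
    return CallerPeakSet(caller, peaks, "homer_pos")


def read_gem_event(
    path: str | Path, caller: str, expand_bp: int = 100
) -> CallerPeakSet:
    """Read a GEM-style event table of point binding events.

    Each data row carries a ``chrom:position`` event coordinate and a signal
    value.  Events become intervals ``[position - expand_bp,
    position + expand_bp)`` with the summit at the original position; starts
    are clamped at 0 (the summit offset then still points at the event).
    """
    if expand_bp <= 0:
        raise ValueError("expand_bp must be > 0")
    peaks: list[PeakRecord] = []
    for lineno, fields in _data_lines(path):
        token = fields[0].strip()
        if token.lower().startswith("position"):
            continue  # GEM column header
        if ":" not in token:
            raise PeakParseError(f"line {lineno}: unparseable event {token!r}")
        chrom, _, pos_s = token.rpartition(":")
        if not chrom:
            raise PeakParseError(f"line {lineno}: unparseable event {token!r}")
        pos = _parse_int(pos_s, "position", lineno)
        score = _parse_float(fields[1]) if len(fields) > 1 else 0.0
        start = max(0, pos - expand_bp)
        end = pos + expand_bp
        summit = pos - start
        name = f"{caller}_{len(peaks) + 1}"
        peaks.append(PeakRecord(chrom, start, end, name, score, ".", summit, caller))
    return CallerPeakSet(caller, peaks, "gem_event")


_READERS = {
    "narrowpeak": read_narrowpeak,
    "broadpeak": read_broadpeak,
    "bed": read_bed,
    "homer_pos": read_homer_pos,
}


def read_peaks(
    path: str | Path, caller: str, dialect: str, expand_bp: int = 100
) -> CallerPeakSet:
    """Dispatch to the reader for ``dialect``."""
    if dialect == "gem_event":
        return read_gem_event(path, caller, expand_bp=expand_bp)
    try:
        return _READERS[dialect](path, caller)
    except KeyError:
        raise ValueError(f"unknown peak dialect {dialect!r}")


# --------------------------------------------------------------------------
# peak writers
# --------------------------------------------------------------------------

def write_narrowpeak(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    """Write narrowPeak (BED6+4); score column 7 carries the peak score."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t{p.strand}\t"
                f"{p.score:g}\t-1\t-1\t{p.summit_offset}\n"
            )


def write_bed(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t{p.strand}\n"
            )


def write_homer_pos(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    """Write the HOMER position dialect (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("#PeakID\tchr\tstart\tend\tstrand\tscore\n")
        for p in peaks:
            fh.write(
                f"{p.name}\t{p.chrom}\t{p.start + 1}\t{p.end}\t"
                f"{p.strand}\t{p.score:g}\n"
            )


# --------------------------------------------------------------------------
# integrated output table
# --------------------------------------------------------------------------

INTEGRATED_FIXED_COLUMNS = [
    "peak_id",
    "chrom",
    "start",
    "end",
    "width",
    "caller_count",
    "callers",
    "fold_change",
    "weighted_center",
]


def _fmt(value: float | int | None) -> str:
    if value is None:
        return "NA"
    if isinstance(value, int):
        return str(value)
    return f"{value:.6g}"


def write_integrated_table(
    peaks: Sequence[MergedPeak],
    path: str | Path,
    callers: Sequence[str] | None = None,
    extra_columns: Mapping[str, Mapping[str, object]] | None = None,
) -> None:
    """Write the single integrated output table.

    One row per merged peak: identifier, span, width, the number and list of
    detecting callers, fold change, weighted center, one -log10 IDR column
    per caller and the final aggregated IDR.  Unset statistics are written
    as ``NA``.  Rows are written in the order given (the ranking order when
    the peaks have been ranked).

    ``extra_columns`` maps column name -> (peak_id -> value) for optional
    trailing columns (e.g. motif hit counts and distances).
    """
    if callers is None:
        seen: "OrderedDict[str, None]" = OrderedDict()
        for p in peaks:
            for c in sorted(p.constituents):
                seen.setdefault(c)
        callers = list(seen)
    extra_columns = extra_columns or {}
    header = (
        INTEGRATED_FIXED_COLUMNS
        + [f"neg_log10_idr_{c}" for c in callers]
        + ["final_idr"]
        + list(extra_columns)
    )
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for p in peaks:
            row = [
                p.peak_id,
                p.chrom,
                str(p.start),
                str(p.end),
                str(p.width),
                str(p.n_callers),
                ",".join(sorted(p.constituents)),
                _fmt(p.fold_change),
                _fmt(p.weighted_center),
            ]
            for c in callers:
                if p.neg_log10_idr_by_caller:
                    row.append(_fmt(p.neg_log10_idr_by_caller.get(c, 0.0)))
                else:
                    row.append("NA")
            row.append(_fmt(p.final_idr))
            for col in extra_columns:
                value = extra_columns[col].get(p.peak_id)
                row.append("NA" if value is None else str(value))
            fh.write("\t".join(row) + "\n")


def read_integrated_table(path: str | Path) -> list[MergedPeak]:
    """Re-read an integrated table written by :func:`write_integrated_table`.

    Constituent peak names are not stored in the table, so provenance is
    reconstructed with one placeholder constituent per detecting caller.
    """
    out: list[MergedPeak] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idr_cols = [
            (i, col[len("neg_log10_idr_"):])
            for i, col in enumerate(header)
            if col.startswith("neg_log10_idr_")
        ]
        for raw in fh:
            fields = raw.rstrip("\n").split("\t")
            rec = dict(zip(header, fields))
            callers = rec["callers"].split(",") if rec["callers"] else []
            peak = MergedPeak(
                peak_id=rec["peak_id"],
                chrom=rec["chrom"],
                start=int(rec["start"]),
                end=int(rec["end"]),
                constituents={c: [f"{c}:{rec['peak_id']}"] for c in callers},
            )
            if rec["fold_change"] != "NA":
                peak.fold_change = float(rec["fold_change"])
            if rec["weighted_center"] != "NA":
                peak.weighted_center = int(float(rec["weighted_center"]))
            nl = {}
            for i, caller in idr_cols:
                if fields[i] != "NA":
                    nl[caller] = float(fields[i])
            if nl:
                peak.neg_log10_idr_by_caller = nl
            if rec["final_idr"] != "NA":
                peak.final_idr = float(rec["final_idr"])
            out.append(peak)
    return out
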