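"""Core domain types shared across the integration layer.

All genomic intervals in this package use the BED convention: 0-based,
half-open ``[start, end)``.  Readers for 1-based dialects convert on input
and writers convert back on output, so nothing downstream ever needs to
think about coordinate systems.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "PeakRecord",
    "CallerPeakSet",
    "MergedPeak",
    "UpsetCounts",
    "chrom_sort_key",
]

_CHROM_TOKEN = re.compile(r"(\d+)")


def chrom_sort_key(chrom: str) -> tuple:
    """Natural-order sort key for chromosome names (chr2 < chr10 < chrX)."""
    parts = _CHROM_TOKEN.split(chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True)
class PeakRecord:
    """One caller-reported peak interval.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open span in bp; ``0 <= start < end``.
    name : str
        Peak identifier; auto-generated by readers when absent.
    score : float
        Caller-reported significance or enrichment (caller-specific scale).
    strand : str
        One of ``+``, ``-``, ``.``.
    summit_offset : int
        Offset of the point-source summit from ``start``; ``-1`` when absent.
    source_caller : str
        Label of the caller that reported this peak (non-empty).
    """

    chrom: str
    start: int
    end: int
    name: str
    score: float = 0.0
    strand: str = "."
    summit_offset: int = -1
    source_caller: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.summit_offset != -1 and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        if not self.source_caller:
            raise ValueError("source_caller must be non-empty")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class CallerPeakSet:
    """Ordered collection of peaks from one caller, with its source dialect."""

    caller: str
    peaks: list[PeakRecord]
    format_dialect: str = "bed"

    _DIALECTS = frozenset(
        {"narrowpeak", "broadpeak", "bed", "homer_pos", "gem_event"}
    )

    def __post_init__(self) -> None:
        if self.format_dialect not in self._DIALECTS:
            raise ValueError(f"unknown dialect {self.format_dialect!r}")
        for p in self.peaks:
            if p.source_caller != self.caller:
                raise ValueError(
                    f"peak {p.name} has source_caller {p.source_caller!r}, "
                    f"expected {self.caller!r}"
                )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def sorted(self) -> "CallerPeakSet":
        return CallerPeakSet(
            self.caller,
            sorted(self.peaks, key=lambda p: (chrom_sort_key(p.chrom), p.start, p.end)),
            self.format_dialect,
        )


@dataclass
class MergedPeak:
    """A union-set region with caller provenance and per-peak statistics.

    ``fold_change``, ``weighted_center`` and ``final_idr`` start unset
    (``None``) and are filled in by the quantification and IDR stages.
    ``neg_log10_idr_by_caller`` maps caller label to -log10(IDR); callers
    that did not detect the peak contribute 0.
    """

    peak_id: str
    chrom: str
    start: int
    end: int
    constituents: dict[str, list[str]] = field(default_factory=dict)
    fold_change: float | None = None
    weighted_center: int | None = None
    neg_log10_idr_by_caller: dict[str, float] = field(default_factory=dict)
    final_idr: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span {self.chrom}:{self.start}-{self.end}")
        if not self.constituents:
            raise ValueError("merged peak must have at least one constituent")

    @property
    def detecting_callers(self) -> frozenset[str]:
        return frozenset(self.constituents)

    @property
    def n_callers(self) -> int:
        return len(self.constituents)

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class UpsetCounts:
    """Counts of merged peaks by exact detecting-caller subset."""

    counts: dict[frozenset[str], int]

    def __post_init__(self) -> None:
        for subset in self.counts:
            if not subset:
                raise ValueError("empty caller subset is not a valid key")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_rows(self) -> list[tuple[str, int]]:
        """Combination/count rows, callers joined by '&', sorted for stable output."""
        return [
            ("&".join(sorted(subset)), n)
            for subset, n in sorted(
                self.counts.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))
            )
        ]
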