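"""Peak-set comparison: pairwise overlap counts, Jaccard index, and the
replicate-consistency + fold-change filter.

Comparisons reuse the union merge machinery: the two sets are merged under
a gap rule and each merged region is classified by provenance as private
to A, private to B, or shared.  The Jaccard index is computed on merged
region counts (set cardinalities), matching how peak-set overlap is
reported as a percentage of peaks rather than of base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import CallerPeakSet, MergedPeak, PeakRecord
from .merge import merge_peaks, normalize_gap

__all__ = [
    "OverlapResult",
    "pairwise_overlap",
    "replicate_consistency_filter",
]


@dataclass(frozen=True)
class OverlapResult:
    """Region counts from a two-set comparison."""

    only_a: int
    only_b: int
    shared: int

    @property
    def jaccard(self) -> float:
        total = self.only_a + self.only_b + self.shared
        return self.shared / total if total else 0.0

    @property
    def total(self) -> int:
        return self.only_a + self.only_b + self.shared


def _as_set(peaks, label: str) -> CallerPeakSet:
    if isinstance(peaks, CallerPeakSet):
        relabeled = [
            PeakRecord(
                p.chrom, p.start, p.end, p.name, p.score, p.strand,
                p.summit_offset, label,
            )
            for p in peaks
        ]
        return CallerPeakSet(label, relabeled)
    out = []
    for i, p in enumerate(peaks, start=1):
        if isinstance(p, PeakRecord):
            out.append(
                PeakRecord(
                    p.chrom, p.start, p.end, p.name or f"{label}_{i}",
                    p.score, p.strand, p.summit_offset, label,
                )
            )
        elif isinstance(p, MergedPeak):
            out.append(
                PeakRecord(p.chrom, p.start, p.end, p.peak_id or f"{label}_{i}",
                           0.0, ".", -1, label)
            )
        else:
            chrom, start, end = p[:3]
            out.append(PeakRecord(chrom, start, end, f"{label}_{i}", 0.0, ".", -1, label))
    return CallerPeakSet(label, out)


def pairwise_overlap(
    a: Sequence, b: Sequence, gap: str | int = "given"
) -> OverlapResult:
    """Classify merged regions of two peak sets as private or shared.

    ``a`` and ``b`` may be CallerPeakSets, sequences of PeakRecord or
    MergedPeak, or plain (chrom, start, end) triples.  ``gap`` follows the
    union-merge convention: ``"given"`` for literal overlap or an integer
    center-distance window in bp.
    """
    set_a = _as_set(a, "A")
    set_b = _as_set(b, "B")
    if len(set_a) == 0 and len(set_b) == 0:
        raise ValueError("both peak sets are empty; nothing to compare")
    merged = merge_peaks([set_a, set_b], gap=gap)
    only_a = only_b = shared = 0
    for m in merged:
        has_a = "A" in m.constituents
        has_b = "B" in m.constituents
        if has_a and has_b:
            shared += 1
        elif has_a:
            only_a += 1
        else:
            only_b += 1
    return OverlapResult(only_a=only_a, only_b=only_b, shared=shared)


def replicate_consistency_filter(
    replicates: Sequence[Sequence],
    min_reps: int,
    fold_changes: Mapping[str, float],
    min_fc: float,
    gap: str | int = 1500,
) -> list[MergedPeak]:
    """Keep regions detected in enough replicates with enough enrichment.

    Replicates are merged under ``gap`` (default: center-distance 1500 bp,
    the window used to overlap replicate peak sets of point-binding data);
    a merged region is kept when it is detected in at least ``min_reps``
    replicates and the maximum fold change over the negative control among
    its constituent peaks is at least ``min_fc``.

    ``fold_changes`` maps constituent peak names to their fold change;
    constituents missing from the mapping count as fold change 0.
    """
    if min_reps > len(replicates):
        raise ValueError(
            f"min_reps={min_reps} exceeds replicate count {len(replicates)}"
        )
    sets = [
        _as_set(rep, f"rep{i}") for i, rep in enumerate(replicates, start=1)
    ]
    merged = merge_peaks(sets, gap=gap)
    kept = []
    for m in merged:
        if m.n_callers < min_reps:
            continue
        max_fc = max(
            (
                fold_changes.get(name, 0.0)
                for names in m.constituents.values()
                for name in names
            ),
            default=0.0,
        )
        if max_fc >= min_fc:
            kept.append(m)
    return kept
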