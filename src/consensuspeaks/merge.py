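"""Union peak-set construction by single-linkage interval clustering.

Two peaks from any callers belong to the same merged region when they
satisfy the gap rule, directly or through a chain of intermediates
(transitive closure).  Two gap rules are provided:

``"given"``      literal overlap - intervals share at least 1 bp;
``d`` (int >= 0) center distance - |center_A - center_B| <= d, with
                 center = floor((start + end) / 2).

Each cluster becomes one :class:`~consensuspeaks.core.MergedPeak` spanning
min(start) to max(end) of its constituents, with full caller provenance.
Strand is ignored: ChIP enrichment is unstranded.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Iterable, Sequence

from .core import CallerPeakSet, MergedPeak, PeakRecord, UpsetCounts, chrom_sort_key

__all__ = [
    "merge_peaks",
    "upset_counts",
    "subset_by_caller_count",
    "normalize_gap",
]


def normalize_gap(gap: str | int) -> str | int:
    """Validate a gap mode token: ``"given"`` or a non-negative integer."""
    if isinstance(gap, bool):
        raise ValueError(f"unknown gap mode: {gap!r}")
    if isinstance(gap, int):
        if gap < 0:
            raise ValueError("center-distance window must be >= 0")
        return gap
    if isinstance(gap, str):
        if gap == "given":
            return "given"
        try:
            return normalize_gap(int(gap))
        except ValueError:
            pass
    raise ValueError(f"unknown gap mode: {gap!r}")


def _clusters_literal(peaks: list[PeakRecord]) -> list[list[PeakRecord]]:
    """Single-linkage clusters under >= 1 bp overlap via a sorted sweep.

    After sorting by start, a peak joins the open cluster iff its start is
    strictly below the running max end; this sweep computes the exact
    transitive closure for interval overlap.
    """
    peaks = sorted(peaks, key=lambda p: (p.start, p.end))
    clusters: list[list[PeakRecord]] = []
    current: list[PeakRecord] = []
    max_end = -1
    for p in peaks:
        if current and p.start < max_end:
            current.append(p)
            max_end = max(max_end, p.end)
        else:
            if current:
                clusters.append(current)
            current = [p]
            max_end = p.end
    if current:
        clusters.append(current)
    return clusters


def _clusters_center(peaks: list[PeakRecord], d: int) -> list[list[PeakRecord]]:
    """Single-linkage clusters under |center_i - center_j| <= d.

    On the line, transitive closure of the center-distance relation is
    obtained by sorting centers and splitting wherever two consecutive
    centers are more than ``d`` apart.
    """
    peaks = sorted(peaks, key=lambda p: (p.center, p.start, p.end))
    clusters: list[list[PeakRecord]] = []
    current: list[PeakRecord] = []
    prev_center = None
    for p in peaks:
        if current and p.center - prev_center <= d:
            current.append(p)
        else:
            if current:
                clusters.append(current)
            current = [p]
        prev_center = p.center
    if current:
        clusters.append(current)
    return clusters


def merge_peaks(
    sets: Iterable[CallerPeakSet],
    gap: str | int = "given",
    id_prefix: str = "peak",
) -> list[MergedPeak]:
    """Merge all caller peak sets into a provenance-annotated union set.

    Parameters
    ----------
    sets
        One :class:`CallerPeakSet` per caller, all in the internal 0-based
        half-open convention.
    gap
        ``"given"`` for literal-overlap clustering, or an integer
        center-distance window in bp.
    id_prefix
        Merged peak identifiers are ``<prefix>_<n>`` in output order.

    Returns
    -------
    list of MergedPeak sorted by (chrom natural order, start, end).
    """
    gap = normalize_gap(gap)
    by_chrom: dict[str, list[PeakRecord]] = defaultdict(list)
    for ps in sets:
        for p in ps:
            by_chrom[p.chrom].append(p)

    merged: list[MergedPeak] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        peaks = by_chrom[chrom]
        if gap == "given":
            clusters = _clusters_literal(peaks)
        else:
            clusters = _clusters_center(peaks, gap)
        for cluster in clusters:
            constituents: dict[str, list[str]] = defaultdict(list)
            for p in cluster:
                constituents[p.source_caller].append(p.name)
            merged.append(
                MergedPeak(
                    peak_id="",
                    chrom=chrom,
                    start=min(p.start for p in cluster),
                    end=max(p.end for p in cluster),
                    constituents=dict(constituents),
                )
            )
    merged.sort(key=lambda m: (chrom_sort_key(m.chrom), m.start, m.end))
    for i, m in enumerate(merged, start=1):
        m.peak_id = f"{id_prefix}_{i}"
    return merged


def upset_counts(merged: Iterable[MergedPeak]) -> UpsetCounts:
    """Count merged peaks by the exact subset of detecting callers."""
    counts: Counter[frozenset[str]] = Counter()
    for m in merged:
        counts[m.detecting_callers] += 1
    return UpsetCounts(dict(counts))


def subset_by_caller_count(
    merged: Sequence[MergedPeak], k: int, n_callers: int
) -> list[MergedPeak]:
    """Peaks detected by at least ``k`` of ``n_callers`` callers.

    ``k = 1`` returns the union unchanged; ``k = n_callers`` the consensus.
    """
    if not (1 <= k <= n_callers):
        raise ValueError(f"k must be in [1, {n_callers}], got {k}")
    return [m for m in merged if m.n_callers >= k]
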