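"""Per-peak fold change and weighted peak center from read coverage.

Fold change is the mean per-base ChIP depth over the peak divided by the
depth-normalized mean control depth, with a pseudocount on both sides so
empty-control peaks stay finite.  Depth normalization uses the ratio of
uniquely mapped read counts (ChIP over control), so the scaled control is
depth-matched to the ChIP sample.

The weighted peak center is the coverage centroid of the ChIP signal over
the peak: round(sum(pos * depth) / sum(depth)).  It is independent of any
summit reported by an individual caller; with zero coverage it falls back
to the interval midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import MergedPeak

__all__ = [
    "AlignmentSummary",
    "CoverageVector",
    "read_alignment_summaries",
    "read_bedgraph",
    "write_bedgraph",
    "compute_norm_factor",
    "peak_fold_change",
    "weighted_peak_center",
    "quantify_peaks",
    "pool_coverage",
]


@dataclass(frozen=True)
class AlignmentSummary:
    """Read-mapping summary for one sample.

    ``uniquely_mapped`` drives depth normalization; ``role`` is ``chip`` or
    ``control``.
    """

    sample_id: str
    uniquely_mapped: int
    total_reads: int
    role: str = "chip"
    replicate_index: int = 1

    def __post_init__(self) -> None:
        if self.uniquely_mapped < 0 or self.total_reads < self.uniquely_mapped:
            raise ValueError(
                f"{self.sample_id}: need 0 <= uniquely_mapped <= total_reads"
            )
        if self.role not in ("chip", "control"):
            raise ValueError(f"{self.sample_id}: role must be chip or control")
        if self.replicate_index < 1:
            raise ValueError(f"{self.sample_id}: replicate_index must be >= 1")


@dataclass
class CoverageVector:
    """Per-base read depth over ``[origin, origin + len(depths))`` of one
    chromosome."""

    chrom: str
    origin: int
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.ndim != 1:
            raise ValueError("depths must be one-dimensional")
        if np.any(self.depths < 0):
            raise ValueError("depths must be non-negative")

    @property
    def end(self) -> int:
        return self.origin + len(self.depths)

    def slice(self, start: int, end: int) -> np.ndarray:
        """Depths over [start, end); the vector must span the interval."""
        if start < self.origin or end > self.end or self.chrom is None:
            raise ValueError(
                f"coverage on {self.chrom}:{self.origin}-{self.end} does not "
                f"span [{start}, {end})"
            )
        return self.depths[start - self.origin : end - self.origin]


def read_alignment_summaries(path: str | Path) -> list[AlignmentSummary]:
    """Read a 4/5-column TSV: sample_id, role, uniquely_mapped, total_reads
    [, replicate_index]."""
    out = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "sample_id":
                continue
            rep = int(fields[4]) if len(fields) > 4 else 1
            out.append(
                AlignmentSummary(
                    sample_id=fields[0],
                    role=fields[1],
                    uniquely_mapped=int(fields[2]),
                    total_reads=int(fields[3]),
                    replicate_index=rep,
                )
            )
    return out


def read_bedgraph(path: str | Path) -> dict[str, CoverageVector]:
    """Read a bedGraph (chrom, start, end, depth; 0-based half-open) into
    one dense CoverageVector per chromosome, origin 0."""
    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e, v = line.split("\t")[:4]
            spans.setdefault(chrom, []).append((int(s), int(e), float(v)))
    out: dict[str, CoverageVector] = {}
    for chrom, rows in spans.items():
        length = max(e for _, e, _ in rows)
        depths = np.zeros(length, dtype=float)
        for s, e, v in rows:
            depths[s:e] = v
        out[chrom] = CoverageVector(chrom, 0, depths)
    return out


def write_bedgraph(coverage: Mapping[str, CoverageVector], path: str | Path) -> None:
    """Write coverage as run-length-merged bedGraph; zero runs are skipped."""
    with open(path, "w") as fh:
        for chrom in sorted(coverage):
            cov = coverage[chrom]
            d = cov.depths
            if len(d) == 0:
                continue
            # boundaries of equal-depth runs
            change = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(d)]))
            for s, e in zip(starts, ends):
                v = d[s]
                if v == 0:
                    continue
                fh.write(
                    f"{chrom}\t{cov.origin + s}\t{cov.origin + e}\t{v:g}\n"
                )


def pool_coverage(
    vectors: Sequence[CoverageVector],
) -> CoverageVector:
    """Sum replicate depth vectors (same chromosome) into one pooled vector."""
    if not vectors:
        raise ValueError("no coverage vectors to pool")
    chroms = {v.chrom for v in vectors}
    if len(chroms) > 1:
        raise ValueError(f"cannot pool across chromosomes {sorted(chroms)}")
    origin = min(v.origin for v in vectors)
    end = max(v.end for v in vectors)
    depths = np.zeros(end - origin, dtype=float)
    for v in vectors:
        depths[v.origin - origin : v.end - origin] += v.depths
    return CoverageVector(vectors[0].chrom, origin, depths)


def compute_norm_factor(
    chip: AlignmentSummary,
    control: AlignmentSummary,
    method: str = "uniquely_mapped",
) -> float:
    """Scaling factor applied to control depth to depth-match the ChIP sample.

    With ``method="uniquely_mapped"`` (the only method in scope) the factor
    is ``chip.uniquely_mapped / control.uniquely_mapped``.
    """
    if method != "uniquely_mapped":
        raise ValueError(f"unsupported normalization method {method!r}")
    if control.uniquely_mapped == 0:
        raise ValueError("control sample has zero uniquely mapped reads")
    return chip.uniquely_mapped / control.uniquely_mapped


def peak_fold_change(
    peak: MergedPeak,
    chip_cov: CoverageVector,
    ctrl_cov: CoverageVector,
    factor: float = 1.0,
    pseudocount: float = 1.0,
) -> float:
    """Normalized fold change of ChIP over control within the peak.

    ``(mean chip depth + pseudocount) / (factor * mean control depth +
    pseudocount)``; strictly positive and finite for ``pseudocount > 0``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    chip_mean = float(np.mean(chip_cov.slice(peak.start, peak.end)))
    ctrl_mean = float(np.mean(ctrl_cov.slice(peak.start, peak.end)))
    return (chip_mean + pseudocount) / (factor * ctrl_mean + pseudocount)


def weighted_peak_center(peak: MergedPeak, chip_cov: CoverageVector) -> int:
    """Coverage centroid of the ChIP signal over ``[start, end)``.

    Returns ``round(sum(pos * depth) / sum(depth))``; the interval midpoint
    when total depth is zero.  Result always lies in ``[start, end)``.
    """
    depths = chip_cov.slice(peak.start, peak.end)
    total = float(depths.sum())
    if total == 0:
        return (peak.start + peak.end) // 2
    positions = np.arange(peak.start, peak.end, dtype=float)
    center = int(round(float((positions * depths).sum() / total)))
    return min(max(center, peak.start), peak.end - 1)


def quantify_peaks(
    merged: Sequence[MergedPeak],
    chip_cov: Mapping[str, CoverageVector],
    ctrl_cov: Mapping[str, CoverageVector],
    factor: float = 1.0,
    pseudocount: float = 1.0,
) -> None:
    """Fill ``fold_change`` and ``weighted_center`` on every merged peak,
    in place."""
    for peak in merged:
        if peak.chrom not in chip_cov or peak.chrom not in ctrl_cov:
            raise ValueError(f"no coverage for chromosome {peak.chrom}")
        peak.fold_change = peak_fold_change(
            peak, chip_cov[peak.chrom], ctrl_cov[peak.chrom], factor, pseudocount
        )
        peak.weighted_center = weighted_peak_center(peak, chip_cov[peak.chrom])
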