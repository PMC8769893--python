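"""Shared fixtures: synthetic landscapes and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from consensuspeaks.core import CallerPeakSet, PeakRecord
from consensuspeaks.simulate import SimulationConfig, simulate_landscape


@pytest.fixture(scope="session")
def landscape(tmp_path_factory):
    """One default-condition landscape, written to disk once per session."""
    out = tmp_path_factory.mktemp("landscape")
    return simulate_landscape(SimulationConfig(seed=11), out)


@pytest.fixture(scope="session")
def small_landscape():
    """A cheap in-memory landscape for quick structural tests."""
    cfg = SimulationConfig(
        seed=5,
        genome_length=120_000,
        n_chroms=1,
        n_sites=30,
        callers=SimulationConfig().callers[:3],
    )
    return simulate_landscape(cfg)


def random_caller_sets(
    rng: np.random.Generator,
    n_callers: int = 4,
    n_peaks: int = 125,
    genome_length: int = 400_000,
    n_chroms: int = 2,
    width_range: tuple[int, int] = (100, 2500),
) -> list[CallerPeakSet]:
    """Unstructured random peak sets for merge stress tests."""
    sets = []
    for ci in range(n_callers):
        caller = f"c{ci}"
        peaks = []
        for i in range(n_peaks):
            chrom = f"chr{rng.integers(1, n_chroms + 1)}"
            width = int(rng.integers(*width_range))
            start = int(rng.integers(0, genome_length - width))
            peaks.append(
                PeakRecord(
                    chrom, start, start + width, f"{caller}_{i + 1}",
                    float(rng.random() * 100), ".", -1, caller,
                )
            )
        sets.append(CallerPeakSet(caller, peaks))
    return sets


def brute_force_merge(sets, gap):
    """O(n^2) transitive-closure merge oracle.

    Builds the full pairwise relation (literal overlap or center distance)
    and extracts connected components with scipy; completely independent of
    the sweep-based implementation under test.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    peaks = [p for s in sets for p in s]
    by_chrom: dict[str, list] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)

    regions = []
    for chrom, group in by_chrom.items():
        n = len(group)
        starts = np.array([p.start for p in group])
        ends = np.array([p.end for p in group])
        if gap == "given":
            adj = (starts[:, None] < ends[None, :]) & (starts[None, :] < ends[:, None])
        else:
            centers = (starts + ends) // 2
            adj = np.abs(centers[:, None] - centers[None, :]) <= gap
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        for comp in range(n_comp):
            members = [group[i] for i in np.flatnonzero(labels == comp)]
            regions.append(
                (
                    chrom,
                    min(p.start for p in members),
                    max(p.end for p in members),
                    frozenset(p.source_caller for p in members),
                    frozenset(p.name for p in members),
                )
            )
    regions.sort()
    return regions


def as_oracle_regions(merged):
    """Project MergedPeak output onto the oracle's comparison tuple."""
    out = [
        (
            m.chrom,
            m.start,
            m.end,
            m.detecting_callers,
            frozenset(n for names in m.constituents.values() for n in names),
        )
        for m in merged
    ]
    out.sort()
    return out
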