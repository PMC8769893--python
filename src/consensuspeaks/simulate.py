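"""Ground-truthed synthetic landscapes for end-to-end testing.

The generator emulates the situation the integration layer is built for:
a genome with planted transcription-factor binding sites, ChIP and control
read coverage with enrichment at the sites, and several imperfect "peak
callers" that each report a sensitivity-thinned, boundary-jittered copy of
the truth plus their own private false positives.  Because every emission
is recorded, precision and recall of any derived peak set are exactly
computable.

What it emulates, and what it does not: binding sites are non-overlapping
and enrichment is flat across a site; coverage is independent Poisson per
base (no fragment-length autocorrelation, no mappability or GC structure);
caller scores are a shared per-site strength times caller-specific
lognormal noise (so multi-caller reproducibility is real but simplistic).
These choices keep every planted quantity recoverable in closed form.

All randomness flows from one ``numpy`` Generator seeded from the config,
so a fixed config yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .core import CallerPeakSet, PeakRecord
from .motifs import PWMotif, write_motif
from .peak_io import write_narrowpeak
from .quant import AlignmentSummary, CoverageVector, write_bedgraph

__all__ = [
    "CallerProfile",
    "SimulationConfig",
    "SimulatedLandscape",
    "default_motif",
    "simulate_landscape",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Consensus of the default planted motif (12 bp, non-palindromic).
_DEFAULT_CONSENSUS = "TGCATAAGGTCA"


def default_motif(dominant: float = 0.85) -> PWMotif:
    """An informative 12-bp planted motif; the dominant base carries
    probability ``dominant`` and the rest share the remainder."""
    L = len(_DEFAULT_CONSENSUS)
    rest = (1.0 - dominant) / 3.0
    matrix = np.full((L, 4), rest)
    for i, base in enumerate(_DEFAULT_CONSENSUS):
        matrix[i, "ACGT".index(base)] = dominant
    return PWMotif("planted_motif", matrix)


@dataclass(frozen=True)
class CallerProfile:
    """Operating characteristics of one simulated peak caller."""

    name: str
    sensitivity: float = 0.85
    n_false_positives: int = 200
    jitter_sd: float = 30.0
    score_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0):
            raise ValueError(f"{self.name}: sensitivity must be in [0, 1]")
        if self.n_false_positives < 0 or self.jitter_sd < 0 or self.score_noise_sd < 0:
            raise ValueError(f"{self.name}: counts and sds must be >= 0")


def _default_callers() -> tuple[CallerProfile, ...]:
    return tuple(
        CallerProfile(name) for name in ("callerA", "callerB", "callerC", "callerD")
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic landscape.

    Defaults emulate a desk-scale transcription-factor experiment: a 2 x
    500 kb genome, 200 flat-enrichment binding sites (width ~ N(200, 40)
    bp, 5-fold enrichment over a Poisson background of mean 2 reads/base),
    the canonical motif planted at 70% of true site centers and at 10% of
    each caller's false-positive centers, and four callers at 85%
    sensitivity with 200 private false positives each.  The control sample
    is sequenced ``control_depth_multiplier`` times deeper than ChIP, so
    depth normalization is exercised for real.
    """

    seed: int = 0
    genome_length: int = 500_000
    n_chroms: int = 2
    n_sites: int = 200
    site_width_mean: float = 200.0
    site_width_sd: float = 40.0
    enrichment: float = 5.0
    background_depth: float = 2.0
    control_depth_multiplier: float = 2.0
    motif_rate: float = 0.7
    fp_motif_rate: float = 0.1
    site_strength_sd: float = 0.25
    callers: tuple[CallerProfile, ...] = field(default_factory=_default_callers)

    def __post_init__(self) -> None:
        if not (0.0 <= self.motif_rate <= 1.0 and 0.0 <= self.fp_motif_rate <= 1.0):
            raise ValueError("motif planting rates must be in [0, 1]")
        if self.enrichment <= 0 or self.background_depth <= 0:
            raise ValueError("enrichment and background depth must be > 0")
        if self.control_depth_multiplier <= 0:
            raise ValueError("control_depth_multiplier must be > 0")


@dataclass
class SimulatedLandscape:
    """In-memory result of one simulation, plus output paths if written."""

    config: SimulationConfig
    genome: dict[str, str]
    motif: PWMotif
    true_sites: list[PeakRecord]          # source_caller == "truth"
    site_has_motif: dict[str, bool]
    site_strength: dict[str, float]
    chip_coverage: dict[str, CoverageVector]
    control_coverage: dict[str, CoverageVector]
    caller_sets: dict[str, CallerPeakSet]
    caller_truth: dict[str, dict[str, str | None]]  # peak name -> site id / None
    alignment_summaries: list[AlignmentSummary]
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def site_ids(self) -> list[str]:
        return [s.name for s in self.true_sites]


def _place_sites(cfg: SimulationConfig, rng: np.random.Generator):
    """Non-overlapping site placement: one site per equal-width slot with
    uniform jitter inside the slot, keeping a guard gap between sites."""
    margin = 1000
    guard = 400
    per_chrom = [cfg.n_sites // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_sites % cfg.n_chroms):
        per_chrom[i] += 1
    max_width = cfg.site_width_mean + 4 * cfg.site_width_sd
    sites: list[tuple[str, int, int]] = []
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        n = per_chrom[ci]
        if n == 0:
            continue
        usable = cfg.genome_length - 2 * margin
        spacing = usable // n
        if spacing < max_width + guard:
            raise ValueError(
                f"infeasible packing: {n} sites of width up to {max_width:.0f} bp "
                f"do not fit in {usable} bp of {chrom}"
            )
        widths = np.clip(
            np.round(rng.normal(cfg.site_width_mean, cfg.site_width_sd, n)),
            50,
            max_width,
        ).astype(int)
        for i in range(n):
            slot_start = margin + i * spacing
            slack = spacing - widths[i] - guard
            start = slot_start + int(rng.integers(0, max(slack, 1)))
            sites.append((chrom, start, start + int(widths[i])))
    return sites


def simulate_landscape(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedLandscape:
    """Generate a full synthetic landscape; optionally write all artifacts.

    When ``out_dir`` is given, the exact dialects the readers consume are
    emitted: ``genome.fa``, ``true_sites.bed``, ``chip.bedgraph`` /
    ``control.bedgraph``, one ``<caller>.narrowPeak`` per caller,
    ``alignment_summaries.tsv``, ``truth_table.tsv`` and the planted motif
    in both motif formats.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    motif = default_motif()
    L = len(motif)

    # genome
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    genome_arrays = {
        c: rng.integers(0, 4, cfg.genome_length, dtype=np.int8) for c in chroms
    }

    # true sites
    placed = _place_sites(cfg, rng)
    true_sites: list[PeakRecord] = []
    site_has_motif: dict[str, bool] = {}
    site_strength: dict[str, float] = {}
    consensus_codes = np.array(
        ["ACGT".index(b) for b in _DEFAULT_CONSENSUS], dtype=np.int8
    )
    rc_codes = 3 - consensus_codes[::-1]

    def plant(chrom: str, center: int) -> None:
        start = center - L // 2
        codes = consensus_codes if rng.random() < 0.5 else rc_codes
        genome_arrays[chrom][start : start + L] = codes

    for i, (chrom, start, end) in enumerate(placed, start=1):
        site_id = f"site_{i}"
        true_sites.append(
            PeakRecord(chrom, start, end, site_id, 0.0, ".", -1, "truth")
        )
        has_motif = bool(rng.random() < cfg.motif_rate)
        site_has_motif[site_id] = has_motif
        if has_motif:
            plant(chrom, (start + end) // 2)
        site_strength[site_id] = float(
            cfg.enrichment * rng.lognormal(0.0, cfg.site_strength_sd)
        )

    # caller peak sets: thinned, jittered truth + private false positives
    caller_sets: dict[str, CallerPeakSet] = {}
    caller_truth: dict[str, dict[str, str | None]] = {}
    site_by_chrom: dict[str, list[PeakRecord]] = {}
    for s in true_sites:
        site_by_chrom.setdefault(s.chrom, []).append(s)

    for profile in cfg.callers:
        peaks: list[PeakRecord] = []
        origins: dict[str, str | None] = {}
        detected = rng.random(len(true_sites)) < profile.sensitivity
        for site, hit in zip(true_sites, detected):
            if not hit:
                continue
            jitter = rng.normal(0.0, profile.jitter_sd, 2)
            start = max(0, site.start + int(round(jitter[0])))
            end = min(cfg.genome_length, site.end + int(round(jitter[1])))
            if end <= start:
                start, end = site.start, site.end
            score = site_strength[site.name] * rng.lognormal(
                0.0, profile.score_noise_sd
            )
            name = f"{profile.name}_{len(peaks) + 1}"
            summit = min(max(site.center - start, 0), end - start - 1)
            peaks.append(
                PeakRecord(
                    site.chrom, start, end, name, float(score), ".",
                    summit, profile.name,
                )
            )
            origins[name] = site.name
        # false positives: uniform placement away from true sites
        n_fp = profile.n_false_positives
        fp_done = 0
        attempts = 0
        while fp_done < n_fp and attempts < 50 * n_fp:
            attempts += 1
            chrom = chroms[int(rng.integers(0, cfg.n_chroms))]
            width = int(
                np.clip(
                    round(rng.normal(cfg.site_width_mean, cfg.site_width_sd)),
                    50,
                    cfg.site_width_mean + 4 * cfg.site_width_sd,
                )
            )
            start = int(rng.integers(100, cfg.genome_length - width - 100))
            end = start + width
            near_site = any(
                s.start - 500 < end and start < s.end + 500
                for s in site_by_chrom.get(chrom, [])
            )
            if near_site:
                continue
            fp_done += 1
            if rng.random() < cfg.fp_motif_rate:
                plant(chrom, (start + end) // 2)
            score = float(rng.lognormal(0.0, 0.5))
            name = f"{profile.name}_{len(peaks) + 1}"
            peaks.append(
                PeakRecord(chrom, start, end, name, score, ".", -1, profile.name)
            )
            origins[name] = None
        if fp_done < n_fp:
            raise ValueError(
                f"could not place {n_fp} false positives for {profile.name}; "
                "genome too crowded"
            )
        caller_sets[profile.name] = CallerPeakSet(
            profile.name, peaks, "narrowpeak"
        ).sorted()
        caller_truth[profile.name] = origins

    # coverage: Poisson background with flat enrichment at sites
    chip_coverage: dict[str, CoverageVector] = {}
    control_coverage: dict[str, CoverageVector] = {}
    for chrom in chroms:
        chip_rate = np.full(cfg.genome_length, cfg.background_depth)
        for s in site_by_chrom.get(chrom, []):
            # flat enrichment: rate = background * per-site strength
            chip_rate[s.start : s.end] = cfg.background_depth * site_strength[s.name]
        chip = rng.poisson(chip_rate).astype(float)
        ctrl = rng.poisson(
            cfg.background_depth * cfg.control_depth_multiplier, cfg.genome_length
        ).astype(float)
        chip_coverage[chrom] = CoverageVector(chrom, 0, chip)
        control_coverage[chrom] = CoverageVector(chrom, 0, ctrl)

    base_reads = 10_000_000
    summaries = [
        AlignmentSummary("chip_rep1", base_reads, int(base_reads * 1.1), "chip", 1),
        AlignmentSummary(
            "control_rep1",
            int(base_reads * cfg.control_depth_multiplier),
            int(base_reads * cfg.control_depth_multiplier * 1.1),
            "control",
            1,
        ),
    ]

    genome = {
        c: "".join(_BASES[genome_arrays[c]]) for c in chroms
    }

    land = SimulatedLandscape(
        config=cfg,
        genome=genome,
        motif=motif,
        true_sites=true_sites,
        site_has_motif=site_has_motif,
        site_strength=site_strength,
        chip_coverage=chip_coverage,
        control_coverage=control_coverage,
        caller_sets=caller_sets,
        caller_truth=caller_truth,
        alignment_summaries=summaries,
    )

    if out_dir is not None:
        land.paths = _write_landscape(land, Path(out_dir))
    return land


def _write_fasta(genome: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _write_landscape(land: SimulatedLandscape, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = out_dir / "genome.fa"
    _write_fasta(land.genome, paths["genome"])

    paths["true_sites"] = out_dir / "true_sites.bed"
    with open(paths["true_sites"], "w") as fh:
        for s in land.true_sites:
            motif_flag = 1 if land.site_has_motif[s.name] else 0
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.name}\t"
                f"{land.site_strength[s.name]:.4f}\t.\t{motif_flag}\n"
            )

    paths["chip_coverage"] = out_dir / "chip.bedgraph"
    write_bedgraph(land.chip_coverage, paths["chip_coverage"])
    paths["control_coverage"] = out_dir / "control.bedgraph"
    write_bedgraph(land.control_coverage, paths["control_coverage"])

    for name, peak_set in land.caller_sets.items():
        p = out_dir / f"{name}.narrowPeak"
        write_narrowpeak(peak_set, p)
        paths[f"peaks:{name}"] = p

    paths["alignment_summaries"] = out_dir / "alignment_summaries.tsv"
    with open(paths["alignment_summaries"], "w") as fh:
        fh.write("sample_id\trole\tuniquely_mapped\ttotal_reads\treplicate\n")
        for s in land.alignment_summaries:
            fh.write(
                f"{s.sample_id}\t{s.role}\t{s.uniquely_mapped}\t"
                f"{s.total_reads}\t{s.replicate_index}\n"
            )

    paths["truth_table"] = out_dir / "truth_table.tsv"
    with open(paths["truth_table"], "w") as fh:
        fh.write("caller\tpeak_name\ttrue_site\n")
        for caller in sorted(land.caller_truth):
            for peak_name, site in sorted(land.caller_truth[caller].items()):
                fh.write(f"{caller}\t{peak_name}\t{site if site else 'FP'}\n")

    paths["motif_homer"] = out_dir / "motif.homer"
    write_motif(land.motif, paths["motif_homer"], "homer")
    paths["motif_meme"] = out_dir / "motif.meme"
    write_motif(land.motif, paths["motif_meme"], "meme")
    return paths
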