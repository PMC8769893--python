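"""One-command orchestration of the integration layer.

A :class:`RunManifest` names every input (caller peak files with their
dialects, coverage, alignment summaries, optionally genome and motif) plus
the settings table, and :func:`run_integration` executes the full chain

    merge -> quantify -> rank -> IDR fit per caller -> aggregate -> write

producing the integrated output table and sidecar reports (upset counts,
fitted IDR parameters).  The run is a pure function of the manifest
contents: no clock, no unseeded randomness, so identical manifests give
byte-identical outputs.

Only the settings-table rows relevant to this layer alter behavior
(``homer_mergePeaks`` selects the merge gap, ``fold_change_calculator``
the normalization method); every other row is parsed, validated and
recorded verbatim for provenance, never executed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import idr as idr_mod
from . import motifs as motifs_mod
from .core import MergedPeak
from .merge import merge_peaks, subset_by_caller_count, upset_counts
from .peak_io import (
    SettingsError,
    SettingsTable,
    parse_settings_table,
    read_peaks,
    write_integrated_table,
)
from .quant import (
    compute_norm_factor,
    quantify_peaks,
    read_alignment_summaries,
    read_bedgraph,
)

__all__ = ["RunManifest", "StageError", "validate_manifest", "run_integration"]

logger = logging.getLogger("consensuspeaks")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunManifest:
    """Declarative description of one integration run.

    ``caller_peaks`` maps caller label -> (path, dialect); genome and motif
    are optional and enable the motif columns of the output table when both
    are present.
    """

    caller_peaks: dict[str, tuple[str, str]]
    chip_coverage: list[str]
    control_coverage: list[str]
    alignment_summaries: str
    out_dir: str
    settings: SettingsTable = field(default_factory=SettingsTable)
    genome: str | None = None
    motif: str | None = None
    motif_dialect: str = "homer"
    gem_expand_bp: int = 100
    pseudocount: float = 1.0
    min_pairs_for_idr: int = 50

    @classmethod
    def from_paths(cls, settings_path: str | None = None, **kwargs) -> "RunManifest":
        settings = (
            parse_settings_table(settings_path) if settings_path else SettingsTable()
        )
        return cls(settings=settings, **kwargs)


def _sniff_dialect(path: str) -> str | None:
    """Best-effort dialect guess from the first data lines; None if unsure."""
    try:
        with open(path) as fh:
            header_hash = False
            for raw in fh:
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                if line.startswith("#"):
                    header_hash = True
                    continue
                if line.startswith(("track", "browser")):
                    continue
                fields = line.split("\t")
                if ":" in fields[0] and len(fields) <= 3:
                    return "gem_event"
                if header_hash and len(fields) >= 4 and not fields[1].isdigit():
                    return "homer_pos"
                if len(fields) >= 10:
                    return "narrowpeak"
                if len(fields) >= 3 and fields[1].isdigit() and fields[2].isdigit():
                    return "bed"
                return None
    except OSError:
        return None
    return None


def validate_manifest(manifest: RunManifest) -> list[str]:
    """Report-only validation: missing files, unknown settings programs,
    dialect mismatches.  Returns a list of issue strings (empty = valid)."""
    issues: list[str] = []
    paths = (
        [(f"caller {c}", p) for c, (p, _) in manifest.caller_peaks.items()]
        + [("chip coverage", p) for p in manifest.chip_coverage]
        + [("control coverage", p) for p in manifest.control_coverage]
        + [("alignment summaries", manifest.alignment_summaries)]
    )
    if manifest.genome:
        paths.append(("genome", manifest.genome))
    if manifest.motif:
        paths.append(("motif", manifest.motif))
    for label, p in paths:
        if not Path(p).exists():
            issues.append(f"missing file for {label}: {p}")
    for caller, (path, dialect) in manifest.caller_peaks.items():
        if dialect not in {"narrowpeak", "broadpeak", "bed", "homer_pos", "gem_event"}:
            issues.append(f"caller {caller}: unknown dialect {dialect!r}")
        elif Path(path).exists():
            guess = _sniff_dialect(path)
            compatible = {
                "narrowpeak": {"narrowpeak", "bed"},
                "broadpeak": {"narrowpeak", "bed"},
                "bed": {"bed", "narrowpeak"},
                "homer_pos": {"homer_pos"},
                "gem_event": {"gem_event"},
            }[dialect]
            if guess is not None and guess not in compatible:
                issues.append(
                    f"caller {caller}: file {path} looks like {guess!r}, "
                    f"declared {dialect!r}"
                )
    try:
        manifest.settings.merge_gap()
    except SettingsError as exc:
        issues.append(str(exc))
    return issues


def run_integration(manifest: RunManifest) -> dict[str, Path]:
    """Execute the full integration chain; returns the output paths.

    Outputs in ``manifest.out_dir``: ``integrated_peaks.tsv`` (ranked),
    ``upset_counts.tsv``, ``consensus_peaks.bed``, ``idr_params.json`` and,
    when genome + motif are given, ``motif_hits.bed`` and
    ``motif_distances.tsv`` plus motif columns in the main table.
    """
    issues = validate_manifest(manifest)
    if issues:
        raise StageError("validate", "; ".join(issues))
    out_dir = Path(manifest.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # ---- read caller peaks
    try:
        caller_sets = {
            caller: read_peaks(path, caller, dialect, manifest.gem_expand_bp)
            for caller, (path, dialect) in sorted(manifest.caller_peaks.items())
        }
    except Exception as exc:
        raise StageError("read_peaks", str(exc)) from exc
    for caller, ps in caller_sets.items():
        logger.info("stage=read_peaks caller=%s n_peaks=%d", caller, len(ps))

    # ---- merge
    gap = manifest.settings.merge_gap()
    merged = merge_peaks(list(caller_sets.values()), gap=gap)
    logger.info(
        "stage=merge gap=%s n_union=%d n_consensus=%d",
        gap,
        len(merged),
        len(subset_by_caller_count(merged, len(caller_sets), len(caller_sets))),
    )

    # ---- quantify
    try:
        summaries = read_alignment_summaries(manifest.alignment_summaries)
        chip_sums = [s for s in summaries if s.role == "chip"]
        ctrl_sums = [s for s in summaries if s.role == "control"]
        if not chip_sums or not ctrl_sums:
            raise ValueError("need at least one chip and one control summary")
        # replicates pool by summing read counts and depth vectors
        chip_total = sum(s.uniquely_mapped for s in chip_sums)
        ctrl_total = sum(s.uniquely_mapped for s in ctrl_sums)
        fc_args = manifest.settings["fold_change_calculator"].split()
        method = "uniquely_mapped"
        if "--normfactor" in fc_args:
            method = fc_args[fc_args.index("--normfactor") + 1]
        factor = compute_norm_factor(
            _pooled_summary(chip_sums, chip_total, "chip"),
            _pooled_summary(ctrl_sums, ctrl_total, "control"),
            method=method,
        )
        chip_cov = _read_pooled_coverage(manifest.chip_coverage)
        ctrl_cov = _read_pooled_coverage(manifest.control_coverage)
        quantify_peaks(merged, chip_cov, ctrl_cov, factor, manifest.pseudocount)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("quantify", str(exc)) from exc
    logger.info("stage=quantify factor=%.4f n_peaks=%d", factor, len(merged))

    # ---- rank, per-caller IDR, aggregate
    ranked = idr_mod.rank_union(merged)
    params_report: dict[str, dict] = {}
    per_caller_idr: dict[str, dict[str, float]] = {}
    for caller, ps in sorted(caller_sets.items()):
        scores = {p.name: p.score for p in ps}
        try:
            pairs = idr_mod.pair_caller_with_union(caller, ranked, scores)
            if pairs.n_matched < manifest.min_pairs_for_idr:
                raise ValueError(
                    f"only {pairs.n_matched} matched pairs "
                    f"(< {manifest.min_pairs_for_idr})"
                )
            params, _local, global_idr = idr_mod.fit_idr(pairs)
        except Exception as exc:
            raise StageError(f"idr:{caller}", str(exc)) from exc
        matched_ids = [
            pid for pid, m in zip(pairs.peak_ids, pairs.matched_mask) if m
        ]
        per_caller_idr[caller] = dict(zip(matched_ids, global_idr))
        params_report[caller] = {
            "p": params.p,
            "rho": params.rho,
            "mu": params.mu,
            "sigma": params.sigma,
            "n_matched": pairs.n_matched,
            "score_source": "caller score column (max over constituents)",
        }
        logger.info(
            "stage=idr caller=%s n_matched=%d p=%.3f rho=%.3f",
            caller, pairs.n_matched, params.p, params.rho,
        )
    idr_mod.aggregate_idr(ranked, per_caller_idr)

    # ---- optional motif stage
    extra_columns = None
    motif_paths: dict[str, Path] = {}
    if manifest.genome and manifest.motif:
        try:
            import pyfaidx

            genome = pyfaidx.Fasta(manifest.genome)
            motif = motifs_mod.read_motif(manifest.motif, manifest.motif_dialect)
            hits = motifs_mod.scan_peaks(ranked, genome, motif, window="given")
            distances = motifs_mod.motif_position_bias(ranked, hits)
            pct = motifs_mod.peak_motif_percentage(ranked, hits)
        except Exception as exc:
            raise StageError("motif", str(exc)) from exc
        hit_counts: dict[str, int] = {}
        for h in hits:
            hit_counts[h.peak_id] = hit_counts.get(h.peak_id, 0) + 1
        extra_columns = {
            "motif_hits": {m.peak_id: hit_counts.get(m.peak_id, 0) for m in ranked},
            "motif_distance": distances,
        }
        motif_paths["motif_hits"] = out_dir / "motif_hits.bed"
        with open(motif_paths["motif_hits"], "w") as fh:
            for h in hits:
                fh.write(
                    f"{h.chrom}\t{h.position}\t{h.position + len(motif)}\t"
                    f"{h.peak_id}\t{h.score:.4f}\t{h.strand}\n"
                )
        motif_paths["motif_distances"] = out_dir / "motif_distances.tsv"
        with open(motif_paths["motif_distances"], "w") as fh:
            fh.write("peak_id\tdistance\n")
            for pid in sorted(distances):
                fh.write(f"{pid}\t{distances[pid]}\n")
        logger.info(
            "stage=motif n_hits=%d peak_motif_pct=%.1f", len(hits), pct
        )

    # ---- write outputs
    callers = sorted(caller_sets)
    paths = {"integrated_table": out_dir / "integrated_peaks.tsv"}
    write_integrated_table(
        ranked, paths["integrated_table"], callers=callers,
        extra_columns=extra_columns,
    )
    paths["upset_counts"] = out_dir / "upset_counts.tsv"
    with open(paths["upset_counts"], "w") as fh:
        fh.write("callers\tcount\n")
        for combo, n in upset_counts(ranked).to_rows():
            fh.write(f"{combo}\t{n}\n")
    paths["consensus"] = out_dir / "consensus_peaks.bed"
    with open(paths["consensus"], "w") as fh:
        for m in subset_by_caller_count(ranked, len(callers), len(callers)):
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.peak_id}\n")
    paths["idr_params"] = out_dir / "idr_params.json"
    with open(paths["idr_params"], "w") as fh:
        json.dump(params_report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths.update(motif_paths)
    logger.info("stage=write out_dir=%s n_rows=%d", out_dir, len(ranked))
    return paths


def _pooled_summary(summaries, total, role):
    from .quant import AlignmentSummary

    return AlignmentSummary(
        sample_id=f"pooled_{role}",
        uniquely_mapped=total,
        total_reads=max(total, max(s.total_reads for s in summaries)),
        role=role,
    )


def _read_pooled_coverage(paths: list[str]):
    from .quant import pool_coverage

    per_chrom: dict[str, list] = {}
    for p in paths:
        for chrom, vec in read_bedgraph(p).items():
            per_chrom.setdefault(chrom, []).append(vec)
    return {chrom: pool_coverage(vecs) for chrom, vecs in per_chrom.items()}
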