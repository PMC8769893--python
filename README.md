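# consensuspeaks

Multi-caller ChIP-seq peak integration: merge the peak sets of several
independent peak callers into one provenance-annotated **union peak set**,
score every union peak with an aggregated multi-caller **irreproducible
discovery rate (IDR)** and a depth-normalized **fold change** with a
coverage-weighted peak center, and slide freely along the gradient from
the union set (all peaks called by any caller) to the **consensus set**
(peaks called concomitantly by every caller) — without reprocessing
anything.

## Who this is for

Peak callers have distinct selectivity/specificity characteristics, and
their outputs seldom overlap cleanly on the same data. Analysts who run
several callers (e.g. a Poisson-model caller, a motif-aware event caller,
a window-clustering broad-peak caller and a pileup-AUC caller) face an
integration problem: which regions are real, and how confident is each
one? This package implements the integration layer: everything after the
callers have run and before biological interpretation.

## The model

**Union merging.** Peaks from all callers are clustered per chromosome by
single-linkage (transitive closure) under one of two gap rules — literal
overlap (≥ 1 bp shared) or center distance (|c_A − c_B| ≤ d) — and each
cluster becomes one region spanning min(start)…max(end), annotated with
the set of detecting callers.

**Ranking.** The union set is ranked by (1) number of detecting callers,
(2) fold change of ChIP signal over the depth-matched control, where the
control is scaled by the ratio of uniquely mapped read counts.

**Multi-caller IDR.** The IDR framework compares exactly two ranked
lists with a two-component Gaussian copula mixture on rank-transformed
pseudo-values z:

    reproducible:    (z₁, z₂) ~ N((μ, μ), σ²[[1, ρ], [ρ, 1]]),  weight p
    irreproducible:  (z₁, z₂) ~ N((0, 0), I),                    weight 1 − p

Each caller's peak set is paired with the union set as its "replicate";
the local idr of a pair is the posterior probability of the
irreproducible component, and the global IDR at rank i is the running
mean of the sorted local idrs. Per peak, the detecting callers' global
IDRs are copied onto the union set as −log₁₀ IDR values (0 for callers
that missed the peak), summed to S, and converted to a single final rate

    final_idr = 10^(−S).

**Peak-set evaluation.** Directed PWM scanning (log₂-odds against
background, both strands) yields the peak-motif percentage (fraction of
peaks with ≥ 1 motif hit) and the motif position bias (signed distance
from each peak's coverage-weighted center to the nearest motif midpoint).
Two peak sets are compared by merged-region counts: shared / (only_A +
only_B + shared) is the Jaccard index; a replicate-consistency filter
keeps regions found in ≥ k replicates with ≥ f-fold enrichment over a
negative control.

## Worked example

Everything is testable without downloads: the built-in generator plants
binding sites, motifs, coverage and imperfect caller outputs with known
ground truth.

```python
from consensuspeaks import (SimulationConfig, simulate_landscape,
                            RunManifest, run_integration)

land = simulate_landscape(SimulationConfig(seed=7), "sim/")
paths = run_integration(RunManifest(
    caller_peaks={c: (str(land.paths[f"peaks:{c}"]), "narrowpeak")
                  for c in land.caller_sets},
    chip_coverage=[str(land.paths["chip_coverage"])],
    control_coverage=[str(land.paths["control_coverage"])],
    alignment_summaries=str(land.paths["alignment_summaries"]),
    out_dir="out/",
))
```

The integrated table (`out/integrated_peaks.tsv`) has one row per union
peak. For seed 7 the top of the ranking looks like:

```
peak_id   chrom  start   end     width  caller_count  callers                          fold_change  weighted_center  ...  final_idr
peak_679  chr2   280551  280863  312    4             callerA,callerB,callerC,callerD  5.52108      280726                6.15737e-16
peak_59   chr1   64898   65254   356    4             callerA,callerB,callerC,callerD  4.95329      65064                 3.33635e-16
```

Reading: both peaks were found by all four callers with ~5-fold
enrichment (the planted truth is 5-fold), and their final IDR is
vanishingly small — every caller reproduces them. Further down the table,
peaks seen by a single caller carry final IDR near 1. In this run the
mean final IDR was 4.6 × 10⁻⁷ for 4-caller peaks versus 0.40 for
1-caller peaks. Subsetting by `caller_count >= k` walks the
union-to-consensus gradient; `upset_counts.tsv` holds the combination
counts and `idr_params.json` the fitted mixture parameters per caller.

The same pipeline is available from the shell:

```sh
consensuspeaks simulate --seed 7 --out sim/
consensuspeaks run --input callerA=sim/callerA.narrowPeak ... \
    --chip-coverage sim/chip.bedgraph --control-coverage sim/control.bedgraph \
    --summaries sim/alignment_summaries.tsv --out out/
```

## Layout

- `consensuspeaks.peak_io` — narrowPeak/broadPeak/BED, 1-based position
  files, point-event tables, settings tables, the integrated output table
- `consensuspeaks.merge` — union merging, upset counts, k-of-n subsetting
- `consensuspeaks.quant` — norm factor, fold change, weighted peak center
- `consensuspeaks.idr` — ranking, caller-vs-union pairing, the copula
  mixture fit, final-IDR aggregation
- `consensuspeaks.motifs` — PWM I/O (MEME/HOMER dialects), scanning,
  peak-motif percentage, position bias
- `consensuspeaks.compare` — pairwise overlap, Jaccard, replicate filter
- `consensuspeaks.simulate` — ground-truthed synthetic landscapes
- `consensuspeaks.workflow` / `consensuspeaks.cli` — manifest-driven runs

See `docs/methods.md` for the modelling choices and their rationale.
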