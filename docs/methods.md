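# Methods

This note documents the models and procedures implemented in
`consensuspeaks`, the parameters that matter, the numerical choices, and
what the synthetic test conditions do and do not demonstrate.

## Coordinates and formats

All intervals are internally 0-based half-open (BED convention). The
1-based inclusive position-file dialect is shifted on read
(`start − 1, end`) and shifted back on write; point-event tables
(`chrom:position`) are expanded to `[pos − w, pos + w)` with the summit
kept at the event position (start clamped at 0 near chromosome ends).
The expansion half-width `w` (default 100 bp) is a free parameter:
merging needs intervals, and no canonical width exists for point calls,
so it is exposed rather than fixed. Peak names missing from input are
auto-generated as `<caller>_<ordinal>` so that provenance joins are
always well defined.

The settings table is a two-column (program, argument-string) record
with a fixed 19-program vocabulary; unknown or duplicated program names
are rejected, programs absent from a user table take the bundled
defaults, and any run of whitespace separates the program from its
verbatim argument string. Only two rows alter this package's behavior —
the merge row (a `-d <int>` argument selects center-distance clustering)
and the fold-change row (normalization method); all other rows are
validated and recorded for provenance only, since this package never
executes external programs.

## Union merging

Two gap rules are provided because both are used in practice: literal
overlap (default; two peaks cluster when they share ≥ 1 bp) and center
distance (cluster when |center_A − center_B| ≤ d, center =
floor((start+end)/2); typical windows are d = 1500 for overlapping
replicates of point-binding data and d = 2000 for cross-technique
comparisons). Clustering is single-linkage (transitive closure): if A
merges with B and B with C, all three form one region even if A and C
alone would not. This matches the span semantics (region start = min,
end = max over constituents). Strand is ignored — ChIP enrichment is
unstranded.

Implementation: per chromosome, a sorted sweep (literal mode: a peak
joins the open cluster iff its start is below the running max end;
center mode: sort centers and split where consecutive centers are > d
apart). Both sweeps compute the exact transitive closure on a line, and
the test suite verifies equivalence against an O(n²)
connected-components oracle in both modes. Output order is (chromosome
in natural order, so chr2 < chr10, then start, then end).

## Fold change and weighted peak center

The control sample is depth-matched to the ChIP sample by the ratio of
uniquely mapped read counts (factor = chip/control); fold change over a
peak is

    (mean ChIP depth + c) / (factor × mean control depth + c)

with pseudocount c (default 1.0) keeping empty-control peaks finite.
Mean per-base depth (not read counts) makes the statistic
width-independent. The pseudocount shrinks fold changes toward 1 in
low-coverage regions; recovery measurements in the tests use c = 0.1 so
the planted enrichment is read off with < 5 % bias at background depth 2.

The weighted peak center is the coverage centroid
round(Σ pos·depth / Σ depth) over the peak, independent of any
caller-reported summit; zero-coverage peaks fall back to the interval
midpoint, and the result is clamped into [start, end). The centroid is
translation-equivariant and sits on the axis of symmetric profiles
(± 1 bp rounding), both asserted as properties. It is isolated behind
one function so an alternative weighting could be swapped in.

Multiple ChIP or control replicates are pooled by summing depth vectors
and read counts before quantification.

## The reproducibility (IDR) model

The copula mixture treats a pair of score lists as draws from

    reproducible:    (z₁, z₂) ~ N((μ, μ), σ²[[1, ρ],[ρ, 1]])   weight p
    irreproducible:  (z₁, z₂) ~ N(0, I)                         weight 1 − p

on pseudo-values z = G⁻¹(u), where u are empirical quantiles (average
ranks / (n + 1)) and G is the mixture's own marginal CDF. Because only
ranks enter, any strictly monotone transform of either score list gives
an identical fit (asserted as a property).

**Estimation.** One EM step (exact M-step: the constrained MLE of the
exchangeable bivariate normal is μ = weighted mean of (z₁ + z₂)/2,
σ² = weighted mean of the two squared deviations, ρ = weighted
cross-moment / σ²) alternates with a pseudo-value refresh until the
parameters stabilize (tolerance 1e-7 per round, at most 3000 rounds),
followed by a plain EM run at fixed pseudo-values whose log-likelihood
trace is non-decreasing by EM theory and is exposed as
`loglik_trace_`. At a joint fixed point the polish is a no-op, so the
reported parameters satisfy both the copula self-consistency and EM
stationarity. Running the *inner* EM to convergence between refreshes
was tried and rejected: it converges to a biased fixed point
(overestimating p by ~0.1 on self-simulated data), while the
step-wise alternation recovers the mixing proportion to ~0.01.

Initialization is fixed (p = 0.5, ρ = 0.5, μ = 1, σ = 1) and nothing is
random, so fits are bit-reproducible run to run. Parameter clamps:
p ∈ [1e-4, 1 − 1e-4], ρ ∈ [0, 1 − 1e-4], μ ≥ 0, σ ≥ 1e-3. Degenerate
inputs (constant scores on either side, or fewer than 50 pairs) are
rejected.

**Identifiability guard.** On independent inputs the likelihood admits a
degenerate solution in which an uncorrelated, low-variance "reproducible"
component swallows the central mass, making everything look reproducible.
When the fitted ρ falls below 0.05 the reproducible component carries no
dependence and the mixture is a relabeling of noise; the model then
reports every pair irreproducible (local idr 1). This gives the correct
null behavior (median global IDR 1 on independent scores) without
affecting genuine fits, whose ρ is far larger.

**Local and global IDR.** Local idr is the posterior probability of the
irreproducible component; global IDR at rank i is the running mean of
the sorted local idrs up to i — non-decreasing along the ranking by
construction.

## Multi-caller aggregation

The IDR framework compares exactly two lists, so each caller is paired
with the union set as its "replicate": the caller-side score of a union
peak is the maximum constituent score that caller assigned inside the
merged region (worst-rank placeholder when the caller missed it), and
the union-side score is the peak's position in the union ranking
(by detecting-caller count, then fold change) — the union is ranked
precisely before the IDR stage so that rank is meaningful. Each fit uses
only the matched pairs.

Per peak, detecting callers contribute −log₁₀(global IDR) (IDR clamped
below at 1e-10 before the log); callers that missed the peak contribute
0, i.e. IDR 1 — absence of detection is absence of evidence, not
counter-evidence. The sum S converts to the final per-peak rate
`final_idr = 10^(−S)`, clamped to [0, 1]: the inverse of the log-sum,
the only conversion consistent with summing −log₁₀ values. Aggregation
is permutation-invariant in caller order.

Which score column a caller contributes is deliberately open — any
numeric score works because the fit is rank-based — and the choice is
recorded in the JSON sidecar of each run.

## Motif analysis

PWMs are read from the MEME minimal format or the `>`-headed
probability-row dialect (whose header carries a log-odds threshold).
Rows are regularized with a 1e-4 pseudocount only when near-zero entries
are present, so re-reading an already-regularized matrix is exact to
file precision. Motifs without a stored threshold get 80 % of their
maximal achievable log-odds score — a deterministic, motif-relative
default.

Scanning computes log₂(motif probability / background) summed over
positions, at every offset on both strands (the reverse strand uses the
reverse-complemented score matrix, so positions always refer to the
forward reference). Ambiguous bases (N) contribute 0, i.e. score as
background — hard-masked repeats are thereby effectively excluded, and
soft-masked (lowercase) sequence is scanned as uppercase. A hit is any
window at or above threshold; its midpoint is position + floor(L/2).

Peak-motif percentage is 100 × |peaks with ≥ 1 hit| / |peaks|. Motif
position bias reports, per peak with hits, (midpoint of nearest hit) −
weighted center, nearest by |distance| with ties to the + strand then
leftmost; peaks without hits are excluded. Statistical testing on the
distance distributions is left to downstream analysis.

## Set comparison

Pairwise overlap merges the two sets under the given gap rule and
classifies regions by provenance; the Jaccard index is computed on
merged-region counts, not base pairs, because peak-set agreement is
conventionally reported as a percentage of peaks. The
replicate-consistency filter merges replicates (default center-distance
1500 bp), then keeps regions detected in ≥ k replicates whose maximum
constituent fold change over the negative control is ≥ f (defaults
mirror the common "≥ 2 replicates, ≥ 4-fold over IgG" rule). Maximum —
rather than mean — across replicates was chosen so that one confident
replicate cannot be vetoed by a weakly covered one.

## Synthetic study conditions

The generator emulates a desk-scale transcription-factor experiment:

| parameter | default | meaning |
|---|---|---|
| genome | 2 × 500 kb | uniform random sequence |
| n_sites | 200 | non-overlapping planted sites, width ~ N(200, 40²) bp |
| enrichment | 5 | flat ChIP rate multiplier across a site |
| background_depth | 2 reads/base | Poisson coverage mean |
| control_depth_multiplier | 2 | control sequenced 2× deeper, so depth normalization is exercised (norm factor 0.5) |
| motif_rate | 0.7 | consensus planted at site centers (random strand) |
| fp_motif_rate | 0.1 | planting rate at false-positive centers |
| callers | 4 | sensitivity 0.85, 200 private false positives, boundary jitter sd 30 bp, lognormal score noise sd 0.25 |

Caller scores are a shared per-site strength (enrichment × lognormal,
sd 0.25) times caller-specific lognormal noise, so scores of true sites
are correlated across callers — the reproducible component the IDR model
estimates — while false positives are caller-private with low scores.

What the generator does **not** emulate: fragment-length
autocorrelation, mappability/GC structure, read-level noise, overlapping
or composite sites, broad-mark peak shapes. Tests passing on these
conditions demonstrate the correctness of the integration arithmetic and
the qualitative behavior of the scores (consensus peaks get small final
IDR, the consensus subset enriches for the motif, the union maximizes
recall); they are not a benchmark of real-data performance.

Determinism: all randomness flows from one seeded generator; identical
configs give byte-identical output files, and the integration run is a
pure function of its manifest (no clock, no unseeded randomness).

## Problem sizes in the test suite

The suite exercises merges up to 500 peaks (against the quadratic
oracle, 20 seeds), mixture fits at n = 10,000 (10 seeds), and motif
scans over 500 × 200 bp peaks; the acceptance script runs the full chain
on the default 1 Mb landscape. These sizes were chosen so every check
runs comfortably on a laptop while keeping sampling error far below the
asserted tolerances.

## Known limitations

- The center-distance merge rule uses peak centers only; two very wide
  peaks whose centers are > d apart do not merge even if they overlap.
- The final-IDR conversion treats per-caller IDRs as independent
  evidence; correlated caller errors (e.g. shared alignment artifacts)
  will overstate confidence.
- The identifiability guard is a hard threshold on ρ; data with genuine
  but extremely weak dependence (ρ < 0.05) is reported as fully
  irreproducible.
- Fold change assumes the provided coverage vectors span every peak;
  peaks outside the covered extent raise rather than truncate.
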