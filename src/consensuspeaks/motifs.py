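"""Directed PWM motif search over peak sequences.

A position probability matrix is scanned against both strands of every
peak window; a hit is any offset whose log-odds score (log2 of motif
probability over background, summed over positions) reaches the motif's
threshold.  Ambiguous bases (N) contribute 0, i.e. score as background.
Soft-masked (lowercase) sequence is scanned as uppercase; hard-masked (N)
sequence is effectively excluded.

From the hits two peak-set evaluation metrics are derived: the
peak-motif percentage (fraction of peaks with at least one hit) and the
motif position bias (signed distance from each peak's weighted center to
the midpoint of the nearest motif instance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import MergedPeak

__all__ = [
    "PWMotif",
    "MotifHit",
    "read_motif",
    "write_motif",
    "scan_sequence",
    "scan_peaks",
    "peak_motif_percentage",
    "motif_position_bias",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_PSEUDOCOUNT = 1e-4


@dataclass
class PWMotif:
    """Position probability matrix over (A, C, G, T) with background model.

    Rows are regularized with a small pseudocount and renormalized on
    construction, so log-odds scores are always finite.
    """

    name: str
    matrix: np.ndarray          # L x 4 probabilities
    background: np.ndarray | None = None  # 4 probabilities, uniform default
    log_odds_threshold: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("motif matrix must be L x 4")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"motif {self.name!r}: row {bad} sums to {sums[bad]:.4f}, not 1"
            )
        # regularize only when near-zero entries are present, so reading an
        # already-regularized matrix is a no-op and round trips are exact to
        # file precision
        if self.matrix.min() < 0.5 * _PSEUDOCOUNT:
            self.matrix = self.matrix + _PSEUDOCOUNT
        self.matrix = self.matrix / self.matrix.sum(axis=1, keepdims=True)
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if abs(float(self.background.sum()) - 1.0) > 1e-6:
            raise ValueError("background must sum to 1")
        if np.any(self.background <= 0):
            raise ValueError("background probabilities must be positive")
        if self.log_odds_threshold is None:
            self.log_odds_threshold = 0.8 * self.max_score

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 4 log2(motif / background) scoring matrix."""
        return np.log2(self.matrix / self.background)

    @property
    def max_score(self) -> float:
        """Log-odds score of the consensus sequence."""
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        """Highest-probability base at each position."""
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWMotif":
        rc = self.matrix[::-1, ::-1].copy()
        return PWMotif(
            self.name, rc, self.background[::-1].copy(), self.log_odds_threshold
        )


@dataclass(frozen=True)
class MotifHit:
    """One motif instance on a peak's chromosome.

    ``position`` is the 0-based start of the instance (always on the
    forward reference, whichever strand matched); ``midpoint`` is
    ``position + floor(L / 2)``.
    """

    peak_id: str
    chrom: str
    position: int
    strand: str
    score: float
    midpoint: int


# --------------------------------------------------------------------------
# motif format I/O
# --------------------------------------------------------------------------

def _read_meme(path: Path, name: str | None) -> PWMotif:
    """MEME minimal motif format: letter-probability matrix block."""
    rows: list[list[float]] = []
    motif_name = name
    background = None
    in_matrix = False
    with open(path) as fh:
        lines = fh.readlines()
    for i, raw in enumerate(lines):
        line = raw.strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if motif_name is None and len(parts) > 1:
                motif_name = parts[-1] if len(parts) > 2 else parts[1]
            in_matrix = False
        elif line.startswith("Background letter frequencies"):
            freq_line = lines[i + 1].split()
            background = np.array(
                [float(freq_line[freq_line.index(b) + 1]) for b in _BASES]
            )
        elif line.startswith("letter-probability matrix"):
            in_matrix = True
        elif in_matrix and line:
            fields = line.split()
            if len(fields) != 4:
                if rows:
                    in_matrix = False
                    continue
                raise ValueError(
                    f"{path}: matrix row has {len(fields)} columns, expected 4"
                )
            rows.append([float(f) for f in fields])
        elif in_matrix and not line:
            in_matrix = False
    if not rows:
        raise ValueError(f"{path}: no letter-probability matrix found")
    return PWMotif(motif_name or "motif", np.array(rows), background, None)


def _read_homer(path: Path, name: str | None) -> PWMotif:
    """HOMER motif format: '>consensus<TAB>name<TAB>threshold' header
    followed by per-position A C G T probability rows."""
    rows: list[list[float]] = []
    motif_name = name
    threshold = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if rows:
                    break  # only the first motif of a multi-motif file
                fields = line[1:].split("\t")
                if motif_name is None and len(fields) > 1:
                    motif_name = fields[1]
                if len(fields) > 2:
                    threshold = float(fields[2])
            else:
                fields = line.split()
                if len(fields) != 4:
                    raise ValueError(
                        f"{path}: probability row has {len(fields)} columns, expected 4"
                    )
                rows.append([float(f) for f in fields])
    if not rows:
        raise ValueError(f"{path}: no probability rows found")
    return PWMotif(motif_name or "motif", np.array(rows), None, threshold)


def read_motif(
    path: str | Path, dialect: str, name: str | None = None
) -> PWMotif:
    """Read a motif from MEME minimal or HOMER motif format.

    HOMER headers carry a log-odds threshold, which is stored; MEME motifs
    get a default threshold of 80% of the maximal achievable score.
    """
    path = Path(path)
    if dialect == "meme":
        return _read_meme(path, name)
    if dialect == "homer":
        return _read_homer(path, name)
    raise ValueError(f"unknown motif dialect {dialect!r}")


def write_motif(motif: PWMotif, path: str | Path, dialect: str) -> None:
    """Write a motif in MEME minimal or HOMER motif format."""
    path = Path(path)
    if dialect == "homer":
        with open(path, "w") as fh:
            fh.write(
                f">{motif.consensus}\t{motif.name}\t{motif.log_odds_threshold:.6g}\n"
            )
            for row in motif.matrix:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")
    elif dialect == "meme":
        bg = motif.background
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
            fh.write("Background letter frequencies\n")
            fh.write(
                " ".join(f"{b} {bg[i]:.5f}" for i, b in enumerate(_BASES)) + "\n\n"
            )
            fh.write(f"MOTIF {motif.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(motif)} "
                f"nsites= 20 E= 0\n"
            )
            for row in motif.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
    else:
        raise ValueError(f"unknown motif dialect {dialect!r}")


# --------------------------------------------------------------------------
# scanning
# --------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    """Map a sequence to indices 0-3 (ACGT) with 4 for any other base."""
    table = np.full(256, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        table[ord(base)] = idx
        table[ord(base.lower())] = idx
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _strand_scores(codes: np.ndarray, scores5: np.ndarray) -> np.ndarray:
    """Log-odds score of every window start for one strand's score matrix.

    ``scores5`` is L x 5 with the N column equal to 0.
    """
    L = scores5.shape[0]
    n_windows = len(codes) - L + 1
    if n_windows <= 0:
        return np.empty(0)
    out = np.zeros(n_windows)
    for j in range(L):
        out += scores5[j, codes[j : j + n_windows]]
    return out


def scan_sequence(
    seq: str, motif: PWMotif, threshold: float | None = None
) -> list[tuple[int, str, float]]:
    """Scan one sequence on both strands.

    Returns (offset, strand, score) triples for every window whose score
    reaches the threshold; the offset is always the window's 0-based start
    on the forward sequence.
    """
    if threshold is None:
        threshold = motif.log_odds_threshold
    L = len(motif)
    if len(seq) < L:
        return []
    codes = _encode(seq)
    lo = motif.log_odds
    fwd5 = np.zeros((L, 5))
    fwd5[:, :4] = lo
    rev5 = np.zeros((L, 5))
    rev5[:, :4] = lo[::-1, ::-1]  # reverse-complement score matrix

    hits: list[tuple[int, str, float]] = []
    for strand, mat in (("+", fwd5), ("-", rev5)):
        scores = _strand_scores(codes, mat)
        for offset in np.flatnonzero(scores >= threshold):
            hits.append((int(offset), strand, float(scores[offset])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def scan_peaks(
    peaks: Sequence[MergedPeak],
    genome: Mapping[str, str],
    motif: PWMotif,
    window: str | int = "given",
    threshold: float | None = None,
) -> list[MotifHit]:
    """Scan every peak window for motif instances on both strands.

    Parameters
    ----------
    peaks
        Merged peaks to scan.
    genome
        Mapping chromosome -> sequence (a dict, or a ``pyfaidx.Fasta``-like
        object whose values stringify to sequence).
    motif
        The PWM to search for.
    window
        ``"given"`` scans the full peak span; an integer scans a window of
        that width centered on the weighted peak center (requires
        ``weighted_center`` to be set).
    threshold
        Overrides the motif's stored log-odds threshold.
    """
    missing = sorted(
        {p.chrom for p in peaks if not _has_chrom(genome, p.chrom)}
    )
    if missing:
        raise ValueError(f"chromosomes absent from genome: {', '.join(missing)}")
    L = len(motif)
    half_mid = L // 2
    hits: list[MotifHit] = []
    for peak in peaks:
        if window == "given":
            start, end = peak.start, peak.end
        else:
            width = int(window)
            if peak.weighted_center is None:
                raise ValueError(
                    f"peak {peak.peak_id}: fixed-width window needs weighted_center"
                )
            start = max(0, peak.weighted_center - width // 2)
            end = start + width
        seq = _fetch(genome, peak.chrom, start, end)
        for offset, strand, score in scan_sequence(seq, motif, threshold):
            pos = start + offset
            hits.append(
                MotifHit(
                    peak_id=peak.peak_id,
                    chrom=peak.chrom,
                    position=pos,
                    strand=strand,
                    score=score,
                    midpoint=pos + half_mid,
                )
            )
    return hits


def _has_chrom(genome, chrom: str) -> bool:
    try:
        return chrom in genome
    except TypeError:
        return False


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    seq = genome[chrom]
    piece = seq[start:end]
    return str(piece).upper()


# --------------------------------------------------------------------------
# peak-set metrics
# --------------------------------------------------------------------------

def peak_motif_percentage(
    peaks: Sequence[MergedPeak], hits: Iterable[MotifHit]
) -> float:
    """Percentage of peaks with at least one motif hit, in [0, 100]."""
    if not peaks:
        raise ValueError("empty peak collection")
    peak_ids = {p.peak_id for p in peaks}
    with_hit = {h.peak_id for h in hits if h.peak_id in peak_ids}
    return 100.0 * len(with_hit) / len(peaks)


def motif_position_bias(
    peaks: Sequence[MergedPeak], hits: Iterable[MotifHit]
) -> dict[str, int]:
    """Signed distance from each peak's weighted center to the midpoint of
    its nearest motif instance.

    Peaks without hits are excluded.  Nearest means minimal |distance|;
    ties prefer the + strand hit, then the leftmost.
    """
    by_peak: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_peak.setdefault(h.peak_id, []).append(h)
    out: dict[str, int] = {}
    for peak in peaks:
        peak_hits = by_peak.get(peak.peak_id)
        if not peak_hits:
            continue
        if peak.weighted_center is None:
            raise ValueError(
                f"peak {peak.peak_id} has motif hits but no weighted center"
            )
        best = min(
            peak_hits,
            key=lambda h: (
                abs(h.midpoint - peak.weighted_center),
                0 if h.strand == "+" else 1,
                h.position,
            ),
        )
        out[peak.peak_id] = best.midpoint - peak.weighted_center
    return out
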