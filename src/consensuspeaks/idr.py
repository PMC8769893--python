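"""Reproducibility scoring of union peaks against each caller.

The irreproducible discovery rate (IDR) framework models a pair of ranked
score lists as a two-component mixture on rank-transformed pseudo-values:
a reproducible component, bivariate normal with mean (mu, mu), variance
sigma^2 and correlation rho, and an irreproducible component, standard
bivariate normal with zero correlation.  The local idr of a pair is the
posterior probability of the irreproducible component; the global IDR at
rank i is the running mean of the sorted local idr values up to i
(monotone non-decreasing in rank).

The framework compares exactly two ranked lists.  Here each caller's peak
set is paired with the union peak set as its "replicate": the caller-side
score of a union peak is the best constituent score that caller assigned
within the merged region (a worst-rank placeholder when the caller missed
the peak), and the union-side score is the peak's position in the union
ranking (by detecting-caller count, then fold change).  Fitting each
caller against the union yields one -log10 IDR per caller per detected
peak; summing these over callers and converting back,
``final_idr = 10**(-S)``, gives the single aggregated per-peak rate.
Undetected callers contribute 0 to the sum (equivalently IDR 1), so
evidence only accrues from callers that saw the peak.

The fit is deterministic: fixed initialization (p=0.5, rho=0.5, mu=1,
sigma=1), no randomness, so identical inputs give identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import MergedPeak, chrom_sort_key

__all__ = [
    "IdrModelParams",
    "PairedScores",
    "IdrMixtureModel",
    "UNDETECTED_SCORE",
    "pair_caller_with_union",
    "fit_idr",
    "aggregate_idr",
    "rank_union",
]

#: Worst-rank placeholder stored in ``score_a`` for union peaks the caller
#: did not detect.
UNDETECTED_SCORE = -math.inf


@dataclass(frozen=True)
class IdrModelParams:
    """Fitted parameters of the two-component reproducibility mixture."""

    p: float      # mixing proportion of the reproducible component
    rho: float    # correlation of the reproducible component
    mu: float     # mean shift of the reproducible component
    sigma: float  # standard deviation of the reproducible component

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"p must be in (0, 1), got {self.p}")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.mu < 0.0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if self.sigma <= 0.0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass
class PairedScores:
    """Per-union-peak score pairs for one caller-vs-union comparison.

    ``score_a`` is the caller-side score (``UNDETECTED_SCORE`` where the
    caller missed the peak), ``score_b`` the union-side ranking score, and
    ``matched_mask`` flags the peaks the caller detected.
    """

    caller: str
    peak_ids: list[str]
    score_a: np.ndarray
    score_b: np.ndarray
    matched_mask: np.ndarray

    def __post_init__(self) -> None:
        self.score_a = np.asarray(self.score_a, dtype=float)
        self.score_b = np.asarray(self.score_b, dtype=float)
        self.matched_mask = np.asarray(self.matched_mask, dtype=bool)
        n = len(self.peak_ids)
        if not (len(self.score_a) == len(self.score_b) == len(self.matched_mask) == n):
            raise ValueError("PairedScores fields must have equal lengths")
        unmatched = ~self.matched_mask
        if np.any(self.score_a[unmatched] != UNDETECTED_SCORE):
            raise ValueError("unmatched entries must carry the worst-rank placeholder")

    @property
    def n_matched(self) -> int:
        return int(self.matched_mask.sum())


def rank_union(merged: Sequence[MergedPeak]) -> list[MergedPeak]:
    """Rank the union set: descending detecting-caller count, ties broken by
    descending fold change, then (chrom, start) for determinism.

    The returned order defines the union-side score used when pairing a
    caller against the union (position 1 = best = highest score).
    """
    for m in merged:
        if m.fold_change is None:
            raise ValueError(f"peak {m.peak_id} has no fold change; rank after quantify")
    return sorted(
        merged,
        key=lambda m: (
            -m.n_callers,
            -m.fold_change,
            chrom_sort_key(m.chrom),
            m.start,
        ),
    )


def pair_caller_with_union(
    caller: str,
    merged: Sequence[MergedPeak],
    caller_scores: Mapping[str, float],
) -> PairedScores:
    """Build the caller-vs-union score pairs over every union peak.

    ``merged`` must be in ranked order (see :func:`rank_union`); the
    union-side score of the peak at rank position ``i`` (0-based) is
    ``n - i``.  The caller-side score is the maximum score over the
    caller's constituent peaks within the merged region.
    """
    n = len(merged)
    peak_ids: list[str] = []
    score_a = np.empty(n)
    score_b = np.empty(n)
    matched = np.zeros(n, dtype=bool)
    seen = False
    for i, m in enumerate(merged):
        peak_ids.append(m.peak_id)
        score_b[i] = n - i
        names = m.constituents.get(caller)
        if names:
            seen = True
            matched[i] = True
            try:
                score_a[i] = max(caller_scores[name] for name in names)
            except KeyError as exc:
                raise KeyError(
                    f"no score for constituent peak {exc.args[0]!r} of caller {caller!r}"
                ) from None
        else:
            score_a[i] = UNDETECTED_SCORE
    if not seen:
        raise ValueError(f"caller {caller!r} detected no union peak; nothing to pair")
    return PairedScores(caller, peak_ids, score_a, score_b, matched)


# --------------------------------------------------------------------------
# mixture model
# --------------------------------------------------------------------------

def _average_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks in [1, n] (ties share their mean rank)."""
    return stats.rankdata(x, method="average")


def _pseudo_values(u: np.ndarray, p: float, mu: float, sigma: float) -> np.ndarray:
    """Invert the mixture marginal CDF G at the empirical quantiles u.

    G(z) = p * Phi((z - mu) / sigma) + (1 - p) * Phi(z); monotone, inverted
    by interpolation on a dense grid spanning both components.
    """
    lo = min(-6.0, mu - 6.0 * sigma)
    hi = max(6.0, mu + 6.0 * sigma)
    grid = np.linspace(lo, hi, 4001)
    cdf = p * stats.norm.cdf((grid - mu) / sigma) + (1.0 - p) * stats.norm.cdf(grid)
    # guard strict monotonicity for np.interp
    cdf = np.maximum.accumulate(cdf)
    return np.interp(u, cdf, grid)


def _log_bivariate_pdf(
    z1: np.ndarray, z2: np.ndarray, mu: float, sigma: float, rho: float
) -> np.ndarray:
    """Log density of N((mu, mu), sigma^2 [[1, rho], [rho, 1]])."""
    one_m_r2 = 1.0 - rho * rho
    a = (z1 - mu) / sigma
    b = (z2 - mu) / sigma
    quad = (a * a - 2.0 * rho * a * b + b * b) / one_m_r2
    return (
        -math.log(2.0 * math.pi)
        - 2.0 * math.log(sigma)
        - 0.5 * math.log(one_m_r2)
        - 0.5 * quad
    )


class IdrMixtureModel:
    """Two-component Gaussian copula mixture for reproducibility scoring.

    Scores are rank-transformed to empirical quantiles and mapped to
    pseudo-values through the inverse of the current mixture marginal.
    Estimation alternates one EM step with a pseudo-value refresh until
    the parameters stabilize, then polishes with a plain EM run at fixed
    pseudo-values (exact M-steps, hence a non-decreasing log-likelihood).
    At a joint fixed point the polish is a no-op, so the reported
    parameters satisfy both the copula self-consistency and the EM
    stationarity conditions.

    Parameters
    ----------
    max_iter : int
        Maximum alternation rounds (one EM step + pseudo-value refresh).
    tol : float
        Convergence tolerance on the parameter change per round.
    polish_iter : int
        Maximum EM iterations of the final fixed-pseudo-value run.

    Attributes (after ``fit``)
    --------------------------
    params_ : IdrModelParams
    local_idr_ : ndarray
        Posterior probability of the irreproducible component per pair.
    global_idr_ : ndarray
        Running mean of sorted local idr, mapped back to input order;
        monotone non-decreasing along the local-idr ranking.
    loglik_trace_ : ndarray
        Per-iteration log-likelihood of the final fixed-pseudo-value EM
        run (non-decreasing).
    converged_ : bool
    degenerate_ : bool
        True when the fitted reproducible component carried no dependence
        (rho below the identifiability floor); all pairs are then reported
        irreproducible.
    n_iter_ : int
        Alternation rounds used.
    """

    _P_MIN = 1e-4
    _RHO_MAX = 1.0 - 1e-4
    _SIGMA_MIN = 1e-3
    #: Below this fitted correlation the "reproducible" component carries no
    #: dependence: the mixture is then a relabeling of noise (a degenerate
    #: uncorrelated blob can swallow the data and make everything look
    #: reproducible), so every pair is reported irreproducible instead.
    _RHO_IDENTIFIABLE = 0.05

    def __init__(
        self, max_iter: int = 3000, tol: float = 1e-7, polish_iter: int = 200
    ):
        self.max_iter = max_iter
        self.tol = tol
        self.polish_iter = polish_iter

    def _em_step(self, z1, z2, n, p, rho, mu, sigma):
        """One E-step + exact M-step; returns updated params, the
        log-likelihood at the *incoming* params, and the posterior."""
        log_f1 = _log_bivariate_pdf(z1, z2, mu, sigma, rho)
        log_f0 = _log_bivariate_pdf(z1, z2, 0.0, 1.0, 0.0)
        a = np.log(p) + log_f1
        b = np.log1p(-p) + log_f0
        m = np.maximum(a, b)
        log_total = m + np.log(np.exp(a - m) + np.exp(b - m))
        ll = float(log_total.sum())
        posterior = np.exp(a - log_total)
        # M-step: exact MLE of the exchangeable bivariate normal component
        w = posterior.sum()
        p = min(max(w / n, self._P_MIN), 1.0 - self._P_MIN)
        if w > 0:
            mu = max(float((posterior * (z1 + z2)).sum() / (2.0 * w)), 0.0)
            d1 = z1 - mu
            d2 = z2 - mu
            var = float((posterior * (d1 * d1 + d2 * d2)).sum() / (2.0 * w))
            sigma = max(math.sqrt(max(var, 0.0)), self._SIGMA_MIN)
            cov = float((posterior * d1 * d2).sum() / w)
            rho = min(max(cov / (sigma * sigma), 0.0), self._RHO_MAX)
        return p, rho, mu, sigma, ll, posterior

    def fit(self, score_a: np.ndarray, score_b: np.ndarray) -> "IdrMixtureModel":
        x = np.asarray(score_a, dtype=float)
        y = np.asarray(score_b, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("score vectors must be equal-length 1-D arrays")
        n = len(x)
        if n < 50:
            raise ValueError(f"need >= 50 matched pairs, got {n}")
        if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
            raise ValueError("degenerate input: scores are constant on one side")

        u = _average_ranks(x) / (n + 1.0)
        v = _average_ranks(y) / (n + 1.0)

        p, rho, mu, sigma = 0.5, 0.5, 1.0, 1.0
        converged = False
        rounds = 0
        for rounds in range(1, self.max_iter + 1):
            z1 = _pseudo_values(u, p, mu, sigma)
            z2 = _pseudo_values(v, p, mu, sigma)
            p0, rho0, mu0, sigma0 = p, rho, mu, sigma
            p, rho, mu, sigma, _, _ = self._em_step(z1, z2, n, p, rho, mu, sigma)
            delta = max(
                abs(p - p0), abs(rho - rho0), abs(mu - mu0), abs(sigma - sigma0)
            )
            if delta < self.tol:
                converged = True
                break

        if not converged:
            warnings.warn(
                "IDR mixture fit did not converge; returning last iterate",
                RuntimeWarning,
                stacklevel=2,
            )

        # polish at fixed pseudo-values; EM guarantees the trace is monotone
        z1 = _pseudo_values(u, p, mu, sigma)
        z2 = _pseudo_values(v, p, mu, sigma)
        trace: list[float] = []
        posterior = np.full(n, 0.5)
        prev_ll = -np.inf
        for _ in range(self.polish_iter):
            p, rho, mu, sigma, ll, posterior = self._em_step(
                z1, z2, n, p, rho, mu, sigma
            )
            trace.append(ll)
            if abs(ll - prev_ll) < 1e-9 * max(1.0, abs(ll)):
                break
            prev_ll = ll

        self.degenerate_ = rho < self._RHO_IDENTIFIABLE
        if self.degenerate_:
            local_idr = np.ones(n)
        else:
            local_idr = 1.0 - posterior
        order = np.argsort(local_idr, kind="stable")
        sorted_local = local_idr[order]
        running_mean = np.cumsum(sorted_local) / np.arange(1, n + 1)
        global_idr = np.empty(n)
        global_idr[order] = running_mean

        self.params_ = IdrModelParams(p=p, rho=rho, mu=mu, sigma=sigma)
        self.local_idr_ = local_idr
        self.global_idr_ = np.clip(global_idr, 0.0, 1.0)
        self.loglik_trace_ = np.asarray(trace)
        self.converged_ = converged
        self.n_iter_ = rounds
        return self

    @staticmethod
    def simulate(
        n: int,
        params: IdrModelParams,
        rng: np.random.Generator,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Draw score pairs from the mixture (pseudo-value scale).

        Used for parameter-recovery checks: the fit is rank-based, so any
        strictly monotone transform of these scores fits identically.
        """
        reproducible = rng.random(n) < params.p
        z = rng.standard_normal((n, 2))
        x = np.where(
            reproducible,
            params.mu
            + params.sigma * z[:, 0],
            z[:, 0],
        )
        mix = params.rho * z[:, 0] + math.sqrt(1.0 - params.rho**2) * z[:, 1]
        y = np.where(
            reproducible,
            params.mu + params.sigma * mix,
            z[:, 1],
        )
        return x, y


def fit_idr(
    pairs: PairedScores, max_iter: int = 200, tol: float = 1e-6
) -> tuple[IdrModelParams, np.ndarray, np.ndarray]:
    """Fit the mixture on the matched pairs of a caller-vs-union comparison.

    Returns (params, local idr, global IDR); the idr vectors cover only the
    matched peaks, in the order they appear in ``pairs``.
    """
    mask = pairs.matched_mask
    model = IdrMixtureModel(max_iter=max_iter, tol=tol).fit(
        pairs.score_a[mask], pairs.score_b[mask]
    )
    return model.params_, model.local_idr_, model.global_idr_


def aggregate_idr(
    merged: Sequence[MergedPeak],
    per_caller_idr: Mapping[str, Mapping[str, float]],
    idr_floor: float = 1e-10,
) -> list[MergedPeak]:
    """Aggregate per-caller global IDR values into one final IDR per peak.

    For each peak, detected callers contribute ``-log10(IDR_c)`` (IDR
    clamped below at ``idr_floor`` before the log) and undetected callers
    contribute 0; the sum S converts to ``final_idr = 10**(-S)``, clamped
    to [0, 1].  Fills ``neg_log10_idr_by_caller`` and ``final_idr`` in
    place and returns the peaks.
    """
    callers = sorted(per_caller_idr)
    for m in merged:
        by_caller: dict[str, float] = {}
        for c in callers:
            idr_value = per_caller_idr[c].get(m.peak_id)
            if idr_value is None or c not in m.constituents:
                by_caller[c] = 0.0
            else:
                if not (0.0 <= idr_value <= 1.0):
                    raise ValueError(
                        f"IDR value {idr_value} for {m.peak_id}/{c} outside [0, 1]"
                    )
                by_caller[c] = -math.log10(max(idr_value, idr_floor))
        m.neg_log10_idr_by_caller = by_caller
        s = sum(by_caller.values())
        m.final_idr = min(max(10.0 ** (-s), 0.0), 1.0)
    return list(merged)
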