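"""Reproducibility model: pairing, EM fit, aggregation, ranking."""

import math
import warnings

import numpy as np
import pytest

from consensuspeaks.core import MergedPeak
from consensuspeaks.idr import (
    UNDETECTED_SCORE,
    IdrMixtureModel,
    IdrModelParams,
    aggregate_idr,
    fit_idr,
    pair_caller_with_union,
    rank_union,
)


def _merged(peak_id, chrom, start, end, constituents, fc=None):
    m = MergedPeak(peak_id, chrom, start, end, constituents)
    m.fold_change = fc
    return m


class TestRankUnion:
    def test_caller_count_dominates_fold_change(self):
        many = _merged("m", "chr1", 0, 100, {c: [f"{c}_1"] for c in "abcd"}, fc=1.1)
        one = _merged("o", "chr1", 200, 300, {"a": ["a_2"]}, fc=50.0)
        assert rank_union([one, many]) == [many, one]

    def test_fold_change_breaks_ties(self):
        lo = _merged("lo", "chr1", 0, 100, {"a": ["a1"], "b": ["b1"]}, fc=3.0)
        hi = _merged("hi", "chr1", 200, 300, {"a": ["a2"], "b": ["b2"]}, fc=8.0)
        assert rank_union([lo, hi]) == [hi, lo]

    def test_matches_independent_comparator(self):
        rng = np.random.default_rng(0)
        peaks = []
        for i in range(100):
            k = int(rng.integers(1, 5))
            peaks.append(
                _merged(
                    f"p{i}", f"chr{rng.integers(1, 3)}", int(rng.integers(0, 10**6)),
                    int(rng.integers(0, 10**6)) + 10**6,
                    {c: [f"{c}_{i}"] for c in "abcd"[:k]},
                    fc=float(rng.random() * 10),
                )
            )
        ranked = rank_union(peaks)
        import functools

        def cmp(x, y):
            if x.n_callers != y.n_callers:
                return -1 if x.n_callers > y.n_callers else 1
            if x.fold_change != y.fold_change:
                return -1 if x.fold_change > y.fold_change else 1
            return -1 if (x.chrom, x.start) < (y.chrom, y.start) else 1

        assert ranked == sorted(peaks, key=functools.cmp_to_key(cmp))

    def test_unset_fold_change_rejected(self):
        with pytest.raises(ValueError, match="fold change"):
            rank_union([_merged("p", "chr1", 0, 10, {"a": ["a1"]})])


class TestPairing:
    def _ranked(self):
        peaks = [
            _merged("u1", "chr1", 0, 100, {"a": ["a_1"], "b": ["b_1"]}, fc=9.0),
            _merged("u2", "chr1", 200, 300, {"a": ["a_2", "a_3"]}, fc=5.0),
            _merged("u3", "chr1", 400, 500, {"b": ["b_2"]}, fc=2.0),
        ]
        return rank_union(peaks)

    def test_full_matching(self):
        pairs = pair_caller_with_union(
            "a", self._ranked()[:2], {"a_1": 1.0, "a_2": 3.2, "a_3": 7.5}
        )
        assert pairs.matched_mask.all()

    def test_missing_peak_gets_placeholder(self):
        pairs = pair_caller_with_union(
            "a", self._ranked(), {"a_1": 1.0, "a_2": 3.2, "a_3": 7.5}
        )
        assert pairs.matched_mask.tolist() == [True, True, False]
        assert pairs.score_a[2] == UNDETECTED_SCORE

    def test_best_constituent_score_is_used(self):
        pairs = pair_caller_with_union(
            "a", self._ranked(), {"a_1": 1.0, "a_2": 3.2, "a_3": 7.5}
        )
        assert pairs.score_a[1] == 7.5  # max over a_2, a_3

    def test_union_score_reflects_rank(self):
        pairs = pair_caller_with_union(
            "a", self._ranked(), {"a_1": 1.0, "a_2": 3.2, "a_3": 7.5}
        )
        assert pairs.score_b.tolist() == [3.0, 2.0, 1.0]

    def test_absent_caller_rejected(self):
        with pytest.raises(ValueError, match="nothing to pair"):
            pair_caller_with_union("zzz", self._ranked(), {})


class TestMixtureFit:
    def test_parameter_recovery_from_self_simulated_data(self):
        truth = IdrModelParams(p=0.7, rho=0.8, mu=2.5, sigma=1.0)
        rng = np.random.default_rng(12)
        x, y = IdrMixtureModel.simulate(10_000, truth, rng)
        model = IdrMixtureModel().fit(x, y)
        assert model.params_.p == pytest.approx(0.7, abs=0.05)

    def test_loglik_trace_monotone_and_global_idr_monotone(self):
        rng = np.random.default_rng(3)
        x, y = IdrMixtureModel.simulate(
            4000, IdrModelParams(0.6, 0.7, 2.0, 1.2), rng
        )
        model = IdrMixtureModel().fit(x, y)
        assert np.all(np.diff(model.loglik_trace_) >= -1e-6)
        order = np.argsort(model.local_idr_, kind="stable")
        assert np.all(np.diff(model.global_idr_[order]) >= -1e-12)

    def test_independent_scores_give_high_idr(self):
        rng = np.random.default_rng(8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = IdrMixtureModel().fit(
                rng.standard_normal(5000), rng.standard_normal(5000)
            )
        assert np.median(model.global_idr_) > 0.5

    def test_perfectly_correlated_scores_give_low_idr(self):
        rng = np.random.default_rng(4)
        s = rng.standard_normal(1000)
        model = IdrMixtureModel().fit(s, 2.0 * s + 3.0)
        assert model.params_.p > 0.9
        assert np.median(model.global_idr_) < 0.05

    def test_rank_invariance(self):
        """Any strictly monotone transform of the scores fits identically."""
        rng = np.random.default_rng(5)
        x, y = IdrMixtureModel.simulate(2000, IdrModelParams(0.7, 0.8, 2.5, 1.0), rng)
        m1 = IdrMixtureModel().fit(x, y)
        m2 = IdrMixtureModel().fit(np.exp(x), y**3)
        assert m1.params_.p == pytest.approx(m2.params_.p, abs=1e-9)
        assert np.allclose(m1.global_idr_, m2.global_idr_)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="50"):
            IdrMixtureModel().fit(np.arange(10.0), np.arange(10.0))

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            IdrMixtureModel().fit(np.ones(100), np.arange(100.0))

    def test_fit_idr_uses_only_matched_pairs(self):
        rng = np.random.default_rng(6)
        x, y = IdrMixtureModel.simulate(500, IdrModelParams(0.7, 0.8, 2.5, 1.0), rng)
        peaks = [
            _merged(f"p{i}", "chr1", i * 1000, i * 1000 + 100,
                    {"a": [f"a_{i}"]}, fc=float(y[i]))
            for i in range(500)
        ] + [
            _merged("q", "chr1", 10**7, 10**7 + 100, {"b": ["b_1"]}, fc=0.5)
        ]
        from consensuspeaks.idr import PairedScores

        mask = np.array([True] * 500 + [False])
        pairs = PairedScores(
            "a",
            [p.peak_id for p in peaks],
            np.concatenate([x, [UNDETECTED_SCORE]]),
            np.concatenate([y, [0.0]]),
            mask,
        )
        params, local, global_idr = fit_idr(pairs)
        assert len(local) == 500 and len(global_idr) == 500


class TestAggregation:
    def test_all_undetected_gives_final_idr_one(self):
        m = _merged("p", "chr1", 0, 10, {"a": ["a1"]})
        aggregate_idr([m], {"a": {}, "b": {}, "c": {}, "d": {}})
        assert m.final_idr == 1.0
        assert all(v == 0.0 for v in m.neg_log10_idr_by_caller.values())

    def test_direct_arithmetic(self):
        m = _merged("p", "chr1", 0, 10, {c: [f"{c}1"] for c in "abcd"})
        aggregate_idr([m], {c: {"p": 0.1} for c in "abcd"})
        assert m.neg_log10_idr_by_caller == pytest.approx({c: 1.0 for c in "abcd"})
        assert m.final_idr == pytest.approx(1e-4)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(7)
        peaks = []
        per_caller = {c: {} for c in "abcd"}
        for i in range(1000):
            detected = [c for c in "abcd" if rng.random() < 0.6] or ["a"]
            m = _merged(f"p{i}", "chr1", i * 10, i * 10 + 5,
                        {c: [f"{c}{i}"] for c in detected})
            peaks.append(m)
            for c in detected:
                per_caller[c][m.peak_id] = float(rng.uniform(1e-8, 1.0))
        aggregate_idr(peaks, per_caller)
        for m in peaks:
            s = sum(
                -math.log10(max(per_caller[c].get(m.peak_id, 1.0), 1e-10))
                for c in m.constituents
            )
            assert m.final_idr == pytest.approx(10.0 ** -s, rel=1e-9)

    def test_zero_idr_clamped_to_floor(self):
        m = _merged("p", "chr1", 0, 10, {"a": ["a1"]})
        aggregate_idr([m], {"a": {"p": 0.0}})
        assert m.neg_log10_idr_by_caller["a"] == pytest.approx(10.0)
        assert m.final_idr == pytest.approx(1e-10)

    def test_permutation_invariance_in_caller_order(self):
        m1 = _merged("p", "chr1", 0, 10, {c: [f"{c}1"] for c in "abc"})
        m2 = _merged("p", "chr1", 0, 10, {c: [f"{c}1"] for c in "abc"})
        idrs = {"a": {"p": 0.2}, "b": {"p": 0.05}, "c": {"p": 0.9}}
        aggregate_idr([m1], idrs)
        aggregate_idr([m2], dict(reversed(list(idrs.items()))))
        assert m1.final_idr == pytest.approx(m2.final_idr, rel=1e-12)
        assert m1.neg_log10_idr_by_caller == m2.neg_log10_idr_by_caller

    def test_out_of_range_idr_rejected(self):
        m = _merged("p", "chr1", 0, 10, {"a": ["a1"]})
        with pytest.raises(ValueError):
            aggregate_idr([m], {"a": {"p": 1.5}})
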