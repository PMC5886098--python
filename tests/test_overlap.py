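"""P-value-informed pruning, per-threshold overlap tests and the
permutation null."""

import numpy as np
import pytest
from scipy import stats

from crosstrait import (OverlapConfig, permutation_overlap,
                        pvalue_informed_prune, select_candidates,
                        threshold_overlap)
from crosstrait.coloc import ColocResult

from conftest import make_sumstats, stack_blocks


def brute_force_prune(pvals, r2, prune_r2):
    """Literal re-execution of the sorted-greedy definition: iterate
    variants in ascending p, keep iff r2 with every kept variant is
    <= prune_r2.  Single-block instance, indices 0..k-1."""
    order = np.lexsort((np.arange(len(pvals)), pvals))
    kept = []
    for i in order:
        if all(r2[i, j] <= prune_r2 for j in kept):
            kept.append(i)
    return set(kept)


def _single_block_sumstats(pvals, ids=None):
    ids = ids or [f"v{i}" for i in range(len(pvals))]
    recs = []
    for i, (vid, p) in enumerate(zip(ids, pvals)):
        z = stats.norm.isf(p / 2)
        recs.append((vid, "1", (i + 1) * 10, "A", "G", z / 100.0, 1 / 100.0))
    s = make_sumstats(recs)
    s.df["pvalue"] = np.asarray(pvals, dtype=float)
    return s, ids


class TestPrune:
    def test_hand_worked_example(self):
        # p=(0.001, 0.01, 0.02); r2(1,2)=0.9, others 0 -> keep {v0, v2}
        r = np.eye(3)
        r[0, 1] = r[1, 0] = np.sqrt(0.9)
        s, ids = _single_block_sumstats([0.001, 0.01, 0.02])
        blocks, mats = stack_blocks([("b", ids, r)])
        assert pvalue_informed_prune(s, blocks, mats, 0.05) == ["v0", "v2"]

    def test_identity_ld_keeps_all(self):
        s, ids = _single_block_sumstats([0.5, 0.1, 0.9, 0.3])
        blocks, mats = stack_blocks([("b", ids, np.eye(4))])
        assert set(pvalue_informed_prune(s, blocks, mats, 0.05)) == set(ids)

    def test_equal_p_tie_broken_by_position(self):
        r = np.full((2, 2), 1.0)
        s, ids = _single_block_sumstats([0.5, 0.5])
        blocks, mats = stack_blocks([("b", ids, r)])
        kept = pvalue_informed_prune(s, blocks, mats, 0.05)
        assert kept == ["v0"]  # earlier position wins the tie

    def test_missing_assignment_raises(self):
        s, ids = _single_block_sumstats([0.5, 0.5])
        blocks, mats = stack_blocks([("b", ids, np.eye(2))])
        del blocks.assignment["v1"]
        with pytest.raises(ValueError, match="assignment"):
            pvalue_informed_prune(s, blocks, mats, 0.05)

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_random_instances(self, seed):
        """Greedy result matches brute-force re-execution; no retained
        within-block pair exceeds the r2 cap."""
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 21)
        # random correlation with substantial LD
        A = rng.normal(size=(k, max(2, k // 2)))
        c = A @ A.T + np.eye(k) * 0.5
        d = np.sqrt(np.diag(c))
        r = c / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
        pvals = rng.uniform(size=k)
        s, ids = _single_block_sumstats(list(pvals))
        blocks, mats = stack_blocks([("b", ids, r)])
        kept = pvalue_informed_prune(s, blocks, mats, 0.05)
        expected = brute_force_prune(pvals, r ** 2, 0.05)
        assert {ids.index(v) for v in kept} == expected
        kept_idx = sorted(ids.index(v) for v in kept)
        for i in kept_idx:
            for j in kept_idx:
                if i != j:
                    assert r[i, j] ** 2 <= 0.05 + 1e-12


class TestThresholdOverlap:
    def test_chi2_by_direct_summation(self):
        # table [[10,90],[5,895]]: chi2 = sum (O-E)^2/E = 54.33...
        a_p = np.r_[np.full(100, 0.01), np.full(900, 0.9)]
        b_p = np.r_[np.full(10, 0.01), np.full(90, 0.9),
                    np.full(5, 0.01), np.full(895, 0.9)]
        res = threshold_overlap(a_p, b_p, 0.05)
        assert res.table2x2 == (10, 90, 5, 895)
        obs = np.array([10, 90, 5, 895], dtype=float)
        exp = np.array([100 * 15, 100 * 985, 900 * 15, 900 * 985]) / 1000.0
        assert res.chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum())
        assert res.chi2 == pytest.approx(54.33, abs=0.01)

    def test_exact_independence_gives_zero(self):
        a_p = np.r_[np.full(2, 0.01), np.full(2, 0.9),
                    np.full(2, 0.01), np.full(2, 0.9)]
        b_p = np.r_[np.full(4, 0.01), np.full(4, 0.9)]
        res = threshold_overlap(a_p, b_p, 0.05)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_is_missing(self):
        res = threshold_overlap(np.full(10, 0.9), np.full(10, 0.01), 0.05)
        assert np.isnan(res.chi2) and np.isnan(res.p_chi2)

    def test_counts_add_up_and_nest(self):
        rng = np.random.default_rng(5)
        a_p, b_p = rng.uniform(size=500), rng.uniform(size=500)
        prev = None
        for t in (0.5, 0.1, 0.05, 0.01):
            res = threshold_overlap(a_p, b_p, t)
            assert sum(res.table2x2) == res.n_total == 500
            if prev is not None:
                assert res.n_overlap <= prev
            prev = res.n_overlap


class TestPermutation:
    def test_add_one_estimator_floor(self):
        rng = np.random.default_rng(0)
        a_p = rng.uniform(size=300)
        cfg = OverlapConfig(thresholds=(0.05,), n_perm=999, seed=1)
        an = permutation_overlap(a_p, a_p, cfg)
        # b identical to a: observed overlap is maximal, no permutation
        # can beat it -> p at the add-one floor 1/(n_perm+1)
        assert an.results[0].p_perm == pytest.approx(1 / 1000)

    def test_shared_stream_across_thresholds(self):
        rng = np.random.default_rng(2)
        a_p, b_p = rng.uniform(size=400), rng.uniform(size=400)
        cfg = OverlapConfig(n_perm=100, seed=3)
        an1 = permutation_overlap(a_p, b_p, cfg)
        an2 = permutation_overlap(a_p, b_p, cfg)
        assert [r.p_perm for r in an1.results] == [r.p_perm for r in an2.results]

    def test_p_perm_approaches_p_chi2_with_many_permutations(self):
        """Under the chi-square null with large counts the permutation
        p converges to the analytic p."""
        rng = np.random.default_rng(4)
        m = 4000
        a_p, b_p = rng.uniform(size=m), rng.uniform(size=m)
        diffs = []
        for n_perm in (400, 12_800):
            cfg = OverlapConfig(thresholds=(0.1,), n_perm=n_perm, seed=9)
            an = permutation_overlap(a_p, b_p, cfg)
            diffs.append(abs(an.results[0].p_perm - an.results[0].p_chi2))
        assert diffs[1] <= diffs[0] + 0.02

    def test_null_calibration_small(self):
        rej = 0
        n_rep = 100
        for i in range(n_rep):
            rng = np.random.default_rng(1000 + i)
            a_p, b_p = rng.uniform(size=1000), rng.uniform(size=1000)
            cfg = OverlapConfig(thresholds=(0.05,), n_perm=400, seed=i)
            an = permutation_overlap(a_p, b_p, cfg)
            rej += an.results[0].p_perm <= 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rej / n_rep - 0.05) < 3 * se + 1e-9


class TestSelectCandidates:
    def _analysis(self, ids, a_p, b_p):
        from crosstrait.overlap import OverlapAnalysis
        return OverlapAnalysis(ids, np.asarray(a_p), np.asarray(b_p))

    def _coloc(self, top1, top2, flagged=True):
        pp = np.array([0.0, 0.0, 0.0, 0.95, 0.05]) if flagged else \
            np.array([0.9, 0.025, 0.025, 0.025, 0.025])
        return ColocResult("b", 10, pp, top1, top2,
                           flagged_h3=flagged, flagged_h4=False)

    def test_empty_selection(self):
        an = self._analysis(["v1"], [0.5], [0.5])
        assert select_candidates([an], [self._coloc("v1", "v1", False)]) == []

    def test_same_top_snp_deduplicated(self):
        assert select_candidates([], [self._coloc("v1", "v1")]) == ["v1"]

    def test_union_count(self):
        an = self._analysis([f"v{i}" for i in range(6)],
                            [1e-4] * 4 + [0.5, 0.5],
                            [1e-4] * 4 + [0.5, 0.5])
        got = select_candidates([an], [self._coloc("v0", "vX")])
        # 4 overlap SNPs + 2 region tops, one of which overlaps the set
        assert got == ["v0", "v1", "v2", "v3", "vX"]
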