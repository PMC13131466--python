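"""Prevalence computation, permutation nulls, and BH adjustment."""

import numpy as np
import pytest
from scipy.stats import hypergeom, kstest
from statsmodels.stats.multitest import multipletests

from aneuclone.errors import AnalysisError
from aneuclone.genome_io import CohortRecord
from aneuclone.prevalence import (
    bh_adjust,
    compute_prevalence,
    format_pvalue,
    pooled_permutation_test,
    rank_permutation_test,
)


def make_cohort(groups, arm="17q"):
    """groups: list of (type, n_deleted, n_total[, n_wgd])."""
    records = []
    for item in groups:
        ctype, n_del, n_tot = item[:3]
        n_wgd = item[3] if len(item) > 3 else 0
        for i in range(n_tot):
            records.append(
                CohortRecord(
                    sample_id=f"{ctype}_{i}",
                    cancer_type=ctype,
                    arm_call={arm: -1 if i < n_del else 0},
                    wgd=i < n_wgd,
                    gbrca1=False,
                    gbrca2=False,
                )
            )
    return records


class TestComputePrevalence:
    def test_printed_count_worked_examples(self):
        # ovarian 6,200/20,493 and breast 14,700/38,550 published proportions
        cohort = make_cohort([("OV", 6200, 20493), ("BRCA", 14700, 38550)])
        res = {r.cancer_type: r for r in compute_prevalence(cohort, "17q")}
        assert res["OV"].prevalence == pytest.approx(0.30254, abs=5e-6)
        assert 100 * res["OV"].prevalence == pytest.approx(30.3, abs=0.05)
        assert res["BRCA"].prevalence == pytest.approx(0.381323, abs=5e-6)
        assert 100 * res["BRCA"].prevalence == pytest.approx(38.0, abs=0.5)

    def test_all_neutral_calls_give_zero_prevalence(self):
        cohort = make_cohort([("X", 0, 50)])
        (res,) = compute_prevalence(cohort, "17q")
        assert res.prevalence == 0.0 and res.n_deleted == 0

    def test_wgd_exclusion_drops_numerator_and_denominator(self):
        # 10 deleted of 20; the first 5 samples (all deleted) are WGD
        cohort = make_cohort([("X", 10, 20, 5)])
        (all_res,) = compute_prevalence(cohort, "17q", exclude_wgd=False)
        (nw_res,) = compute_prevalence(cohort, "17q", exclude_wgd=True)
        assert (all_res.n_deleted, all_res.n_total) == (10, 20)
        assert (nw_res.n_deleted, nw_res.n_total) == (5, 15)

    def test_exclusion_is_identity_on_wgd_free_cohort(self):
        cohort = make_cohort([("A", 3, 10), ("B", 2, 8)])
        assert compute_prevalence(cohort, "17q", False) == compute_prevalence(
            cohort, "17q", True
        )

    def test_emptied_type_flagged_not_raised(self):
        cohort = make_cohort([("A", 2, 5, 5), ("B", 1, 5)])
        res = {r.cancer_type: r for r in compute_prevalence(cohort, "17q", True)}
        assert res["A"].n_total == 0 and res["A"].prevalence is None

    def test_missing_arm_is_an_error(self):
        cohort = make_cohort([("A", 1, 3)])
        with pytest.raises(AnalysisError):
            compute_prevalence(cohort, "13q")


class TestPooledPermutation:
    def test_concentrated_deletions_give_extreme_p(self):
        # all deletions in one type: exact hypergeometric tail oracle
        n_a, n_b, k = 60, 60, 30
        cohort = make_cohort([("A", k, n_a), ("B", 0, n_b)])
        res = {
            r.cancer_type: r
            for r in pooled_permutation_test(cohort, "17q", n_perm=20000, seed=3)
        }
        exact = hypergeom.sf(k - 1, n_a + n_b, k, n_a)  # P(perm count >= k)
        assert res["A"].p_perm == pytest.approx(exact, abs=4e-3)
        assert res["A"].p_perm < 1.0 / 1000
        assert res["B"].p_perm == 1.0  # nothing is below prevalence 0

    def test_permuted_allocation_matches_literal_shuffle(self):
        # the multivariate-hypergeometric draw equals literally shuffling
        # the pooled indicator vector and re-partitioning
        cohort = make_cohort([("A", 8, 30), ("B", 4, 20), ("C", 2, 10)])
        res = pooled_permutation_test(cohort, "17q", n_perm=30000, seed=0)
        rng = np.random.default_rng(12)
        pool = np.array([1] * 14 + [0] * 46)
        sizes, obs = [30, 20, 10], [8, 4, 2]
        hits = np.zeros(3)
        B = 30000
        for _ in range(B):
            rng.shuffle(pool)
            parts = np.split(pool, np.cumsum(sizes)[:-1])
            for g in range(3):
                hits[g] += parts[g].sum() >= obs[g]
        for r, p_ref in zip(sorted(res, key=lambda r: r.cancer_type), hits / B):
            se = np.sqrt(p_ref * (1 - p_ref) / B)
            assert r.p_perm == pytest.approx(p_ref, abs=6 * se + 1e-3)

    def test_null_pvalues_near_uniform_on_exchangeable_cohort(self):
        # types drawn from one urn: p approximately U(0,1) over seeds
        pvals = []
        rng = np.random.default_rng(7)
        for seed in range(200):
            dels = rng.multivariate_hypergeometric([120, 120], 72)
            cohort = make_cohort([("A", int(dels[0]), 120), ("B", int(dels[1]), 120)])
            res = pooled_permutation_test(cohort, "17q", n_perm=400, seed=seed)
            pvals.append(res[0].p_perm)
        stat = kstest(pvals, "uniform").statistic
        assert stat < 0.12  # generous: permutation p is discrete

    def test_type_i_error_rate_near_nominal(self):
        rng = np.random.default_rng(21)
        hits = total = 0
        for seed in range(200):
            dels = rng.multivariate_hypergeometric([250, 250, 250], 225)
            cohort = make_cohort(
                [(t, int(d), 250) for t, d in zip("ABC", dels)]
            )
            for r in pooled_permutation_test(cohort, "17q", n_perm=400, seed=seed):
                hits += r.p_perm <= 0.05
                total += 1
        rate = hits / total
        assert abs(rate - 0.05) < 0.03

    def test_fdr_dominates_p_and_rejects_bad_nperm(self):
        cohort = make_cohort([("A", 5, 20), ("B", 2, 20)])
        for r in pooled_permutation_test(cohort, "17q", n_perm=500, seed=1):
            assert r.fdr >= r.p_perm
        with pytest.raises(AnalysisError):
            pooled_permutation_test(cohort, "17q", n_perm=0, seed=1)

    def test_zero_count_formats_as_resolution_bound(self):
        assert format_pvalue(0.0, 10000) == "< 0.0001"
        assert format_pvalue(0.25, 10000) == "0.25"
        assert format_pvalue(None, 100) == "NA"


class TestRankPermutation:
    def test_miniature_matches_exhaustive_label_shuffle(self):
        # 2 types of 3 samples, 2 deletions total, focal holds both;
        # enumerate all C(6,2)=15 equally likely allocations
        cohort = make_cohort([("F", 2, 3), ("O", 0, 3)])
        (res,) = rank_permutation_test(cohort, "17q", ["F"], n_perm=40000, seed=5)
        assert res.observed_rank == 1
        # rank(F)=1 iff F's count >= O's count (min-rank ties): counts (1,1),(2,0)
        exact = (hypergeom.pmf(1, 6, 2, 3) + hypergeom.pmf(2, 6, 2, 3))
        assert res.p == pytest.approx(exact, abs=0.01)

    def test_single_type_is_degenerate(self):
        cohort = make_cohort([("F", 2, 6)])
        (res,) = rank_permutation_test(cohort, "17q", ["F"], n_perm=100, seed=0)
        assert (res.observed_rank, res.n_types, res.p) == (1, 1, 1.0)

    def test_zero_prevalence_focal_ranks_last_with_p_one(self):
        groups = [("F", 0, 40)] + [(t, 10, 40) for t in "ABCD"]
        cohort = make_cohort(groups)
        (res,) = rank_permutation_test(cohort, "17q", ["F"], n_perm=2000, seed=2)
        assert res.observed_rank == 5
        assert res.p == pytest.approx(1.0, abs=0.02)

    def test_invariant_to_sample_order_and_nonfocal_relabeling(self):
        groups = [("F", 5, 20), ("X", 2, 20), ("Y", 3, 20)]
        cohort = make_cohort(groups)
        (a,) = rank_permutation_test(cohort, "17q", ["F"], n_perm=3000, seed=9)
        reordered = list(reversed(cohort))
        (b,) = rank_permutation_test(reordered, "17q", ["F"], n_perm=3000, seed=9)
        assert (a.observed_rank, a.p) == (b.observed_rank, b.p)
        relabeled = make_cohort([("F", 5, 20), ("Q", 2, 20), ("Z", 3, 20)])
        (c,) = rank_permutation_test(relabeled, "17q", ["F"], n_perm=3000, seed=9)
        assert (a.observed_rank, a.p) == (c.observed_rank, c.p)

    def test_absent_focal_type_is_an_error(self):
        cohort = make_cohort([("A", 1, 5), ("B", 0, 5)])
        with pytest.raises(AnalysisError):
            rank_permutation_test(cohort, "17q", ["Z"], n_perm=10, seed=0)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.5], [0.5]),
            ([0.04, 1.0], [0.08, 1.0]),
        ],
    )
    def test_hand_computed_step_up_examples(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected)

    def test_matches_statsmodels_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.random(rng.integers(1, 12))
            ours = bh_adjust(list(p))
            ref = multipletests(p, method="fdr_bh")[1]
            assert ours == pytest.approx(list(ref), rel=1e-12)

    def test_monotone_in_p_and_capped_at_one(self):
        rng = np.random.default_rng(4)
        p = np.sort(rng.random(15))
        q = bh_adjust(list(p))
        assert all(b >= a - 1e-15 for a, b in zip(q, q[1:]))
        assert max(q) <= 1.0

    def test_rejects_out_of_range(self):
        with pytest.raises(AnalysisError):
            bh_adjust([0.5, 1.2])
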