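"""Arm-deletion prevalence per cancer type and its permutation nulls.

Two tests are provided, mirroring the two cohort designs they serve:

* ``pooled_permutation_test`` — per cancer type, is the observed deletion
  prevalence higher than expected if deletion indicators were exchangeable
  across the whole cohort?  The pooled vector of per-sample indicators is
  reshuffled and re-partitioned into groups of the original type sizes
  (equivalently, the deletions are allocated by a multivariate
  hypergeometric draw); the p-value is the upper-tail count over
  permutations, BH-adjusted across types within the arm.

* ``rank_permutation_test`` — does a focal cancer type *rank* as high in
  prevalence as observed when cancer-type labels are shuffled?  Rank 1 is
  the highest prevalence and ties take the best (minimum) rank.

p-values use the plug-in estimator count / n_perm; an exact zero is
formatted "< 1/n_perm" for display while the numeric field stores 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import rng as rngmod
from .errors import AnalysisError
from .genome_io import CohortRecord

__all__ = [
    "PrevalenceResult",
    "RankTestResult",
    "compute_prevalence",
    "pooled_permutation_test",
    "rank_permutation_test",
    "bh_adjust",
    "format_pvalue",
]

DEFAULT_N_PERM = 10_000


@dataclass
class PrevalenceResult:
    cancer_type: str
    arm: str
    n_deleted: int
    n_total: int
    prevalence: float | None  # None when n_total == 0
    p_perm: float | None = None
    fdr: float | None = None
    n_perm: int | None = None


@dataclass
class RankTestResult:
    focal_type: str
    arm: str
    observed_rank: int
    n_types: int
    p: float
    n_perm: int


def format_pvalue(p: float | None, n_perm: int | None) -> str:
    if p is None:
        return "NA"
    if p == 0 and n_perm:
        return f"< {1.0 / n_perm:g}"
    return f"{p:g}"


def _group_counts(
    cohort: Sequence[CohortRecord], arm: str, exclude_wgd: bool
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-type (names, n_deleted, n_total) for one arm."""
    types: list[str] = []
    for rec in cohort:
        if rec.cancer_type not in types:
            types.append(rec.cancer_type)
    types.sort()
    idx = {t: i for i, t in enumerate(types)}
    n_del = np.zeros(len(types), dtype=np.int64)
    n_tot = np.zeros(len(types), dtype=np.int64)
    for rec in cohort:
        if exclude_wgd and rec.wgd:
            continue
        if arm not in rec.arm_call:
            raise AnalysisError(f"sample {rec.sample_id} has no call for arm {arm!r}")
        i = idx[rec.cancer_type]
        n_tot[i] += 1
        if rec.arm_call[arm] == -1:
            n_del[i] += 1
    return types, n_del, n_tot


def compute_prevalence(
    cohort: Sequence[CohortRecord], arm: str, exclude_wgd: bool = False
) -> list[PrevalenceResult]:
    """Observed deletion prevalence of one arm, per cancer type.

    ``exclude_wgd`` drops WGD-flagged samples from numerator and
    denominator (after whole-genome doubling a single-copy arm loss no
    longer implies LOH).  A type emptied by filtering yields n_total = 0
    with an undefined prevalence, not an exception.
    """
    types, n_del, n_tot = _group_counts(cohort, arm, exclude_wgd)
    return [
        PrevalenceResult(
            cancer_type=t,
            arm=arm,
            n_deleted=int(d),
            n_total=int(n),
            prevalence=(d / n) if n > 0 else None,
        )
        for t, d, n in zip(types, n_del, n_tot)
    ]


def pooled_permutation_test(
    cohort: Sequence[CohortRecord],
    arm: str,
    exclude_wgd: bool = False,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> list[PrevalenceResult]:
    """Upper-tail permutation test of per-type prevalence, BH-adjusted.

    Each permutation shuffles the pooled deletion indicators across all
    samples and re-partitions them into groups of the original type sizes;
    the per-type permuted deletion count is therefore a multivariate
    hypergeometric draw, which is how it is sampled.  p = fraction of
    permutations whose permuted prevalence >= the observed one.
    """
    if n_perm < 1:
        raise AnalysisError("n_perm must be >= 1")
    results = compute_prevalence(cohort, arm, exclude_wgd)
    nonempty = [r for r in results if r.n_total > 0]
    if len(nonempty) < 2:
        raise AnalysisError("pooled permutation test needs >= 2 nonempty cancer types")
    sizes = np.array([r.n_total for r in nonempty], dtype=np.int64)
    obs = np.array([r.n_deleted for r in nonempty], dtype=np.int64)
    k_pool = int(obs.sum())
    rng = rngmod.stream(seed, f"pooled-perm:{arm}")
    perm = rng.multivariate_hypergeometric(sizes, k_pool, size=n_perm)  # (B, G)
    # compare prevalences; same per-type denominator, so compare counts
    p_vals = (perm >= obs[None, :]).mean(axis=0)
    fdrs = bh_adjust(list(p_vals))
    for r, p, q in zip(nonempty, p_vals, fdrs):
        r.p_perm = float(p)
        r.fdr = float(q)
        r.n_perm = n_perm
    for r in results:
        if r.n_total == 0:
            r.n_perm = n_perm
    return results


def _min_rank_of_focal(prev: np.ndarray, focal_idx: int) -> np.ndarray:
    """Rank of the focal column per row; rank 1 = highest, ties get best rank."""
    focal = prev[:, focal_idx][:, None]
    return 1 + (prev > focal).sum(axis=1)


def rank_permutation_test(
    cohort: Sequence[CohortRecord],
    arm: str,
    focal_types: Sequence[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> list[RankTestResult]:
    """Rank-resampling test: shuffle type labels, re-rank prevalences.

    For each focal type, p = fraction of permutations in which the focal
    type's permuted prevalence rank is <= (at least as good as) its
    observed rank.
    """
    if n_perm < 1:
        raise AnalysisError("n_perm must be >= 1")
    types, n_del, n_tot = _group_counts(cohort, arm, exclude_wgd=False)
    if (n_tot == 0).any():
        empty = [t for t, n in zip(types, n_tot) if n == 0]
        raise AnalysisError(f"rank test requires nonempty types; empty: {empty}")
    for ft in focal_types:
        if ft not in types:
            raise AnalysisError(f"focal type {ft!r} absent from cohort")
    obs_prev = n_del / n_tot
    k_pool = int(n_del.sum())
    rng = rngmod.stream(seed, f"rank-perm:{arm}")
    perm = rng.multivariate_hypergeometric(n_tot, k_pool, size=n_perm)
    perm_prev = perm / n_tot[None, :]
    out = []
    for ft in focal_types:
        fi = types.index(ft)
        obs_rank = int(1 + (obs_prev > obs_prev[fi]).sum())
        perm_ranks = _min_rank_of_focal(perm_prev, fi)
        p = float((perm_ranks <= obs_rank).mean())
        out.append(
            RankTestResult(
                focal_type=ft,
                arm=arm,
                observed_rank=obs_rank,
                n_types=len(types),
                p=p,
                n_perm=n_perm,
            )
        )
    return out


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending ordering,
    capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise AnalysisError("bh_adjust: p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return [float(x) for x in out]
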