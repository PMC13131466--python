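"""Association between arm loss and germline carrier status per cancer type.

Each (cancer type, arm, gene) gives a 2x2 table

    a = deleted & carrier     b = deleted & non-carrier
    c = intact  & carrier     d = intact  & non-carrier

tested with a two-sided Fisher's exact test (sum of hypergeometric
probabilities over all margin-compatible tables at most as probable as the
observed one, with a 1e-7 relative tie tolerance).  The odds ratio is the
sample cross-product (a*d)/(b*c) with the Haldane 0.5 continuity correction
whenever any cell is zero.  BH adjustment runs within each (arm, gene)
family across cancer types; at a given FDR threshold an association is
called co-occurrence (OR > 1) or mutual exclusivity (OR < 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import hypergeom

from .errors import AnalysisError
from .genome_io import CohortRecord
from .prevalence import bh_adjust

__all__ = [
    "ContingencyResult",
    "build_contingency",
    "fisher_exact_two_sided",
    "classify_associations",
]

_TIE_RTOL = 1e-7


@dataclass
class ContingencyResult:
    cancer_type: str
    arm: str
    gene: str
    table: tuple[int, int, int, int]  # (a, b, c, d) as documented above
    odds_ratio: float | None = None  # None when a margin is zero
    p: float | None = None
    fdr: float | None = None
    direction: str = "none"

    @property
    def empty(self) -> bool:
        return sum(self.table) == 0


def build_contingency(
    cohort: Sequence[CohortRecord],
    arm: str,
    gene: str,
    by_type: bool = True,
) -> list[ContingencyResult]:
    """Count the 2x2 tables of deletion (call == -1) vs carrier status."""
    if gene not in ("BRCA1", "BRCA2"):
        raise AnalysisError(f"gene must be BRCA1 or BRCA2, got {gene!r}")
    flag = "gbrca1" if gene == "BRCA1" else "gbrca2"
    tables: dict[str, list[int]] = {}
    for rec in cohort:
        if arm not in rec.arm_call:
            raise AnalysisError(f"sample {rec.sample_id} has no call for arm {arm!r}")
        key = rec.cancer_type if by_type else "ALL"
        t = tables.setdefault(key, [0, 0, 0, 0])
        deleted = rec.arm_call[arm] == -1
        carrier = bool(getattr(rec, flag))
        if deleted and carrier:
            t[0] += 1
        elif deleted:
            t[1] += 1
        elif carrier:
            t[2] += 1
        else:
            t[3] += 1
    return [
        ContingencyResult(cancer_type=k, arm=arm, gene=gene, table=tuple(tables[k]))
        for k in sorted(tables)
    ]


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_exact_two_sided(
    table: tuple[int, int, int, int],
) -> tuple[float | None, float]:
    """Two-sided Fisher exact p and Haldane-corrected sample odds ratio.

    With margins fixed, the table is determined by its a-cell, which under
    the null follows Hypergeometric(N, a+b, a+c); p sums the probabilities
    of all support points whose probability is <= that of the observed
    table (within 1e-7 relative tolerance).  A zero margin makes the table
    degenerate: p = 1 and the odds ratio is undefined (None).
    """
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise AnalysisError("contingency counts must be nonnegative")
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return None, 1.0
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = range(lo, hi + 1)
    dist = hypergeom(n, row1, col1)
    probs = dist.pmf(list(support))
    p_obs = float(dist.pmf(a))
    p = float(probs[probs <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return _sample_odds_ratio(a, b, c, d), min(p, 1.0)


def classify_associations(
    results: Sequence[ContingencyResult],
    fdr_threshold: float = 0.05,
) -> list[ContingencyResult]:
    """Compute p/OR where missing, BH-adjust per (arm, gene), set direction."""
    for r in results:
        if r.p is None:
            r.odds_ratio, r.p = fisher_exact_two_sided(r.table)
    families: dict[tuple[str, str], list[ContingencyResult]] = {}
    for r in results:
        families.setdefault((r.arm, r.gene), []).append(r)
    for fam in families.values():
        fdrs = bh_adjust([r.p for r in fam])
        for r, q in zip(fam, fdrs):
            r.fdr = q
    for r in results:
        if (
            r.fdr is not None
            and r.fdr <= fdr_threshold
            and r.odds_ratio is not None
            and not math.isclose(r.odds_ratio, 1.0)
        ):
            r.direction = "co-occurrence" if r.odds_ratio > 1 else "mutual-exclusivity"
        else:
            r.direction = "none"
    return list(results)
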