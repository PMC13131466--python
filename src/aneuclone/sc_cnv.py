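"""Per-cell arm-deletion fractions and genome-wide aneuploidy burden.

All quantities are length-weighted over the *segmented* (covered) portion
of the genome, never over nominal chromosome lengths: a cell's arm-deletion
fraction is the fraction of that arm's segmented length in a deletion-like
state (copy number <= 1 by default), and the burden summaries measure the
fraction of segmented genome at least one copy below/above the cell's
baseline ploidy.  Baseline ploidy is the segment-length-weighted lower
median copy-number state, so it is always an attained integer state (~2 in
diploid cells, ~4 after whole-genome doubling).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import AnalysisError
from .genome_io import ArmRecord, GenomeArmMap, SegmentProfile

__all__ = [
    "CellArmStats",
    "CellBurden",
    "arm_deletion_fraction",
    "call_arm_deletion",
    "cell_fraction_report",
    "baseline_cn",
    "genome_burden",
    "classify_states_absolute",
    "cell_burden_table",
]


@dataclass
class CellArmStats:
    cell_id: str
    region: str
    covered_length: int
    deleted_length: int
    deleted_fraction: float | None  # None when no segment covers the region
    called_deleted: bool | None = None

    @property
    def defined(self) -> bool:
        return self.deleted_fraction is not None


@dataclass
class CellBurden:
    cell_id: str
    baseline_cn: int
    loss_fraction: float
    gain_fraction: float
    altered_fraction: float
    median_deviation: float
    wgd_like: bool
    del13: bool | None = None
    del17: bool | None = None


def _clip_segments(
    profile: SegmentProfile, region: ArmRecord
) -> list[tuple[int, int, int]]:
    """Segments intersected with the region, as (start, end, cn)."""
    out = []
    for chrom, start, end, cn in profile.segments:
        if chrom != region.chrom:
            continue
        s, e = max(start, region.start), min(end, region.end)
        if e > s:
            out.append((s, e, cn))
    return out


def arm_deletion_fraction(
    profile: SegmentProfile,
    arms: GenomeArmMap,
    region: str,
    cn_cutoff: int = 1,
) -> CellArmStats:
    """Fraction of a region's segmented length in a deletion-like state.

    The denominator is the covered (segmented) length within the region;
    the numerator is the covered length with cn <= cn_cutoff.  If nothing
    covers the region the fraction is undefined (None), not an error.
    """
    rec = arms.region(region)
    clipped = _clip_segments(profile, rec)
    covered = sum(e - s for s, e, _ in clipped)
    deleted = sum(e - s for s, e, cn in clipped if cn <= cn_cutoff)
    fraction = deleted / covered if covered > 0 else None
    return CellArmStats(profile.cell_id, region, covered, deleted, fraction)


def call_arm_deletion(stats: CellArmStats, threshold: float = 0.5) -> CellArmStats:
    """Label the region deleted if the fraction meets the threshold (>=).

    An undefined fraction yields called_deleted = False (the flag is
    visible through ``stats.defined``).
    """
    if stats.deleted_fraction is None:
        return replace(stats, called_deleted=False)
    return replace(stats, called_deleted=stats.deleted_fraction >= threshold)


def cell_fraction_report(
    cells: Sequence[CellArmStats],
    thresholds: Sequence[float] = (0.25, 0.5),
) -> dict[float, dict]:
    """Per-threshold counts of cells meeting the deletion fraction.

    Returns {threshold: {"count": k, "total": n, "percent": 100*k/n,
    "display": "xx.x%"}}.  Cells with undefined fractions count in the
    total but can never meet a threshold.
    """
    if not cells:
        raise AnalysisError("cell_fraction_report: empty cell list")
    total = len(cells)
    report: dict[float, dict] = {}
    for thr in thresholds:
        count = sum(
            1 for c in cells if c.deleted_fraction is not None and c.deleted_fraction >= thr
        )
        pct = 100.0 * count / total
        report[thr] = {
            "count": count,
            "total": total,
            "percent": pct,
            "display": f"{pct:.1f}%",
        }
    return report


def _weighted_lower_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Smallest value whose cumulative weight reaches >= 50% of the total."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    idx = int(np.searchsorted(cum, 0.5 * cum[-1]))
    return float(v[idx])


def baseline_cn(profile: SegmentProfile) -> int:
    """Cell ploidy: segment-length-weighted lower median copy-number state."""
    if not profile.segments:
        raise AnalysisError(f"cell {profile.cell_id}: empty profile")
    cn = np.array([s[3] for s in profile.segments], dtype=float)
    lengths = np.array([s[2] - s[1] for s in profile.segments], dtype=float)
    return int(_weighted_lower_median(cn, lengths))


def genome_burden(profile: SegmentProfile, wgd_baseline_min: int = 3) -> CellBurden:
    """Genome-wide aneuploidy burden relative to the cell's own baseline.

    loss/gain fractions are length-weighted fractions of segmented genome
    with cn at least one below/above baseline; median_deviation is the
    length-weighted lower median of |cn - baseline| over altered segments
    (0 when nothing is altered); wgd_like flags baseline >= wgd_baseline_min.
    """
    base = baseline_cn(profile)
    cn = np.array([s[3] for s in profile.segments], dtype=float)
    lengths = np.array([s[2] - s[1] for s in profile.segments], dtype=float)
    total = lengths.sum()
    loss = lengths[cn <= base - 1].sum() / total
    gain = lengths[cn >= base + 1].sum() / total
    altered = cn != base
    if altered.any():
        dev = _weighted_lower_median(np.abs(cn - base)[altered], lengths[altered])
    else:
        dev = 0.0
    return CellBurden(
        cell_id=profile.cell_id,
        baseline_cn=base,
        loss_fraction=float(loss),
        gain_fraction=float(gain),
        altered_fraction=float(loss + gain),
        median_deviation=dev,
        wgd_like=base >= wgd_baseline_min,
    )


def classify_states_absolute(profile: SegmentProfile) -> tuple[float, float]:
    """Megabases of deletion-like (cn <= 1) and gain-like (cn >= 3) genome.

    This is the absolute-state summary (independent of baseline): in HMM
    state language, states 1-2 are deletions and states 4+ are gains, i.e.
    copies <= 1 and copies >= 3.
    """
    if not profile.segments:
        raise AnalysisError(f"cell {profile.cell_id}: empty profile")
    cnd = sum(e - s for _, s, e, cn in profile.segments if cn <= 1) / 1e6
    gain = sum(e - s for _, s, e, cn in profile.segments if cn >= 3) / 1e6
    return cnd, gain


def cell_burden_table(
    profiles: Iterable[SegmentProfile],
    arms: GenomeArmMap,
    regions: Sequence[str] = ("13q", "17q"),
    cn_cutoff: int = 1,
    call_threshold: float = 0.5,
    wgd_baseline_min: int = 3,
) -> list[CellBurden]:
    """Per-cell burden rows with chr13/chr17 deletion flags attached.

    The first region in ``regions`` fills ``del13`` and the second
    ``del17``; the region choice (q arm vs whole chromosome) is the
    caller's and is carried in pipeline metadata.
    """
    out = []
    for p in profiles:
        burden = genome_burden(p, wgd_baseline_min=wgd_baseline_min)
        calls = [
            call_arm_deletion(
                arm_deletion_fraction(p, arms, region, cn_cutoff=cn_cutoff),
                threshold=call_threshold,
            ).called_deleted
            for region in regions
        ]
        if len(calls) > 0:
            burden.del13 = bool(calls[0])
        if len(calls) > 1:
            burden.del17 = bool(calls[1])
        out.append(burden)
    return out
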