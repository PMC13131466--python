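"""Arm fractions, baseline ploidy and burden vs base-pair brute force."""

import numpy as np
import pytest

from aneuclone.errors import AnalysisError
from aneuclone.genome_io import SegmentProfile
from aneuclone.sc_cnv import (
    arm_deletion_fraction,
    baseline_cn,
    call_arm_deletion,
    cell_burden_table,
    cell_fraction_report,
    classify_states_absolute,
    genome_burden,
)
from conftest import brute_force_region_fraction


def split_segments(profile, pieces=3):
    """Split every segment into equal-cn adjacent pieces (merge invariance)."""
    segs = []
    for chrom, s, e, cn in profile.segments:
        cuts = np.linspace(s, e, pieces + 1).astype(int)
        cuts[0], cuts[-1] = s, e
        for a, b in zip(cuts, cuts[1:]):
            if b > a:
                segs.append((chrom, int(a), int(b), cn))
    return SegmentProfile(profile.cell_id, segs)


class TestArmDeletionFraction:
    def test_whole_region_deleted(self, toy_arms):
        p = SegmentProfile("c", [("chr17", 300, 1000, 1)])
        s = arm_deletion_fraction(p, toy_arms, "17q")
        assert s.deleted_fraction == 1.0 and s.covered_length == 700

    def test_half_deleted_half_gained(self, toy_arms):
        p = SegmentProfile(
            "c", [("chr17", 300, 650, 0), ("chr17", 650, 1000, 2)]
        )
        assert arm_deletion_fraction(p, toy_arms, "17q").deleted_fraction == 0.5

    def test_partial_coverage_uses_segmented_denominator(self, toy_arms):
        # 60% of the 700bp q arm covered; one third of covered length deleted
        p = SegmentProfile(
            "c",
            [
                ("chr17", 300, 440, 1),   # 140 deleted
                ("chr17", 500, 640, 2),   # 140 neutral
                ("chr17", 700, 840, 3),   # 140 gained
            ],
        )
        s = arm_deletion_fraction(p, toy_arms, "17q")
        assert s.covered_length == 420
        assert s.deleted_fraction == pytest.approx(1 / 3)
        ncov, ndel, frac = brute_force_region_fraction(p, toy_arms.region("17q"))
        assert (s.covered_length, s.deleted_length) == (ncov, ndel)
        assert s.deleted_fraction == pytest.approx(frac)

    def test_clipping_to_region_boundaries(self, toy_arms):
        p = SegmentProfile("c", [("chr17", 0, 1000, 1)])
        s = arm_deletion_fraction(p, toy_arms, "17p")
        assert s.covered_length == 300 and s.deleted_fraction == 1.0

    def test_uncovered_region_flagged_undefined(self, toy_arms):
        p = SegmentProfile("c", [("chr13", 0, 1000, 2)])
        s = arm_deletion_fraction(p, toy_arms, "17q")
        assert s.deleted_fraction is None and not s.defined
        assert call_arm_deletion(s).called_deleted is False

    def test_random_fixture_matches_brute_force(self, toy_arms):
        rng = np.random.default_rng(5)
        for _ in range(25):
            cuts = np.sort(rng.choice(np.arange(1, 1000), 6, replace=False))
            bounds = [0, *cuts.tolist(), 1000]
            segs = []
            for a, b in zip(bounds, bounds[1:]):
                if rng.random() < 0.7:  # leave gaps sometimes
                    segs.append(("chr17", a, b, int(rng.integers(0, 5))))
            if not segs:
                continue
            p = SegmentProfile("c", segs)
            for region in ("17p", "17q", "17"):
                s = arm_deletion_fraction(p, toy_arms, region)
                ncov, ndel, frac = brute_force_region_fraction(
                    p, toy_arms.region(region)
                )
                assert (s.covered_length, s.deleted_length) == (ncov, ndel)

    def test_merge_invariance(self, toy_arms):
        p = SegmentProfile(
            "c", [("chr17", 300, 650, 1), ("chr17", 650, 1000, 3)]
        )
        q = split_segments(p, 4)
        for region in ("17q", "17"):
            a = arm_deletion_fraction(p, toy_arms, region)
            b = arm_deletion_fraction(q, toy_arms, region)
            assert (a.covered_length, a.deleted_length) == (
                b.covered_length,
                b.deleted_length,
            )


class TestCallAndReport:
    def test_inclusive_threshold(self, toy_arms):
        s = arm_deletion_fraction(
            SegmentProfile("c", [("chr17", 300, 650, 1), ("chr17", 650, 1000, 2)]),
            toy_arms,
            "17q",
        )
        assert call_arm_deletion(s, 0.5).called_deleted is True
        assert call_arm_deletion(s, 0.5001).called_deleted is False
        assert call_arm_deletion(s, 0.25).called_deleted is True

    def _stats(self, fractions):
        return [
            type("S", (), {"deleted_fraction": f, "cell_id": str(i)})()
            for i, f in enumerate(fractions)
        ]

    def test_printed_count_reports(self):
        # 2321/2473 over 25%, 896/2473 over 50%
        fractions = [0.8] * 896 + [0.3] * (2321 - 896) + [0.1] * (2473 - 2321)
        report = cell_fraction_report(self._stats(fractions), [0.25, 0.5])
        assert report[0.25]["count"] == 2321
        assert report[0.25]["percent"] == pytest.approx(93.85, abs=0.005)
        assert round(report[0.25]["percent"]) == 94
        assert report[0.5]["count"] == 896
        assert report[0.5]["percent"] == pytest.approx(36.23, abs=0.005)
        # 826/990 over 25%
        fractions = [0.6] * 826 + [0.05] * (990 - 826)
        report = cell_fraction_report(self._stats(fractions), [0.25])
        assert report[0.25]["percent"] == pytest.approx(83.43, abs=0.005)
        assert report[0.25]["display"] == "83.4%"

    def test_zero_and_empty(self):
        report = cell_fraction_report(self._stats([0.0] * 100), [0.25])
        assert report[0.25]["percent"] == 0.0
        with pytest.raises(AnalysisError):
            cell_fraction_report([], [0.25])


class TestBaselineAndBurden:
    def test_uniform_diploid(self):
        p = SegmentProfile("c", [("chr1", 0, 1000, 2)])
        assert baseline_cn(p) == 2
        b = genome_burden(p)
        assert (b.loss_fraction, b.gain_fraction, b.median_deviation) == (0, 0, 0)
        assert not b.wgd_like

    def test_majority_tetraploid(self):
        p = SegmentProfile("c", [("chr1", 0, 600, 4), ("chr1", 600, 1000, 2)])
        assert baseline_cn(p) == 4
        assert genome_burden(p).wgd_like

    def test_lower_median_convention_on_even_split(self):
        p = SegmentProfile("c", [("chr1", 0, 500, 2), ("chr1", 500, 1000, 3)])
        assert baseline_cn(p) == 2

    def test_mixed_burden_fixture_vs_brute_force(self):
        # baseline 2; 10% at cn 0, 20% at cn 3
        p = SegmentProfile(
            "c",
            [
                ("chr1", 0, 100, 0),
                ("chr1", 100, 800, 2),
                ("chr1", 800, 1000, 3),
            ],
        )
        b = genome_burden(p)
        assert b.baseline_cn == 2
        assert b.loss_fraction == pytest.approx(0.1)
        assert b.gain_fraction == pytest.approx(0.2)
        assert b.altered_fraction == pytest.approx(0.3)
        assert b.median_deviation == 1.0
        # per-base oracle
        base = np.concatenate([np.full(100, 0), np.full(700, 2), np.full(200, 3)])
        assert b.loss_fraction == (base <= 1).mean()
        assert b.gain_fraction == (base >= 3).mean()

    def test_all_tetraploid_cell(self):
        p = SegmentProfile("c", [("chr1", 0, 1000, 4)])
        b = genome_burden(p)
        assert b.baseline_cn == 4 and b.altered_fraction == 0 and b.wgd_like

    def test_doubling_preserves_relative_classification(self):
        p = SegmentProfile(
            "c",
            [("chr1", 0, 100, 1), ("chr1", 100, 800, 2), ("chr1", 800, 1000, 3)],
        )
        doubled = SegmentProfile(
            "c", [(c, s, e, 2 * cn) for c, s, e, cn in p.segments]
        )
        a, b = genome_burden(p), genome_burden(doubled)
        assert (a.loss_fraction, a.gain_fraction) == (b.loss_fraction, b.gain_fraction)
        assert b.baseline_cn == 2 * a.baseline_cn and b.wgd_like and not a.wgd_like

    def test_merge_invariance_of_burden(self):
        p = SegmentProfile(
            "c", [("chr1", 0, 400, 1), ("chr1", 400, 1000, 2), ("chr2", 0, 500, 3)]
        )
        q = split_segments(p, 5)
        a, b = genome_burden(p), genome_burden(q)
        assert (a.baseline_cn, a.loss_fraction, a.gain_fraction, a.median_deviation) == (
            b.baseline_cn,
            b.loss_fraction,
            b.gain_fraction,
            b.median_deviation,
        )

    def test_empty_profile_is_an_error(self):
        with pytest.raises(AnalysisError):
            baseline_cn(SegmentProfile("c", []))


class TestClassifyStatesAbsolute:
    def test_simple_megabase_accounting(self):
        p = SegmentProfile(
            "c",
            [
                ("chr1", 0, 10_000_000, 1),
                ("chr1", 10_000_000, 90_000_000, 2),
                ("chr2", 0, 5_000_000, 3),
            ],
        )
        cnd, gain = classify_states_absolute(p)
        assert cnd == pytest.approx(10.0)
        assert gain == pytest.approx(5.0)

    def test_mixed_fixture_matches_brute_force(self):
        rng = np.random.default_rng(9)
        bounds = [0, *np.sort(rng.choice(np.arange(1, 2000), 8, False)).tolist(), 2000]
        segs = [
            ("chr1", a, b, int(rng.integers(0, 6))) for a, b in zip(bounds, bounds[1:])
        ]
        p = SegmentProfile("c", segs)
        cnd, gain = classify_states_absolute(p)
        per_base = np.concatenate([np.full(e - s, cn) for _, s, e, cn in segs])
        assert cnd * 1e6 == (per_base <= 1).sum()
        assert gain * 1e6 == (per_base >= 3).sum()


class TestBurdenTable:
    def test_region_flags_attached(self, toy_arms):
        p1 = SegmentProfile(
            "a", [("chr13", 0, 1000, 2), ("chr17", 0, 300, 2), ("chr17", 300, 1000, 1)]
        )
        p2 = SegmentProfile("b", [("chr13", 0, 1000, 2), ("chr17", 0, 1000, 2)])
        rows = cell_burden_table([p1, p2], toy_arms, regions=("13q", "17q"))
        by_id = {r.cell_id: r for r in rows}
        assert by_id["a"].del17 and not by_id["a"].del13
        assert not by_id["b"].del17 and not by_id["b"].del13
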