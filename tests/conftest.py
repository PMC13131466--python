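import pytest

from aneuclone.genome_io import ArmRecord, GenomeArmMap, SegmentProfile


@pytest.fixture
def toy_arms() -> GenomeArmMap:
    """Two-chromosome arm map with small coordinates for brute-force checks."""
    return GenomeArmMap(
        [
            ArmRecord("chr13", "p", 0, 400),
            ArmRecord("chr13", "q", 400, 1000),
            ArmRecord("chr17", "p", 0, 300),
            ArmRecord("chr17", "q", 300, 1000),
        ]
    )


@pytest.fixture
def diploid_profile() -> SegmentProfile:
    return SegmentProfile(
        "cell_a",
        [("chr13", 0, 1000, 2), ("chr17", 0, 1000, 2)],
    )


def brute_force_region_fraction(profile, region, cn_cutoff=1):
    """Per-base-pair oracle for deletion fraction over a region."""
    import numpy as np

    covered = np.zeros(region.end - region.start, dtype=bool)
    deleted = np.zeros(region.end - region.start, dtype=bool)
    for chrom, s, e, cn in profile.segments:
        if chrom != region.chrom:
            continue
        lo, hi = max(s, region.start), min(e, region.end)
        if hi > lo:
            covered[lo - region.start : hi - region.start] = True
            if cn <= cn_cutoff:
                deleted[lo - region.start : hi - region.start] = True
    ncov = int(covered.sum())
    return ncov, int(deleted.sum()), (deleted.sum() / ncov if ncov else None)
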