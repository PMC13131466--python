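"""Readers/writers for the external formats and the shared data model.

Formats
-------
- chromosome-arm definitions: BED4 (0-based half-open), name column like
  ``13q`` / ``17p``;
- segmented copy-number profiles: SEG-dialect TSV with columns
  ``cell_id, chrom, start, end, cn`` (1-based inclusive on disk);
- cohort tables: TSV with ``sample_id, cancer_type, <arm columns>, wgd,
  gbrca1, gbrca2``;
- cell phylogenies: Newick.

In memory every interval is 0-based half-open so ``length == end - start``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "ArmRecord",
    "GenomeArmMap",
    "CohortRecord",
    "SegmentProfile",
    "read_arm_bed",
    "write_arm_bed",
    "read_segments",
    "write_segments",
    "read_cohort_table",
    "write_cohort_table",
    "cohort_to_frame",
    "read_newick",
    "write_newick",
    "bundled_arm_map",
]

_ARM_LABELS = ("p", "q", "whole")


@dataclass(frozen=True)
class ArmRecord:
    chrom: str
    arm: str  # "p" | "q" | "whole"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.arm not in _ARM_LABELS:
            raise ValidationError(f"arm label must be p/q/whole, got {self.arm!r}")
        if self.end <= self.start:
            raise ValidationError(
                f"arm {self.name}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        base = self.chrom[3:] if self.chrom.startswith("chr") else self.chrom
        return base if self.arm == "whole" else f"{base}{self.arm}"


class GenomeArmMap:
    """Chromosome-arm coordinate table defining analysis denominators.

    Arms are addressable by short name (``"13q"``, ``"17p"``) and whole
    chromosomes by ``"13"`` or ``"chr13"``.  ``whole`` records span the
    union of that chromosome's arms and are synthesized on construction
    when absent.
    """

    def __init__(self, records: Iterable[ArmRecord], synthesize_whole: bool = True):
        recs = list(records)
        by_chrom: dict[str, list[ArmRecord]] = {}
        for r in recs:
            by_chrom.setdefault(r.chrom, []).append(r)
        # validate non-overlap of p/q per chromosome
        for chrom, rs in by_chrom.items():
            arms = sorted((r for r in rs if r.arm != "whole"), key=lambda r: r.start)
            for a, b in zip(arms, arms[1:]):
                if b.start < a.end:
                    raise ValidationError(
                        f"overlapping arm records on {chrom}: {a.name} and {b.name}"
                    )
        if synthesize_whole:
            for chrom, rs in list(by_chrom.items()):
                if any(r.arm == "whole" for r in rs):
                    continue
                arms = [r for r in rs if r.arm != "whole"]
                if arms:
                    whole = ArmRecord(
                        chrom,
                        "whole",
                        min(r.start for r in arms),
                        max(r.end for r in arms),
                    )
                    rs.append(whole)
                    recs.append(whole)
        self.records: list[ArmRecord] = recs
        self._index: dict[str, ArmRecord] = {}
        for r in recs:
            self._index[r.name] = r
            if r.arm == "whole":
                self._index.setdefault("chr" + r.name, r)
                self._index.setdefault(r.chrom, r)

    def region(self, name: str) -> ArmRecord:
        """Resolve a region name like ``"17q"`` or ``"chr13"``."""
        try:
            return self._index[name]
        except KeyError:
            raise ValidationError(f"region {name!r} not present in arm map") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __len__(self) -> int:
        return len(self.records)

    def arm_names(self, include_whole: bool = False) -> list[str]:
        return [r.name for r in self.records if include_whole or r.arm != "whole"]

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.chrom)
        return list(seen)


@dataclass
class CohortRecord:
    """One tumor sample with per-arm CNV calls and germline/WGD flags.

    Arm calls use the conventional encoding -1 (loss) / 0 (neutral) /
    +1 (gain); a deletion always means call == -1.
    """

    sample_id: str
    cancer_type: str
    arm_call: dict[str, int]
    wgd: bool
    gbrca1: bool
    gbrca2: bool

    def __post_init__(self) -> None:
        for arm, call in self.arm_call.items():
            if call not in (-1, 0, 1):
                raise ValidationError(
                    f"sample {self.sample_id}: call {call!r} for arm {arm} "
                    "outside {-1, 0, 1}"
                )


@dataclass
class SegmentProfile:
    """One cell's segmented integer copy-number genome.

    Segments are (chrom, start, end, cn) with 0-based half-open
    coordinates, sorted and non-overlapping within each chromosome.
    """

    cell_id: str
    segments: list[tuple[str, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s[0], s[1]))
        prev: dict[str, tuple[int, int]] = {}
        for chrom, start, end, cn in self.segments:
            if end <= start:
                raise ValidationError(
                    f"cell {self.cell_id}: segment {chrom}:{start}-{end} has end <= start"
                )
            if cn < 0:
                raise ValidationError(
                    f"cell {self.cell_id}: negative copy number {cn} at {chrom}:{start}"
                )
            if chrom in prev and start < prev[chrom][1]:
                raise ValidationError(
                    f"cell {self.cell_id}: overlapping segments on {chrom} "
                    f"at {start} (previous ends {prev[chrom][1]})"
                )
            prev[chrom] = (start, end)

    @property
    def total_length(self) -> int:
        return sum(e - s for _, s, e, _ in self.segments)


# ---------------------------------------------------------------------------
# arm BED


def read_arm_bed(path: str | Path) -> GenomeArmMap:
    """Parse a BED4 file of chromosome arms into a validated GenomeArmMap.

    Whole-chromosome records are synthesized per chromosome.  An empty file
    yields an empty map.
    """
    records: list[ArmRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 BED columns, got {len(parts)}")
            chrom, start_s, end_s, name = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            arm = name[-1]
            if arm not in ("p", "q"):
                raise FormatError(
                    f"{path}:{lineno}: arm name {name!r} must end in 'p' or 'q'"
                )
            try:
                records.append(ArmRecord(chrom, arm, start, end))
            except ValidationError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    try:
        return GenomeArmMap(records)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_arm_bed(arms: GenomeArmMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in sorted(
            (r for r in arms.records if r.arm != "whole"),
            key=lambda r: (r.chrom, r.start),
        ):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


def bundled_arm_map() -> GenomeArmMap:
    """The hg19-style chromosome-arm table shipped with the package.

    Boundaries are approximate centromere positions; treat the map as a
    convenience default, not an authority — analyses accept any BED.
    """
    from importlib.resources import files

    data = files("aneuclone").joinpath("data/hg19_arms.bed").read_text()
    records = []
    for line in data.strip().splitlines():
        chrom, start, end, name = line.split("\t")
        records.append(ArmRecord(chrom, name[-1], int(start), int(end)))
    return GenomeArmMap(records)


# ---------------------------------------------------------------------------
# SEG-dialect segment tables

_SEG_COLUMNS = ["cell_id", "chrom", "start", "end", "cn"]


def read_segments(path: str | Path, cn_encoding: str = "copies") -> list[SegmentProfile]:
    """Read a SEG-dialect TSV of per-cell copy-number segments.

    On disk coordinates are 1-based inclusive; in memory they become
    0-based half-open.  ``cn_encoding`` must be declared by the caller:
    ``"copies"`` takes the cn column at face value, ``"state"`` maps an
    HMM state k to k - 1 copies (so states 1 and 2 become 0 and 1 copies,
    the deletion-like states).
    """
    if cn_encoding not in ("copies", "state"):
        raise ValueError(f"cn_encoding must be 'copies' or 'state', got {cn_encoding!r}")
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "chrom": str})
    missing = [c for c in _SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    cn = df["cn"].to_numpy()
    if cn_encoding == "state":
        cn = cn - 1
    if (cn < 0).any():
        bad = df.loc[cn < 0].iloc[0]
        raise ValidationError(
            f"{path}: negative copy number after state mapping for cell "
            f"{bad['cell_id']} at {bad['chrom']}:{bad['start']}"
        )
    profiles: list[SegmentProfile] = []
    for cell_id, grp in df.assign(cn=cn).groupby("cell_id", sort=True):
        segments = [
            (row.chrom, int(row.start) - 1, int(row.end), int(row.cn))
            for row in grp.itertuples()
        ]
        profiles.append(SegmentProfile(str(cell_id), segments))
    return profiles


def write_segments(profiles: Sequence[SegmentProfile], path: str | Path) -> None:
    """Write profiles in the 1-based-inclusive SEG dialect (copies encoding)."""
    rows = []
    for p in profiles:
        for chrom, start, end, cn in p.segments:
            rows.append((p.cell_id, chrom, start + 1, end, cn))
    pd.DataFrame(rows, columns=_SEG_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort tables

_COHORT_FIXED = ["sample_id", "cancer_type", "wgd", "gbrca1", "gbrca2"]
_TRUTHY = {"1", "true", "t", "yes"}
_FALSY = {"0", "false", "f", "no"}


def _parse_bool(value, column: str, sample: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise FormatError(f"sample {sample}: cannot parse boolean {column}={value!r}")


def read_cohort_table(path: str | Path) -> list[CohortRecord]:
    """Read a cohort TSV; every non-fixed column is an arm-call column."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cancer_type": str})
    missing = [c for c in _COHORT_FIXED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"{path}: duplicate sample_id {dup.iloc[0]!r}")
    arm_cols = [c for c in df.columns if c not in _COHORT_FIXED]
    records = []
    for d in df.to_dict("records"):
        sid = str(d["sample_id"])
        calls = {}
        for c in arm_cols:
            call = int(d[c])
            if call not in (-1, 0, 1):
                raise ValidationError(
                    f"{path}: sample {sid}: arm call {c}={d[c]!r} outside {{-1,0,1}}"
                )
            calls[c] = call
        records.append(
            CohortRecord(
                sample_id=sid,
                cancer_type=str(d["cancer_type"]),
                arm_call=calls,
                wgd=_parse_bool(d["wgd"], "wgd", sid),
                gbrca1=_parse_bool(d["gbrca1"], "gbrca1", sid),
                gbrca2=_parse_bool(d["gbrca2"], "gbrca2", sid),
            )
        )
    return records


def cohort_to_frame(cohort: Sequence[CohortRecord]) -> pd.DataFrame:
    arm_cols: list[str] = []
    for rec in cohort:
        for a in rec.arm_call:
            if a not in arm_cols:
                arm_cols.append(a)
    rows = []
    for rec in cohort:
        row = {
            "sample_id": rec.sample_id,
            "cancer_type": rec.cancer_type,
            **{a: rec.arm_call.get(a, 0) for a in arm_cols},
            "wgd": int(rec.wgd),
            "gbrca1": int(rec.gbrca1),
            "gbrca2": int(rec.gbrca2),
        }
        rows.append(row)
    cols = ["sample_id", "cancer_type", *arm_cols, "wgd", "gbrca1", "gbrca2"]
    return pd.DataFrame(rows, columns=cols)


def write_cohort_table(cohort: Sequence[CohortRecord], path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick trees


def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a rooted Newick tree and normalize it for downstream analysis.

    Missing branch lengths default to 1; polytomies are resolved into
    binary nodes by inserting zero-length branches in input order;
    duplicate tip labels are an error.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        if "uplicate" in str(exc):
            raise ValidationError(f"{path}: duplicate tip label") from None
        raise FormatError(f"{path}: cannot parse Newick: {exc}") from None
    return normalize_tree(tree, source=str(path))


def parse_newick_string(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        if "uplicate" in str(exc):
            raise ValidationError("duplicate tip label") from None
        raise FormatError(f"cannot parse Newick: {exc}") from None
    return normalize_tree(tree, source="<string>")


def normalize_tree(tree: dendropy.Tree, source: str = "<tree>") -> dendropy.Tree:
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        seen: set[str] = set()
        dup = next(l for l in labels if l in seen or seen.add(l))  # type: ignore[func-returns-value]
        raise ValidationError(f"{source}: duplicate tip label {dup!r}")
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0 if edge.head_node is tree.seed_node else 1.0
        elif edge.length < 0:
            raise ValidationError(f"{source}: negative branch length {edge.length}")
    tree.resolve_polytomies(limit=2, update_bipartitions=False)
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))


def tree_tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]
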