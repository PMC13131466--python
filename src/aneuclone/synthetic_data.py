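"""Synthetic cohorts and single-cell populations for end-to-end testing.

Restricted-access inputs (large clinical CNV cohorts; single-cell WGS with
inferred phylogenies) are emulated by two generators:

* ``simulate_cohort`` draws per-sample arm-deletion calls, WGD flags and
  germline carrier flags per cancer type, with a configurable odds ratio
  linking an arm's deletion to a carrier gene (the 2x2 joint is solved
  from its margins and the odds ratio, the Plackett construction).

* ``simulate_yule_tree`` + ``simulate_cell_profiles`` grow a pure-birth
  cell phylogeny and place arm-deletion events on it under three clonal
  architectures: a single inherited event on an internal branch
  ("clonal"), independent terminal-branch events ("dispersed"), or a
  single affected tip ("sparse"), with optional background copy-number
  noise and whole-genome doubling of one clade.

All randomness flows from a single integer seed through named streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from . import rng as rngmod
from .errors import AnalysisError, ValidationError
from .genome_io import ArmRecord, CohortRecord, GenomeArmMap, SegmentProfile

__all__ = [
    "CohortTypeConfig",
    "CohortSimConfig",
    "CellSimConfig",
    "solve_joint_from_or",
    "simulate_cohort",
    "simulate_yule_tree",
    "simulate_cell_profiles",
]


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortTypeConfig:
    """Generation parameters for one cancer type."""

    name: str
    n_samples: int
    prevalence: dict[str, float]  # arm -> P(deletion)
    wgd_rate: float = 0.0
    carrier_rate: dict[str, float] = field(default_factory=dict)  # gene -> P(carrier)
    cooccurrence_or: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for arm, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"type {self.name}: prevalence({arm})={p} outside [0,1]")
        if not 0.0 <= self.wgd_rate <= 1.0:
            raise ValidationError(f"type {self.name}: wgd_rate outside [0,1]")
        for gene, p in self.carrier_rate.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"type {self.name}: carrier_rate({gene}) outside [0,1]")
        for key, theta in self.cooccurrence_or.items():
            if not (math.isfinite(theta) and theta > 0):
                raise ValidationError(f"type {self.name}: odds ratio for {key} must be finite > 0")


@dataclass
class CohortSimConfig:
    types: list[CohortTypeConfig]
    seed: int = 0


def solve_joint_from_or(p_del: float, p_car: float, theta: float) -> float:
    """P(deletion AND carrier) for given margins and odds ratio.

    Solves theta = p11 p00 / (p10 p01) with the stated margins; for
    theta = 1 this is the independent product.  The solution is the root
    of a quadratic lying in the Frechet interval
    [max(0, p_del + p_car - 1), min(p_del, p_car)].
    """
    lo, hi = max(0.0, p_del + p_car - 1.0), min(p_del, p_car)
    if abs(theta - 1.0) < 1e-12 or p_del in (0.0, 1.0) or p_car in (0.0, 1.0):
        return p_del * p_car
    a = theta - 1.0
    b = -((theta - 1.0) * (p_del + p_car) + 1.0)
    c = theta * p_del * p_car
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise AnalysisError(
            f"no 2x2 joint with margins ({p_del}, {p_car}) and odds ratio {theta}"
        )
    sq = math.sqrt(disc)
    for p11 in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
        if lo - 1e-12 <= p11 <= hi + 1e-12:
            return min(max(p11, lo), hi)
    raise AnalysisError(
        f"no feasible 2x2 joint with margins ({p_del}, {p_car}) and odds ratio {theta}"
    )


def simulate_cohort(config: CohortSimConfig) -> list[CohortRecord]:
    """Draw a multi-type cohort of per-sample arm calls and flags.

    Carrier flags are drawn first; an arm linked to a gene through
    ``cooccurrence_or`` is then drawn conditionally on that carrier flag so
    the population 2x2 table has the configured odds ratio.  Each arm may
    be linked to at most one gene.  WGD flags are independent Bernoulli.
    """
    records: list[CohortRecord] = []
    for tc in config.types:
        rng = rngmod.stream(config.seed, f"cohort:{tc.name}")
        n = tc.n_samples
        genes = sorted(tc.carrier_rate)
        carrier = {g: rng.random(n) < tc.carrier_rate[g] for g in genes}
        arm_gene: dict[str, str] = {}
        for (arm, gene), theta in tc.cooccurrence_or.items():
            if arm in arm_gene:
                raise AnalysisError(
                    f"type {tc.name}: arm {arm} linked to multiple genes "
                    f"({arm_gene[arm]}, {gene}); one odds ratio per arm"
                )
            if gene not in tc.carrier_rate:
                raise AnalysisError(
                    f"type {tc.name}: odds ratio references gene {gene} "
                    "with no carrier_rate"
                )
            arm_gene[arm] = gene
        calls: dict[str, np.ndarray] = {}
        for arm in sorted(tc.prevalence):
            p = tc.prevalence[arm]
            if arm in arm_gene:
                gene = arm_gene[arm]
                q = tc.carrier_rate[gene]
                theta = tc.cooccurrence_or[(arm, gene)]
                try:
                    p11 = solve_joint_from_or(p, q, theta)
                except AnalysisError as exc:
                    raise AnalysisError(f"type {tc.name}, arm {arm}, gene {gene}: {exc}")
                p_given_car = p11 / q if q > 0 else p
                p_given_non = (p - p11) / (1 - q) if q < 1 else p
                u = rng.random(n)
                calls[arm] = np.where(
                    carrier[gene], u < p_given_car, u < p_given_non
                )
            else:
                calls[arm] = rng.random(n) < p
        wgd = rng.random(n) < tc.wgd_rate
        for i in range(n):
            records.append(
                CohortRecord(
                    sample_id=f"{tc.name}_{i:06d}",
                    cancer_type=tc.name,
                    arm_call={a: -1 if calls[a][i] else 0 for a in calls},
                    wgd=bool(wgd[i]),
                    gbrca1=bool(carrier.get("BRCA1", np.zeros(n, bool))[i]),
                    gbrca2=bool(carrier.get("BRCA2", np.zeros(n, bool))[i]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Yule tree simulation


def simulate_yule_tree(n_tips: int, birth_rate: float, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree on ``n_tips`` extant cells.

    Starting from one lineage, each of the k active lineages splits after
    an exponential wait with total rate k * birth_rate; once n_tips
    lineages exist a final Exp(n * birth_rate) interval runs to the
    present, where all tips are sampled.
    """
    if n_tips < 2:
        raise AnalysisError("simulate_yule_tree: n_tips must be >= 2")
    if birth_rate <= 0:
        raise AnalysisError("simulate_yule_tree: birth_rate must be > 0")
    rng = rngmod.stream(seed, "yule")
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = [(tree.seed_node, 0.0)]
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        node, born = active.pop(idx)
        node.edge.length = t - born
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    for i, (node, born) in enumerate(active):
        node.edge.length = t - born
        node.taxon = taxa.new_taxon(label=f"cell_{i + 1:04d}")
    tree.seed_node.edge.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# single-cell copy-number simulation


@dataclass
class CellSimConfig:
    """Generation parameters for a simulated single-cell population.

    ``event_fraction_range`` is the (uniform) range of the fraction of the
    target region removed by one deletion event; the default (0.6, 1.0)
    keeps every event above the 50% calling threshold so truth recovery is
    exact when background noise is off.  ``dispersed_event_rate`` is the
    per-unit-branch-length rate of independent terminal-branch deletions
    in the dispersed scenario (a tip is affected with probability
    1 - exp(-rate * pendant_branch_length)).
    """

    n_tips: int = 100
    birth_rate: float = 1.0
    scenario: str = "clonal"  # "clonal" | "dispersed" | "sparse"
    target_region: str = "17q"
    event_fraction_range: tuple[float, float] = (0.6, 1.0)
    background_event_rate: float = 0.0
    dispersed_event_rate: float = 0.6
    wgd_tips_fraction: float = 0.0
    genome: GenomeArmMap | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValidationError("n_tips must be >= 2")
        lo, hi = self.event_fraction_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValidationError("event_fraction_range must lie within (0, 1]")
        if self.scenario not in ("clonal", "dispersed", "sparse"):
            raise ValidationError(f"unknown scenario {self.scenario!r}")


class _PiecewiseCN:
    """Integer copy number over one chromosome as breakpoints + values."""

    __slots__ = ("bounds", "cn")

    def __init__(self, start: int, end: int, cn: int = 2):
        self.bounds = [start, end]
        self.cn = [cn]

    def copy(self) -> "_PiecewiseCN":
        new = _PiecewiseCN.__new__(_PiecewiseCN)
        new.bounds = list(self.bounds)
        new.cn = list(self.cn)
        return new

    def _split_at(self, pos: int) -> None:
        import bisect

        i = bisect.bisect_left(self.bounds, pos)
        if i < len(self.bounds) and self.bounds[i] == pos:
            return
        self.bounds.insert(i, pos)
        self.cn.insert(i - 1, self.cn[i - 1])

    def apply_delta(self, start: int, end: int, delta: int) -> None:
        start = max(start, self.bounds[0])
        end = min(end, self.bounds[-1])
        if end <= start:
            return
        self._split_at(start)
        self._split_at(end)
        for i in range(len(self.cn)):
            if self.bounds[i] >= start and self.bounds[i + 1] <= end:
                self.cn[i] = max(0, self.cn[i] + delta)

    def double(self) -> None:
        self.cn = [2 * c for c in self.cn]

    def segments(self, chrom: str) -> list[tuple[str, int, int, int]]:
        return [
            (chrom, self.bounds[i], self.bounds[i + 1], self.cn[i])
            for i in range(len(self.cn))
        ]

    def fraction_at_most(self, start: int, end: int, cutoff: int) -> float:
        total = end - start
        hit = 0
        for i in range(len(self.cn)):
            s, e = max(self.bounds[i], start), min(self.bounds[i + 1], end)
            if e > s and self.cn[i] <= cutoff:
                hit += e - s
        return hit / total


def _clade_sizes(tree: dendropy.Tree) -> dict[dendropy.Node, int]:
    sizes: dict[dendropy.Node, int] = {}
    for node in tree.postorder_node_iter():
        sizes[node] = 1 if node.is_leaf() else sum(sizes[c] for c in node.child_nodes())
    return sizes


def _deletion_interval(
    region: ArmRecord, fraction: float, rng: np.random.Generator
) -> tuple[int, int]:
    length = max(1, int(round(fraction * region.length)))
    slack = region.length - length
    start = region.start + (int(rng.integers(slack + 1)) if slack > 0 else 0)
    return start, start + length


def simulate_cell_profiles(
    tree: dendropy.Tree, config: CellSimConfig
) -> tuple[list[SegmentProfile], dict[str, float]]:
    """Evolve copy-number profiles on a phylogeny and return them + truth.

    Every cell starts diploid over the genome map.  Deletion events
    decrement copy number by 1 (floor 0); background events (small
    deletions/gains on non-target chromosomes) arise as a Poisson process
    along branches and are inherited; optional WGD doubles all states of
    one clade of tips after events.  The truth map gives each cell's final
    deleted fraction (cn <= 1) of the target region.
    """
    genome = config.genome if config.genome is not None else _default_genome()
    if config.target_region not in genome:
        raise AnalysisError(f"target region {config.target_region!r} absent from genome map")
    target = genome.region(config.target_region)
    rng = rngmod.stream(config.seed, f"cells:{config.scenario}")

    tips = [leaf for leaf in tree.leaf_node_iter()]
    n = len(tips)
    sizes = _clade_sizes(tree)

    # events planned per node edge: list of (chrom, start, end, delta)
    events: dict[dendropy.Node, list[tuple[str, int, int, int]]] = {}

    def add_event(node: dendropy.Node, ev: tuple[str, int, int, int]) -> None:
        events.setdefault(node, []).append(ev)

    lo, hi = config.event_fraction_range
    if config.scenario == "clonal":
        internal = [
            nd
            for nd in tree.preorder_node_iter()
            if not nd.is_leaf() and nd is not tree.seed_node
        ]
        if not internal:  # 2-tip tree: fall back to the root's first child
            internal = [c for c in tree.seed_node.child_nodes() if not c.is_leaf()] or list(
                tree.seed_node.child_nodes()
            )
        host = min(internal, key=lambda nd: (abs(sizes[nd] - n / 4), id(nd)))
        frac = rng.uniform(lo, hi)
        s, e = _deletion_interval(target, frac, rng)
        add_event(host, (target.chrom, s, e, -1))
    elif config.scenario == "dispersed":
        for leaf in tips:
            b = leaf.edge.length or 0.0
            if rng.random() < 1.0 - math.exp(-config.dispersed_event_rate * b):
                frac = rng.uniform(lo, hi)
                s, e = _deletion_interval(target, frac, rng)
                add_event(leaf, (target.chrom, s, e, -1))
    else:  # sparse
        leaf = tips[int(rng.integers(n))]
        frac = rng.uniform(lo, hi)
        s, e = _deletion_interval(target, frac, rng)
        add_event(leaf, (target.chrom, s, e, -1))

    # background noise: small events on non-target chromosomes, inherited
    if config.background_event_rate > 0:
        bg_arms = [
            r
            for r in genome.records
            if r.arm != "whole" and r.chrom != target.chrom
        ]
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            b = node.edge.length or 0.0
            for _ in range(rng.poisson(config.background_event_rate * b)):
                arm = bg_arms[int(rng.integers(len(bg_arms)))]
                frac = rng.uniform(0.05, 0.3)
                s, e = _deletion_interval(arm, frac, rng)
                delta = -1 if rng.random() < 0.5 else +1
                add_event(node, (arm.chrom, s, e, delta))

    # WGD clade: pick the clade whose size is nearest the requested count
    wgd_tips: set[dendropy.Node] = set()
    if config.wgd_tips_fraction > 0:
        want = max(1, int(round(config.wgd_tips_fraction * n)))
        host = min(
            tree.preorder_node_iter(), key=lambda nd: (abs(sizes[nd] - want), id(nd))
        )
        wgd_tips = set(host.leaf_iter())

    # walk the tree, inheriting state
    chroms = {
        r.chrom: (r.start, r.end) for r in genome.records if r.arm == "whole"
    }
    states: dict[dendropy.Node, dict[str, _PiecewiseCN]] = {}
    root_state = {c: _PiecewiseCN(s, e) for c, (s, e) in chroms.items()}
    states[tree.seed_node] = root_state
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            state = states[node]
        else:
            state = {c: pw.copy() for c, pw in states[node.parent_node].items()}
            for chrom, s, e, delta in events.get(node, ()):
                state[chrom].apply_delta(s, e, delta)
            states[node] = state
        # free parent state once all children visited (keep memory modest)

    profiles: list[SegmentProfile] = []
    truth: dict[str, float] = {}
    for leaf in tips:
        state = states[leaf]
        if leaf in wgd_tips:
            state = {c: pw.copy() for c, pw in state.items()}
            for pw in state.values():
                pw.double()
        cell_id = leaf.taxon.label if leaf.taxon else f"tip_{id(leaf)}"
        segments: list[tuple[str, int, int, int]] = []
        for chrom in chroms:
            segments.extend(state[chrom].segments(chrom))
        profiles.append(SegmentProfile(cell_id, segments))
        truth[cell_id] = state[target.chrom].fraction_at_most(
            target.start, target.end, cutoff=1
        )
    return profiles, truth


def _default_genome() -> GenomeArmMap:
    from .genome_io import bundled_arm_map

    return bundled_arm_map()
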