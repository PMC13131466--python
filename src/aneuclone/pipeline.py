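"""End-to-end orchestration of the two analysis tracks.

Cohort track: per-arm prevalence (all samples and WGD-excluded) ->
pooled permutation test with BH FDR -> rank test for focal types ->
co-occurrence of each arm with its germline gene.

Cell track: per-cell arm-deletion fractions and calls for each target
region -> cell-fraction report at the 25%/50% thresholds -> per-cell
burden table -> Fritz-Purvis D per region (trait = called deletion at the
>= 50% rule) -> pooled HC3 burden regression.

Both tracks are driven by a plain dict (usually loaded from YAML), write a
bundle of JSON/TSV files plus a manifest, and are deterministic for a
fixed config: every stochastic stage derives its seed from the single
config seed, the manifest records those seeds, and outputs carry no
timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__, burden_regression, cooccurrence, phylosignal, prevalence, sc_cnv
from .errors import AnalysisError
from .genome_io import (
    bundled_arm_map,
    read_arm_bed,
    read_cohort_table,
    read_newick,
    read_segments,
)

__all__ = ["run_cohort_track", "run_cell_track", "load_config"]

log = logging.getLogger("aneuclone.pipeline")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _digest(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            k: _jsonable(v)
            for k, v in dataclasses.asdict(obj).items()
            if not k.startswith("_")
        }
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, float) and (np.isinf(obj) or np.isnan(obj)):
        return str(obj)
    return obj


def _write_json(data: Any, path: Path) -> None:
    path.write_text(json.dumps(_jsonable(data), indent=2, sort_keys=True) + "\n")


def _stage(name: str):
    """Decorator attaching the stage name to propagated errors."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except AnalysisError as exc:
                raise AnalysisError(f"[stage {name}] {exc}") from exc

        return inner

    return wrap


def run_cohort_track(config: Mapping[str, Any], outdir: str | Path) -> dict:
    """Prevalence -> permutation tests -> co-occurrence, from one config.

    Config keys: cohort (TSV path), arms (list of arm names), focal_types
    (list, for the rank test), arm_genes (map arm -> BRCA1/BRCA2 for
    co-occurrence), n_perm, seed, fdr_threshold.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    n_perm = int(config.get("n_perm", prevalence.DEFAULT_N_PERM))
    fdr_threshold = float(config.get("fdr_threshold", 0.05))
    arms = list(config["arms"])
    focal_types = list(config.get("focal_types", []))
    arm_genes = dict(config.get("arm_genes", {}))

    cohort = _stage("read-cohort")(read_cohort_table)(config["cohort"])
    bundle: dict[str, Any] = {"track": "cohort", "arms": {}}
    seeds: dict[str, int] = {}
    for arm in arms:
        arm_out: dict[str, Any] = {}
        for label, excl in (("all", False), ("non_wgd", True)):
            stage = f"pooled-perm:{arm}:{label}"
            seeds[stage] = seed
            results = _stage(stage)(prevalence.pooled_permutation_test)(
                cohort, arm, exclude_wgd=excl, n_perm=n_perm, seed=seed
            )
            arm_out[f"prevalence_{label}"] = [
                {
                    **dataclasses.asdict(r),
                    "p_display": prevalence.format_pvalue(r.p_perm, r.n_perm),
                }
                for r in results
            ]
        if focal_types:
            stage = f"rank-perm:{arm}"
            seeds[stage] = seed
            ranks = _stage(stage)(prevalence.rank_permutation_test)(
                cohort, arm, focal_types, n_perm=n_perm, seed=seed
            )
            arm_out["rank_test"] = [dataclasses.asdict(r) for r in ranks]
        if arm in arm_genes:
            stage = f"cooccur:{arm}"
            tables = _stage(stage)(cooccurrence.build_contingency)(
                cohort, arm, arm_genes[arm], by_type=True
            )
            classified = cooccurrence.classify_associations(tables, fdr_threshold)
            arm_out["cooccurrence"] = [dataclasses.asdict(r) for r in classified]
        bundle["arms"][arm] = arm_out

    _write_json(bundle, outdir / "report.json")
    manifest = {
        "config_digest": _digest(config),
        "package_version": __version__,
        "seeds": seeds,
        "inputs": {"cohort": str(config["cohort"])},
        "outputs": {"report": str(outdir / "report.json")},
    }
    _write_json(manifest, outdir / "manifest.json")
    bundle["manifest"] = manifest
    return bundle


def run_cell_track(config: Mapping[str, Any], outdir: str | Path) -> dict:
    """Arm fractions -> calls -> burden -> D statistic -> regression.

    Config keys: segments (SEG TSV path), cn_encoding, tree (Newick path),
    arms_bed (path; omitted -> bundled hg19-style map), regions (list),
    cn_cutoff, call_threshold, report_thresholds, n_perm, seed,
    wgd_baseline_min.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    n_perm = int(config.get("n_perm", 1000))
    regions = list(config.get("regions", ["13q", "17q"]))
    cn_cutoff = int(config.get("cn_cutoff", 1))
    call_threshold = float(config.get("call_threshold", 0.5))
    thresholds = list(config.get("report_thresholds", [0.25, 0.5]))
    wgd_min = int(config.get("wgd_baseline_min", 3))

    arms = (
        _stage("read-arms")(read_arm_bed)(config["arms_bed"])
        if config.get("arms_bed")
        else bundled_arm_map()
    )
    profiles = _stage("read-segments")(read_segments)(
        config["segments"], cn_encoding=config.get("cn_encoding", "copies")
    )
    tree = _stage("read-tree")(read_newick)(config["tree"])

    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    profile_ids = {p.cell_id for p in profiles}
    orphans = sorted(profile_ids - tip_labels)
    if orphans:
        log.warning(
            "%d cells present in segments but absent from tree; excluded from "
            "phylogenetic analysis: %s%s",
            len(orphans),
            orphans[:5],
            "..." if len(orphans) > 5 else "",
        )

    bundle: dict[str, Any] = {"track": "cell", "regions": {}}
    seeds: dict[str, int] = {}
    calc = phylosignal.PhyloDCalculator(tree)
    by_id = {p.cell_id: p for p in profiles}
    for region in regions:
        stats = [
            sc_cnv.arm_deletion_fraction(p, arms, region, cn_cutoff=cn_cutoff)
            for p in profiles
        ]
        report = _stage(f"fractions:{region}")(sc_cnv.cell_fraction_report)(
            stats, thresholds
        )
        calls = {
            s.cell_id: sc_cnv.call_arm_deletion(s, call_threshold) for s in stats
        }
        trait = {
            label: int(bool(calls[label].called_deleted)) if label in calls else 0
            for label in calc.tip_labels
        }
        region_out: dict[str, Any] = {
            "fraction_report": {str(k): v for k, v in report.items()},
            "deleted_tips": sorted(
                l for l, v in trait.items() if v == 1
            ),  # for external tree visualization
            "denominator": "segmented length of region "
            + region
            + f" (inclusive >= {call_threshold} call rule, cn <= {cn_cutoff})",
        }
        k_pos = sum(trait.values())
        if 0 < k_pos < calc.n_tips:
            stage = f"phylo-d:{region}"
            seeds[stage] = seed
            d_res = _stage(stage)(calc.phylo_d)(trait, n_perm=n_perm, seed=seed)
            region_out["d_stat"] = dataclasses.asdict(d_res)
        else:
            region_out["d_stat"] = None
            region_out["d_stat_note"] = "trait invariant (all tips share one state)"
        bundle["regions"][region] = region_out

    burdens = sc_cnv.cell_burden_table(
        profiles,
        arms,
        regions=tuple(regions[:2]) if len(regions) >= 2 else tuple(regions),
        cn_cutoff=cn_cutoff,
        call_threshold=call_threshold,
        wgd_baseline_min=wgd_min,
    )
    burden_rows = [dataclasses.asdict(b) for b in burdens]
    bundle["burden"] = burden_rows
    import pandas as pd

    pd.DataFrame(burden_rows).to_csv(outdir / "burden.tsv", sep="\t", index=False)
    try:
        fit = _stage("regression")(burden_regression.fit_burden_model)(burdens)
        bundle["regression"] = {
            "terms": fit.terms,
            "coefficients": fit.coefficients,
            "se_classical": fit.se_classical,
            "se_hc3": fit.se_hc3,
            "t_hc3": fit.t_hc3,
            "p_hc3": fit.p_hc3,
            "n": fit.n,
            "dropped_terms": fit.dropped_terms,
        }
    except AnalysisError as exc:
        # e.g. a single deletion-positive cell is perfectly leveraged; the
        # rest of the bundle is still useful, so record and continue
        log.warning("burden regression not estimable: %s", exc)
        bundle["regression"] = {"error": str(exc)}

    _write_json(
        {k: v for k, v in bundle.items() if k != "burden"}, outdir / "report.json"
    )
    manifest = {
        "config_digest": _digest(config),
        "package_version": __version__,
        "seeds": seeds,
        "inputs": {
            "segments": str(config["segments"]),
            "tree": str(config["tree"]),
            "arms_bed": str(config.get("arms_bed", "<bundled hg19-style>")),
        },
        "excluded_cells_not_in_tree": orphans,
        "outputs": {
            "report": str(outdir / "report.json"),
            "burden": str(outdir / "burden.tsv"),
        },
    }
    _write_json(manifest, outdir / "manifest.json")
    bundle["manifest"] = manifest
    return bundle
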