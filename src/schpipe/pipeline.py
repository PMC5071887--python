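"""End-to-end orchestration: simulate/load -> cluster -> SCHs -> characterize.

The analysis core (:func:`run_analysis`) is pure in-memory; the pipeline
wrapper (:func:`run_pipeline`) adds file I/O (persisted intermediates,
consolidated JSON report) around it.  All stage randomness (background
resampling) derives from the single run seed, so identical config + seed
reproduces the report byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .comut import (
    GeneClusterSet,
    MutationRecord,
    build_matrix,
    comutated_pairs,
    read_mutations,
    seed_cluster,
    select_threshold,
)
from .config import RunConfig, SyntheticConfig
from .ctcf import SignalTrack, compare_tss_signal, read_bedgraph
from .enrichment import (
    PathwayDB,
    driver_fraction,
    enrichment_fraction,
    pathway_coverage,
    read_driver_list,
    read_gmt,
)
from .errors import AnalysisError, SchpipeError
from .flanks import (
    conservation_background_test,
    extract_flanks,
    signature_conservation_correlation,
)
from .hic import (
    ContactMatrix,
    gene_level_background,
    hic_cluster_all,
    overall_background,
    proximity_test,
    read_contact_matrix,
)
from .io import read_annotation_bed, write_clusters_tsv, write_sch_table
from .sch import SCH, detect_schs, intra_inter_comparison, pair_f1
from .signatures import build_type_matrix, complementary_z_test, group_jaccard_report
from .synthetic import PlantedTruth, ReferenceView, simulate, write_dataset

log = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    """In-memory bundle of everything the analysis consumes."""

    records: list[MutationRecord]
    contact_maps: dict[str, ContactMatrix]
    annotation: pd.DataFrame
    reference: Any | None = None  # Mapping chrom -> sliceable sequence
    pathways: dict[str, set[str]] | None = None
    drivers: set[str] | None = None
    ctcf: SignalTrack | None = None
    truth: PlantedTruth | None = None


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_jsonable(v) for v in items]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def run_analysis(inputs: PipelineInputs, cfg: RunConfig, seed: int = 0) -> dict:
    """Run every analysis stage on in-memory inputs; returns the report dict.

    Stages whose preconditions fail on this dataset (for example too few
    SCHs for a Z-test) are reported as skipped with the reason rather than
    aborting the run.
    """
    report: dict[str, Any] = {"version": __version__, "seed": seed}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5C4]))

    # --- co-mutation (DB) clustering with threshold selection
    m = build_matrix(inputs.records)
    threshold, grid = select_threshold(
        m, inputs.contact_maps, inputs.annotation, cfg.threshold_grid, welch=cfg.welch
    )
    db = seed_cluster(m, threshold)
    report["db_clustering"] = {
        "threshold": threshold,
        "p_grid": {f"{r.threshold:.1f}": r.p for r in grid.itertuples(index=False)},
        "n_genes": len(m.gene_ids),
        "n_samples": m.n_sp,
        "n_clusters": len(db.clusters),
        "n_clusters_ge2": sum(1 for c in db.clusters if len(c) >= 2),
    }

    # --- proximity of co-mutated pairs vs distance backgrounds
    backgrounds = {
        chrom: (overall_background(cm), gene_level_background(cm, inputs.annotation))
        for chrom, cm in inputs.contact_maps.items()
    }
    try:
        prox = proximity_test(
            comutated_pairs(m), inputs.contact_maps, inputs.annotation, backgrounds
        )
        report["proximity"] = {
            "n_pairs": prox.n_pairs,
            "mean_comut": prox.mean_comut,
            "mean_overall_bkg": prox.mean_overall,
            "mean_gene_level_bkg": prox.mean_gene_level,
            "p_vs_overall": prox.p_vs_overall,
            "p_vs_gene_level": prox.p_vs_gene_level,
        }
    except AnalysisError as exc:
        report["proximity"] = {"skipped": str(exc)}

    # --- spatial (Hi-C) clustering
    hic = hic_cluster_all(
        inputs.contact_maps,
        inputs.annotation,
        cfg.hic_cutoff_policy,
        cfg.hic_cutoff_value,
    )
    report["hic_clustering"] = {
        "n_clusters": len(hic.clusters),
        "n_excluded_genes": len(hic.excluded),
    }

    # --- intra- vs inter-class contact comparison on the DB clusters
    try:
        ii = intra_inter_comparison(
            db, inputs.contact_maps, inputs.annotation,
            alpha=cfg.alpha_intra_inter, welch=cfg.welch,
        )
        report["intra_inter"] = {
            "p": ii.p,
            "mean_intra": ii.mean_intra,
            "mean_inter": ii.mean_inter,
            "alpha": cfg.alpha_intra_inter,
            "passed": ii.passed,
        }
    except AnalysisError as exc:
        report["intra_inter"] = {"skipped": str(exc)}

    # --- SCH detection
    schs = detect_schs(db, hic, inputs.annotation)
    sch_groups = [list(s.gene_ids) for s in schs]
    report["sch"] = {
        "n_schs": len(schs),
        "sizes": sorted((len(s.gene_ids) for s in schs), reverse=True),
    }
    if inputs.truth is not None:
        report["sch"]["pair_f1_vs_truth"] = pair_f1(
            sch_groups, inputs.truth.truth_groups()
        )

    # --- mutational signatures
    mtm = build_type_matrix(inputs.records, m.gene_ids)
    try:
        jac = group_jaccard_report(schs, db.clusters, hic.clusters, mtm)
        report["signatures"] = {
            "means": jac.means(),
            "p_vs_db": jac.p_vs_db,
            "p_vs_hic": jac.p_vs_hic,
            "p_vs_inter_sch": jac.p_vs_inter,
        }
    except AnalysisError as exc:
        report["signatures"] = {"skipped": str(exc)}
    try:
        comp = complementary_z_test(schs, mtm)
        report["complementing"] = {
            "background_score": comp.background_score,
            "mean_sch_score": float(np.mean(list(comp.sch_scores.values()))),
            "z": comp.z,
            "p": comp.p,
            "n_schs": len(comp.sch_scores),
        }
    except AnalysisError as exc:
        report["complementing"] = {"skipped": str(exc)}

    # --- flanking-sequence conservation
    if inputs.reference is not None:
        windows = extract_flanks(inputs.records, inputs.reference)
        gene_to_sch: dict[str, str] = {}
        for s in schs:
            for g in s.gene_ids:
                gene_to_sch[g] = s.sch_id
        sch_windows: dict[str, list] = {}
        for w in windows:
            sid = gene_to_sch.get(w.gene_id)
            if sid is not None:
                sch_windows.setdefault(sid, []).append(w)
        try:
            cons = conservation_background_test(
                sch_windows, windows, n_resamples=cfg.conservation_resamples, rng=rng
            )
            report["conservation"] = {
                "mean_sch_score": float(np.mean(list(cons.sch_scores.values()))),
                "background_mean": cons.background_mean,
                "background_sd": cons.background_sd,
                "z": cons.z,
                "p": cons.p,
            }
        except AnalysisError as exc:
            report["conservation"] = {"skipped": str(exc)}
        sim = signature_conservation_correlation(
            sch_windows, max_pairs_per_sch=2000, rng=rng
        )
        m0, m1 = sim.means()
        report["signature_vs_conservation"] = {
            "mean_same_type": m0,
            "mean_diff_type": m1,
            "p": sim.p if sim.evaluable else None,
            "evaluable": sim.evaluable,
        }

    # --- pathway enrichment + drivers
    cluster_sets = {
        "DB": [c for c in db.clusters if len(c) >= 2],
        "HiC": [c for c in hic.clusters if len(c) >= 2],
        "SCH": sch_groups,
    }
    if inputs.pathways is not None:
        pdb = PathwayDB(
            pathways=dict(inputs.pathways), universe=set(inputs.annotation["gene_id"])
        )
        try:
            frac = enrichment_fraction(cluster_sets, pdb, cfg.enrichment_cutoffs)
            cov = pathway_coverage(cluster_sets, pdb, cfg.enrichment_report_cutoff)
            report["enrichment"] = {
                "fractions": {
                    f"{r.dataset}@{r.cutoff:g}": r.fraction
                    for r in frac.itertuples(index=False)
                },
                "coverage": cov,
                "cutoff": cfg.enrichment_report_cutoff,
            }
        except AnalysisError as exc:
            report["enrichment"] = {"skipped": str(exc)}
    if inputs.drivers:
        try:
            drv = driver_fraction(cluster_sets, inputs.drivers)
            report["drivers"] = {
                "percent": drv.percentages,
                "p_sch_vs_db": drv.p_sch_vs_db,
                "p_sch_vs_hic": drv.p_sch_vs_hic,
            }
        except AnalysisError as exc:
            report["drivers"] = {"skipped": str(exc)}

    # --- CTCF profile around SCH-gene TSSs vs all genes
    if inputs.ctcf is not None:
        sch_genes = sorted({g for s in schs for g in s.gene_ids})
        ann = inputs.annotation.set_index("gene_id")
        all_tss = [
            (r.chrom, int(r.tss), r.strand)
            for r in inputs.annotation.itertuples(index=False)
        ]
        sch_tss = [
            (ann.loc[g, "chrom"], int(ann.loc[g, "tss"]), ann.loc[g, "strand"])
            for g in sch_genes
            if g in ann.index
        ]
        try:
            ct = compare_tss_signal(inputs.ctcf, sch_tss, all_tss)
            report["ctcf"] = {
                "mean_sch": ct.mean_sch,
                "mean_background": ct.mean_background,
                "p": ct.p,
                "n_sch_genes": len(sch_tss),
            }
        except AnalysisError as exc:
            report["ctcf"] = {"skipped": str(exc)}

    return _jsonable(report)


def load_inputs(cfg: RunConfig, bin_size: int = 40_000) -> PipelineInputs:
    """Load pipeline inputs from the file paths of a run configuration."""
    import pyfaidx

    if cfg.mutations is None or cfg.annotation is None or cfg.hic_dir is None:
        raise SchpipeError("run config must provide mutations, annotation and hic_dir")
    records = read_mutations(cfg.mutations)
    annotation = read_annotation_bed(cfg.annotation)
    contact_maps: dict[str, ContactMatrix] = {}
    for path in sorted(Path(cfg.hic_dir).glob("*.dense.tsv")):
        chrom = path.name.split(".")[0]
        contact_maps[chrom] = read_contact_matrix(
            path, "dense", chrom=chrom, bin_size=bin_size
        )
    reference = pyfaidx.Fasta(cfg.fasta) if cfg.fasta else None
    pathways = None
    if cfg.gmt:
        pathways = read_gmt(cfg.gmt, annotation["gene_id"]).pathways
    drivers = read_driver_list(cfg.drivers) if cfg.drivers else None
    ctcf = read_bedgraph(cfg.ctcf) if cfg.ctcf else None
    return PipelineInputs(
        records=records,
        contact_maps=contact_maps,
        annotation=annotation,
        reference=reference,
        pathways=pathways,
        drivers=drivers,
        ctcf=ctcf,
    )


def inputs_from_dataset(ds) -> PipelineInputs:
    """Wrap an in-memory synthetic dataset as pipeline inputs."""
    return PipelineInputs(
        records=ds.mutation_records(),
        contact_maps=ds.contact_maps,
        annotation=ds.annotation,
        reference=ds.reference_view(),
        pathways=ds.pathways,
        drivers=ds.drivers,
        ctcf=ds.ctcf,
        truth=ds.truth,
    )


REPORT_REQUIRED_KEYS = ("version", "seed", "db_clustering", "hic_clustering", "sch")


def validate_report(report: dict) -> None:
    """Minimal schema check of a run report (raises on violation)."""
    for key in REPORT_REQUIRED_KEYS:
        if key not in report:
            raise SchpipeError(f"run report is missing required key {key!r}")
    if not isinstance(report["sch"].get("n_schs"), int):
        raise SchpipeError("run report: sch.n_schs must be an integer")


def write_report(report: dict, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the schema-checked JSON report plus a human-readable summary."""
    validate_report(report)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    jpath = out / "report.json"
    with open(jpath, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    lines = [f"schpipe {report['version']} run (seed {report['seed']})"]
    db = report.get("db_clustering", {})
    lines.append(
        f"DB clustering: threshold {db.get('threshold')} -> "
        f"{db.get('n_clusters')} clusters ({db.get('n_clusters_ge2')} with >=2 genes)"
    )
    if "proximity" in report:
        pr = report["proximity"]
        if "skipped" in pr:
            lines.append(f"proximity test skipped: {pr['skipped']}")
        else:
            lines.append(
                "proximity: co-mutated pair contact "
                f"{pr['mean_comut']:.3g} vs overall {pr['mean_overall_bkg']:.3g} "
                f"(p={pr['p_vs_overall']:.3g}) / gene-level "
                f"{pr['mean_gene_level_bkg']:.3g} (p={pr['p_vs_gene_level']:.3g})"
            )
    lines.append(f"SCHs detected: {report['sch']['n_schs']}")
    if "pair_f1_vs_truth" in report["sch"]:
        lines.append(f"planted-recovery pair F1: {report['sch']['pair_f1_vs_truth']:.3f}")
    for stage in ("intra_inter", "signatures", "complementing", "conservation",
                  "enrichment", "drivers", "ctcf"):
        if stage in report:
            blob = report[stage]
            if isinstance(blob, dict) and "skipped" in blob:
                lines.append(f"{stage}: skipped ({blob['skipped']})")
            else:
                lines.append(f"{stage}: {json.dumps(blob, sort_keys=True)}")
    spath = out / "summary.txt"
    spath.write_text("\n".join(lines) + "\n")
    return jpath, spath


def run_pipeline(cfg: RunConfig, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute the full pipeline and persist intermediates plus the report.

    With a ``simulate`` block the inputs are generated (and written) first;
    otherwise they are loaded from the configured paths.  ``seed`` defaults
    to the simulate seed (or 0).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.simulate is not None:
        ds = simulate(cfg.simulate)
        write_dataset(ds, out / "inputs")
        inputs = inputs_from_dataset(ds)
        if seed is None:
            seed = cfg.simulate.seed
    else:
        inputs = load_inputs(cfg)
        if seed is None:
            seed = 0
    report = run_analysis(inputs, cfg, seed=seed)

    # persist clustering intermediates for stage-wise reuse
    m = build_matrix(inputs.records)
    db = seed_cluster(m, report["db_clustering"]["threshold"])
    hic = hic_cluster_all(
        inputs.contact_maps, inputs.annotation, cfg.hic_cutoff_policy, cfg.hic_cutoff_value
    )
    write_clusters_tsv(db, out / "db_clusters.tsv")
    write_clusters_tsv(hic, out / "hic_clusters.tsv")
    write_sch_table(detect_schs(db, hic, inputs.annotation), out / "schs.tsv")
    write_report(report, out)
    return report
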