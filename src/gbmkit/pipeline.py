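"""End-to-end orchestration: simulate (or load) a dataset, run every
analysis stage in dependency order, write all tables.

The demo path generates a synthetic study, writes it to disk through
the io_formats writers, reads it back through the readers (formats are
exercised, never bypassed) and then runs: methylation calling ->
feature aggregation -> consolidated set -> DMRs; expression ingestion
-> status calling -> QC; four-way integration; peak calling ->
consolidation -> overlap statistics; profiles; GO enrichment.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import chromatin, dmr, expression, go_enrichment, integration, methylome, profiles
from .config import PipelineConfig
from .io_formats import (
    read_annotation,
    read_bedgraph,
    read_cytosine_report,
    write_bed,
)
from .synthetic_data import (
    MARKS,
    STAGES,
    TruthParams,
    generate_genome,
    simulate_expression_and_tracks,
    simulate_gene2go,
    simulate_methylome,
    simulate_truth,
    write_dataset,
)

logger = logging.getLogger("gbmkit")

__all__ = ["run_demo", "run_analysis", "simulate_dataset"]


def simulate_dataset(
    outdir: str | Path,
    seed: int = 0,
    n_genes: int = 200,
    mean_coverage: float = 30.0,
    n_replicates: int = 3,
    params: TruthParams | None = None,
) -> dict:
    """Generate a complete synthetic study and write it to ``outdir``."""
    ann, sites = generate_genome(n_genes, seed=seed)
    truth = simulate_truth(ann, sites, params=params, seed=seed + 1)
    meth = simulate_methylome(
        ann, sites, truth, n_replicates=n_replicates, mean_coverage=mean_coverage,
        seed=seed + 2,
    )
    expr = simulate_expression_and_tracks(
        ann, truth, n_replicates=n_replicates, seed=seed + 3
    )
    paths = write_dataset(outdir, ann, sites, truth, meth, expr)
    gene2go = simulate_gene2go(truth, seed=seed + 4)
    go_path = Path(outdir) / "gene2go.tsv"
    go_enrichment.write_gene2go(gene2go, go_path)
    paths["gene2go"] = go_path
    return {"annotation": ann, "sites": sites, "truth": truth, "paths": paths}


def _stage_samples(sample_names: Sequence[str]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {s: [] for s in STAGES}
    for name in sample_names:
        stage = name.rsplit("_", 1)[0]
        if stage in groups:
            groups[stage].append(name)
    return groups


def run_analysis(
    datadir: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Run every stage on a dataset laid out as written by
    :func:`simulate_dataset`; returns the summary dict and writes all
    tables under ``outdir``."""
    cfg = config or PipelineConfig()
    datadir, outdir = Path(datadir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    ann = read_annotation(datadir / "annotation.gff3")
    logger.info("annotation: %d genes on %d chromosome(s)", len(ann), len(ann.chrom_sizes))

    # ----- methylome ------------------------------------------------------
    report_paths = sorted(datadir.glob("*.CpG_report.txt"))
    if not report_paths:
        raise FileNotFoundError(f"no cytosine reports in {datadir}")
    per_sample_records = {}
    conversion = {}
    calls = {}
    feature_meth = {}
    gene_map = methylome.gene_feature_map(ann, span=cfg.gene_methylation_span)
    for path in report_paths:
        sample = path.name.replace(".CpG_report.txt", "")
        records = read_cytosine_report(path, sample)
        genomic, controls = methylome.split_control_records(records, cfg.control_chroms)
        per_sample_records[sample] = genomic
        eff = methylome.conversion_efficiency(controls.get("Lambda", []))
        conversion[sample] = eff
        calls[sample] = methylome.call_cpg_levels(genomic, cfg.min_coverage)
        feature_meth[sample] = methylome.feature_methylation(
            calls[sample], gene_map, cfg.min_cpgs
        )
    summary["conversion_efficiency"] = conversion
    consolidated = methylome.consolidated_gene_set(feature_meth)
    summary["n_genes_annotated"] = len(ann)
    summary["n_genes_consolidated"] = len(consolidated)

    groups = _stage_samples(per_sample_records)
    stage_level = {}
    for stage, samples in groups.items():
        per_rep = pd.concat(
            [feature_meth[s]["mean_level"] for s in samples], axis=1
        )
        stage_level[stage] = per_rep.mean(axis=1)
        gw = methylome.genome_wide_methylation(
            [c for s in samples for c in calls[s]], cfg.meth_threshold
        )
        summary[f"genome_wide_{stage}"] = gw
    region = methylome.region_class_summary(calls[groups["embryo"][0]], ann)
    region.to_csv(outdir / "region_class_summary.tsv", sep="\t", index=False)

    pd.DataFrame(
        {f"{s}": feature_meth[s]["mean_level"] for s in per_sample_records}
    ).to_csv(outdir / "gene_methylation.tsv", sep="\t")

    # ----- DMRs -----------------------------------------------------------
    dmrs = dmr.call_dmrs(
        per_sample_records,
        group1=groups["embryo"],
        group2=groups["adult"],
        min_cov=cfg.dmr_cov_min,
        max_cov=cfg.dmr_cov_max,
        max_gap=cfg.dmr_max_gap,
        min_cpgs=cfg.dmr_min_cpgs,
        min_diff=cfg.dmr_min_diff,
        alpha=cfg.dmr_alpha,
    )
    per_dmr, dmr_counts = dmr.annotate_dmrs(dmrs, ann)
    per_dmr.to_csv(outdir / "dmrs.tsv", sep="\t", index=False)
    dmr_counts.to_csv(outdir / "dmr_feature_counts.tsv", sep="\t", index=False)
    write_bed(dmr.dmrs_to_bed(dmrs), outdir / "dmrs.bed")
    summary["n_dmrs"] = len(dmrs)
    summary["n_dmrs_hypo"] = sum(1 for d in dmrs if d.direction == "hypo")
    summary["n_dmrs_hyper"] = sum(1 for d in dmrs if d.direction == "hyper")

    # ----- expression -----------------------------------------------------
    fpkm = {
        stage: pd.read_csv(datadir / f"fpkm_{stage}.tsv", sep="\t", index_col=0)
        for stage in STAGES
    }
    stage_fpkm = {
        stage: expression.summarize_fpkm(
            df, cfg.excluded_replicates, how=cfg.fpkm_summary
        )
        for stage, df in fpkm.items()
    }
    qc = expression.replicate_qc(
        pd.concat(fpkm.values(), axis=1),
        groups={s: [c for c in fpkm[s].columns] for s in STAGES},
        correlation_floor=cfg.qc_correlation_floor,
    )
    summary["qc_flagged_replicates"] = qc["flagged"]
    deg_table = pd.read_csv(datadir / "deg.tsv", sep="\t", index_col=0)
    summary["deg"] = expression.deg_accounting(deg_table, alpha=0.05)

    # ----- integration ----------------------------------------------------
    status = {}
    for stage in STAGES:
        status[stage] = integration.build_gene_status_table(
            stage_level[stage].to_dict(),
            stage_fpkm[stage].to_dict(),
            consolidated,
            meth_threshold=cfg.meth_threshold,
            fpkm_threshold=cfg.fpkm_threshold,
        )
        status[stage].to_csv(outdir / f"gene_status_{stage}.tsv", sep="\t")
    trans = integration.transition_counts(status["embryo"], status["adult"])
    trans.flows.to_csv(outdir / "transition_flows.tsv", sep="\t")
    trans.long_flows().to_csv(outdir / "transition_sankey.tsv", sep="\t", index=False)
    summary["transitions"] = {
        "n_genes": trans.n_genes,
        "embryo_expressed": trans.embryo_expressed,
        "adult_expressed": trans.adult_expressed,
        "become_active": trans.become_active,
        "become_inactive": trans.become_inactive,
        "gain_methylation": trans.gain_methylation,
        "lose_methylation": trans.lose_methylation,
        **trans.percentages(),
    }
    cat_stats = integration.category_stats(status["embryo"], ann)
    cat_stats.to_csv(outdir / "category_stats_embryo.tsv", sep="\t", index=False)
    summary["category_counts_embryo"] = dict(
        zip(cat_stats["category"], cat_stats["n_genes"].astype(int))
    )
    try:
        summary["gbm_expression_regression"] = integration.gbm_expression_regression(
            status["embryo"]
        )
    except ValueError:
        summary["gbm_expression_regression"] = None

    dmr_genes: dict[str, set[str]] = {"hypo": set(), "hyper": set()}
    for d in dmrs:
        for g in ann.genes_on(d.chrom):
            if g.start < d.end and g.end > d.start:
                dmr_genes[d.direction].add(g.gene_id)
    deg_sig = deg_table[deg_table["padj"] < 0.05]
    deg_genes = {
        "up": set(deg_sig.index[deg_sig["log2fc"] > 0]),
        "down": set(deg_sig.index[deg_sig["log2fc"] < 0]),
    }
    overlap = integration.dmr_deg_overlap(dmr_genes, deg_genes, consolidated)
    overlap.to_csv(outdir / "dmr_deg_overlap.tsv", sep="\t", index=False)
    change = integration.methylation_change_profile(
        stage_level["embryo"].reindex(sorted(consolidated)).to_dict(),
        stage_level["adult"].reindex(sorted(consolidated)).to_dict(),
    )
    change.to_csv(outdir / "methylation_change_profile.tsv", sep="\t", index=False)

    # ----- chromatin ------------------------------------------------------
    peak_sets: dict[str, list] = {}
    tracks_rep1 = {}
    for mark in MARKS:
        reps = []
        for path in sorted(datadir.glob(f"{mark}_rep*.bedgraph")):
            track = read_bedgraph(path)
            if mark not in tracks_rep1:
                tracks_rep1[mark] = track
            reps.append(chromatin.call_peaks(track, cfg.peak_fraction))
        if len(reps) >= 2:
            peak_sets[mark] = chromatin.consolidate_replicates(reps)
        elif reps:
            peak_sets[mark] = reps[0]
    summary["peaks"] = {}
    for mark, peaks in peak_sets.items():
        per_peak, fractions = chromatin.assign_peaks(peaks, ann)
        per_peak.to_csv(outdir / f"peaks_{mark}.tsv", sep="\t", index=False)
        write_bed(chromatin.peaks_to_bed(peaks), outdir / f"peaks_{mark}.bed")
        summary["peaks"][mark] = {"n_high_confidence": len(peaks), **fractions}
    expr_sets = {
        "expressed": set(status["embryo"].index[status["embryo"]["expr_status"] == "expressed"]),
        "not expressed": set(
            status["embryo"].index[status["embryo"]["expr_status"] == "not expressed"]
        ),
    }
    category_sets = {
        cat: set(status["embryo"].index[status["embryo"]["category"] == cat])
        for cat in integration.CATEGORIES
    }
    flags, set_summary = chromatin.gene_mark_overlap(
        ann, peak_sets, gene_sets={**expr_sets, **category_sets}
    )
    flags.to_csv(outdir / "gene_mark_overlap.tsv", sep="\t")
    set_summary.to_csv(outdir / "gene_mark_summary.tsv", sep="\t", index=False)
    summary["gene_mark_summary"] = set_summary.set_index("gene_set").to_dict("index")
    enrich_rows = []
    for mark, peaks in peak_sets.items():
        marked = set(flags.index[flags[mark]]) & consolidated
        enr = chromatin.category_mark_enrichment(category_sets, marked, consolidated)
        enr.insert(0, "mark", mark)
        enrich_rows.append(enr)
    if enrich_rows:
        pd.concat(enrich_rows).to_csv(
            outdir / "category_mark_enrichment.tsv", sep="\t", index=False
        )

    # ----- profiles -------------------------------------------------------
    genes = list(ann)
    embryo_calls = calls[groups["embryo"][0]]
    meth_mat = profiles.metagene_matrix(
        embryo_calls, genes, cfg.profile_body, cfg.profile_flank, cfg.profile_bin
    )
    meth_mat.to_csv(outdir / "metagene_methylation.tsv", sep="\t")
    summary["profiles"] = {}
    me_set = category_sets["methylated/expressed"]
    prof = profiles.set_mean_profile(meth_mat, me_set)
    prof.to_csv(outdir / "profile_methylation_meth_expressed.tsv", sep="\t")
    for mark, track in tracks_rep1.items():
        mat = profiles.metagene_matrix(
            track, genes, cfg.profile_body, cfg.profile_flank, cfg.profile_bin
        )
        for name, gene_set in expr_sets.items():
            p = profiles.set_mean_profile(mat, gene_set)
            safe = name.replace(" ", "_").replace("/", "_")
            p.to_csv(outdir / f"profile_{mark}_{safe}.tsv", sep="\t")
            summary["profiles"][f"{mark}_{safe}_peak_bin"] = (
                int(np.nanargmax(p["mean"].to_numpy())) if p["mean"].notna().any() else None
            )
        for anchor in ("TSS", "TES"):
            amat = profiles.anchored_profile(
                track, genes, anchor, cfg.anchored_flank, cfg.profile_bin
            )
            ap = profiles.set_mean_profile(amat, expr_sets["expressed"])
            ap.to_csv(outdir / f"anchored_{mark}_{anchor}.tsv", sep="\t")
    seg = profiles.segment_profile(embryo_calls, ann, me_set, cfg.profile_flank, cfg.min_cpgs)
    seg.to_csv(outdir / "segment_profile_meth_expressed.tsv", sep="\t", index=False)

    # ----- GO enrichment --------------------------------------------------
    gene2go_path = datadir / "gene2go.tsv"
    if gene2go_path.exists():
        gene2go = go_enrichment.read_gene2go(gene2go_path)
        go_counts = {}
        for cat, gene_set in category_sets.items():
            res = go_enrichment.go_fisher(gene_set & consolidated, consolidated, gene2go)
            top = go_enrichment.top_terms(res, cfg.go_top_n)
            safe = cat.replace(" ", "_").replace("/", "_")
            top.to_csv(outdir / f"go_{safe}.tsv", sep="\t", index=False)
            go_counts[cat] = int((res["q_bh"] < cfg.go_alpha).sum()) if len(res) else 0
        summary["go_significant_terms"] = go_counts

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=_json_default)
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_demo(
    outdir: str | Path,
    seed: int = 0,
    config: PipelineConfig | None = None,
    n_genes: int = 200,
    mean_coverage: float = 30.0,
) -> dict:
    """One-command synthetic demo: simulate, write, re-read, analyse."""
    outdir = Path(outdir)
    cfg = config or PipelineConfig(seed=seed)
    sim = simulate_dataset(
        outdir / "data", seed=seed, n_genes=n_genes, mean_coverage=mean_coverage
    )
    summary = run_analysis(outdir / "data", outdir / "results", cfg)
    summary["seed"] = seed
    summary["config"] = cfg.to_dict()
    with open(outdir / "results" / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=_json_default)
    return {"summary": summary, **sim}
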