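"""Synthetic multiomics dataset generator with ground-truth record.

Emulates the processed data layer of a two-stage (embryo/adult) insect
multiomics study: per-sample CpG records with Poisson coverage and
beta-binomial counts (plus unmethylated Lambda and fully methylated
pUC19 spike-ins), FPKM tables and a differential-expression table, and
per-replicate histone-mark coverage tracks (H3K27ac: narrow Gaussian
bump at the TSS of expressed genes; H3K36me3: broad 5'->3' ramp over
the bodies of expressed or methylated genes, decaying exponentially
into the downstream flank).

Truth structure per gene and stage: ~25% of genes methylated (true
gene-body levels drawn uniformly in 15-70%, unmethylated genes below
8%), 36.5% of genes expressed in embryos with activation/inactivation
rates that bring adults to ~44%, methylation status maintained by
~95% of genes, a CpG-methylation dip (true level 0) within +-200 bp
of the TSS of methylated/expressed genes, and a mild
regression-to-baseline drift of adult methylation so that highly
methylated genes tend to lose methylation.  Differentially methylated
regions are additionally planted as contiguous-CpG shifts (default 15
CpGs, -30 points in the adult) inside genes that stay methylated in
both stages.

All randomness flows from a single integer seed; identical seeds give
identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CpGRecord,
    Gene,
    GenomeAnnotation,
    SignalTrack,
    write_annotation,
    write_bedgraph,
    write_cytosine_report,
)

__all__ = [
    "SimTruth",
    "TruthParams",
    "generate_genome",
    "simulate_methylome",
    "simulate_truth",
    "simulate_expression_and_tracks",
    "write_dataset",
]

STAGES = ("embryo", "adult")
MARKS = ("H3K27ac", "H3K36me3")

# control "chromosomes" mimicking spike-in fasta entries
CONTROL_SIZES = {"Lambda": 3000, "pUC19": 2000}
CONTROL_CPG_SPACING = 10


@dataclass
class TruthParams:
    """Generative parameters; defaults are the study-like conditions."""

    # category structure
    p_meth: float = 0.25
    p_expr_embryo: float = 0.365
    p_inactive_given_expr: float = 0.093  # expressed embryo -> silent adult
    p_active_given_not: float = 0.175  # silent embryo -> expressed adult
    p_lose_meth: float = 0.168  # methylated embryo -> unmethylated adult
    p_gain_meth: float = 0.007
    # methylation levels (integer percent)
    meth_level_low: int = 15
    meth_level_high: int = 70
    unmeth_level_high: int = 7
    intergenic_level: int = 1
    tss_dip_halfwidth: int = 200
    adult_drift: float = 0.15  # shrink of adult level toward baseline
    # planted DMRs
    n_dmrs: int = 8
    dmr_n_cpgs: int = 15
    dmr_effect: float = -30.0
    # sequencing model
    conversion_failure: float = 0.005  # false-methylated call rate
    dispersion: float = 0.1  # beta-binomial rho
    # expression model
    expr_log10_low: float = 0.4
    expr_log10_high: float = 2.5
    silent_log10_low: float = -2.0
    silent_log10_high: float = -0.2
    gbm_expr_slope: float = 0.01  # log10 FPKM per methylation point
    gbm_expr_intercept: float = 0.5
    gbm_expr_sd: float = 0.3
    fpkm_rep_sd: float = 0.1  # log10 replicate noise
    # track model
    track_bin: int = 50
    noise_blob_p: float = 0.2
    noise_blob_scale: float = 0.3
    k27ac_height: float = 5.0
    k27ac_sigma: float = 150.0
    k36me3_base: float = 0.5
    k36me3_max: float = 3.0
    k36me3_decay: float = 1000.0
    k36me3_decay_reach: float = 2000.0  # hard cutoff; < min intergenic gap
    track_rep_sd: float = 0.1


def generate_genome(
    n_genes: int,
    chrom_length: int | None = None,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[GenomeAnnotation, dict[str, np.ndarray]]:
    """Random gene annotation plus CpG site positions on one chromosome.

    Genes get 1-8 exons, alternate strands at random and are separated
    by at least 3 kb of intergenic sequence.  CpGs are laid down more
    densely in exons (mean spacing ~27 bp) than in introns and
    intergenic space (~105 bp).  Raises when ``chrom_length`` cannot
    hold the requested genes.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    genes: list[Gene] = []
    cursor = int(rng.integers(3000, 5001))
    exonic_blocks: list[tuple[int, int]] = []
    for i in range(n_genes):
        n_ex = int(rng.integers(1, 9))
        exon_lens = rng.integers(150, 601, size=n_ex)
        intron_lens = rng.integers(100, 501, size=max(n_ex - 1, 0))
        exons = []
        pos = cursor
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if j < len(intron_lens):
                pos += int(intron_lens[j])
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{i + 1:04d}"
        genes.append(Gene(gid, chrom, cursor, pos, strand, tuple(exons)))
        exonic_blocks.extend(exons)
        cursor = pos + int(rng.integers(3000, 5001))
    total = cursor
    if chrom_length is None:
        chrom_length = total
    elif chrom_length < total:
        raise ValueError(
            f"chromosome length {chrom_length} too short for {n_genes} genes "
            f"(need >= {total})"
        )
    ann = GenomeAnnotation({chrom: chrom_length}, genes)

    exonic = np.zeros(chrom_length, dtype=bool)
    for s, e in exonic_blocks:
        exonic[s:e] = True
    sites: list[int] = []
    p = int(rng.integers(5, 40))
    while p < chrom_length:
        sites.append(p + 1)  # 1-based cytosine position
        gap = rng.integers(15, 40) if exonic[p] else rng.integers(60, 150)
        p += int(gap)
    return ann, {chrom: np.asarray(sites, dtype=int)}


@dataclass
class SimTruth:
    """Ground truth of one simulated study."""

    params: TruthParams
    seed: int
    genes: pd.DataFrame  # per-gene truth table
    dmrs: list[dict] = field(default_factory=list)
    spikein_levels: dict[str, float] = field(
        default_factory=lambda: {"Lambda": 0.0, "pUC19": 100.0}
    )

    def category(self, stage: str, gene_id: str) -> str:
        row = self.genes.loc[gene_id]
        meth = "methylated" if row[f"level_{stage}"] >= 10 else "not methylated"
        expr = "expressed" if row[f"expr_{stage}"] else "not expressed"
        return f"{meth}/{expr}"

    def categories(self, stage: str) -> pd.Series:
        return pd.Series(
            {g: self.category(stage, g) for g in self.genes.index}, name="category"
        )

    def cpg_level_arrays(
        self, ann: GenomeAnnotation
    ) -> dict[str, dict[str, np.ndarray]]:
        """Per-stage per-chromosome true level (percent) for every base."""
        p = self.params
        out: dict[str, dict[str, np.ndarray]] = {}
        for stage in STAGES:
            arrays = {}
            for chrom, size in ann.chrom_sizes.items():
                lev = np.full(size, float(p.intergenic_level))
                for g in ann.genes_on(chrom):
                    row = self.genes.loc[g.gene_id]
                    lev[g.start : g.end] = float(row[f"level_{stage}"])
                    if row[f"level_{stage}"] >= 10 and row[f"expr_{stage}"]:
                        lo = max(g.tss - p.tss_dip_halfwidth, 0)
                        hi = min(g.tss + p.tss_dip_halfwidth + 1, size)
                        lev[lo:hi] = 0.0
                arrays[chrom] = lev
            out[stage] = arrays
        for d in self.dmrs:
            arr = out[d["stage"]][d["chrom"]]
            arr[d["start"] : d["end"]] = np.clip(
                arr[d["start"] : d["end"]] + d["effect"], 0.0, 100.0
            )
        return out

    def gene_true_means(
        self, ann: GenomeAnnotation, sites: Mapping[str, np.ndarray], stage: str
    ) -> pd.Series:
        """Per-gene mean of per-CpG true levels over the gene span."""
        arrays = self.cpg_level_arrays(ann)[stage]
        out = {}
        for g in ann:
            pos = sites[g.chrom]
            inside = pos[(pos >= g.start + 1) & (pos <= g.end)]
            out[g.gene_id] = (
                float(arrays[g.chrom][inside - 1].mean()) if len(inside) else np.nan
            )
        return pd.Series(out, name=f"true_mean_{stage}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "params": asdict(self.params),
            "spikein_levels": self.spikein_levels,
            "dmrs": self.dmrs,
            "genes": self.genes.reset_index().to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        genes = pd.DataFrame(payload["genes"]).set_index("gene_id")
        return cls(
            params=TruthParams(**payload["params"]),
            seed=payload["seed"],
            genes=genes,
            dmrs=payload["dmrs"],
            spikein_levels=payload["spikein_levels"],
        )


def simulate_truth(
    ann: GenomeAnnotation,
    sites: Mapping[str, np.ndarray],
    params: TruthParams | None = None,
    seed: int = 0,
) -> SimTruth:
    """Draw per-gene truth (categories, levels, FPKM) and plant DMRs."""
    p = params or TruthParams()
    rng = np.random.default_rng(seed)
    rows = []
    for g in ann:
        meth_e = rng.random() < p.p_meth
        if meth_e:
            level_e = int(rng.integers(p.meth_level_low, p.meth_level_high + 1))
            meth_a = rng.random() >= p.p_lose_meth
        else:
            level_e = int(rng.integers(0, p.unmeth_level_high + 1))
            meth_a = rng.random() < p.p_gain_meth
        if meth_a and meth_e:
            # mild regression toward baseline: high levels drift down
            level_a = int(round(level_e - p.adult_drift * max(level_e - p.meth_level_low, 0)))
            level_a = max(level_a, 10)
        elif meth_a:
            level_a = int(rng.integers(p.meth_level_low, 41))
        else:
            level_a = int(rng.integers(0, p.unmeth_level_high + 1))

        expr_e = rng.random() < p.p_expr_embryo
        if expr_e:
            expr_a = rng.random() >= p.p_inactive_given_expr
        else:
            expr_a = rng.random() < p.p_active_given_not

        fpkms = {}
        for stage, expr, level in (("embryo", expr_e, level_e), ("adult", expr_a, level_a)):
            if not expr:
                fpkms[stage] = 10.0 ** rng.uniform(p.silent_log10_low, p.silent_log10_high)
            elif level >= 10:
                # methylated/expressed: expression tied linearly to level
                while True:
                    lg = (
                        p.gbm_expr_intercept
                        + p.gbm_expr_slope * level
                        + rng.normal(0.0, p.gbm_expr_sd)
                    )
                    if lg > 0.05:
                        break
                fpkms[stage] = 10.0**lg
            else:
                fpkms[stage] = 10.0 ** rng.uniform(p.expr_log10_low, p.expr_log10_high)
        rows.append(
            {
                "gene_id": g.gene_id,
                "level_embryo": level_e if meth_e else min(level_e, 9),
                "level_adult": level_a if meth_a else min(level_a, 9),
                "expr_embryo": bool(expr_e),
                "expr_adult": bool(expr_a),
                "fpkm_embryo": float(fpkms["embryo"]),
                "fpkm_adult": float(fpkms["adult"]),
            }
        )
    genes = pd.DataFrame(rows).set_index("gene_id")

    # plant DMRs in genes that stay clearly methylated in both stages
    dmrs: list[dict] = []
    eligible = []
    for g in ann:
        row = genes.loc[g.gene_id]
        if row["level_embryo"] >= 40 and row["level_adult"] >= 40:
            pos = sites[g.chrom]
            inside = pos[(pos >= g.start + 1) & (pos <= g.end)]
            if len(inside) >= 2 * p.dmr_n_cpgs:
                eligible.append((g, inside))
    rng.shuffle(eligible)
    for g, inside in eligible[: p.n_dmrs]:
        # the planted run must be the only stage difference in its gene:
        # host genes are exempt from the adult drift
        genes.loc[g.gene_id, "level_adult"] = genes.loc[g.gene_id, "level_embryo"]
        start_idx = int(rng.integers(0, len(inside) - p.dmr_n_cpgs + 1))
        run = inside[start_idx : start_idx + p.dmr_n_cpgs]
        dmrs.append(
            {
                "chrom": g.chrom,
                "start": int(run[0] - 1),
                "end": int(run[-1]),
                "stage": "adult",
                "effect": float(p.dmr_effect),
                "n_cpgs": int(p.dmr_n_cpgs),
                "gene_id": g.gene_id,
                "direction": "hypo" if p.dmr_effect < 0 else "hyper",
            }
        )
    dmrs.sort(key=lambda d: (d["chrom"], d["start"]))
    return SimTruth(params=p, seed=seed, genes=genes, dmrs=dmrs)


def _beta_binomial(
    rng: np.random.Generator, n: np.ndarray, mean: np.ndarray, rho: float
) -> np.ndarray:
    """Counts ~ BetaBinomial(n, mean, rho); rho=0 degenerates to binomial."""
    mean = np.clip(mean, 0.0, 1.0)
    if rho <= 0:
        return rng.binomial(n, mean)
    c = (1.0 - rho) / rho
    a, b = mean * c, (1.0 - mean) * c
    ps = np.where(
        (a > 0) & (b > 0), rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12)), mean
    )
    return rng.binomial(n, ps)


def simulate_methylome(
    ann: GenomeAnnotation,
    sites: Mapping[str, np.ndarray],
    truth: SimTruth,
    n_replicates: int = 3,
    mean_coverage: float = 30.0,
    seed: int = 0,
    exact: bool = False,
) -> dict[str, list[CpGRecord]]:
    """Per-sample CpG records, including Lambda/pUC19 spike-in records.

    Sample keys are ``{stage}_{replicate}``.  Coverage is
    Poisson(``mean_coverage``); methylated counts are beta-binomial
    around the site's true level after adding the conversion-failure
    rate as false methylated calls.  ``exact=True`` silences all
    sequencing noise: constant coverage 100 and deterministic counts
    equal to the expected value, so per-CpG levels reproduce the truth
    exactly (integer-percent truth levels).
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    p = truth.params
    arrays = truth.cpg_level_arrays(ann)
    fail = 0.0 if exact else p.conversion_failure
    rho = 0.0 if exact else p.dispersion
    rng = np.random.default_rng(seed)
    out: dict[str, list[CpGRecord]] = {}
    for stage in STAGES:
        for rep in range(1, n_replicates + 1):
            records: list[CpGRecord] = []
            for chrom, pos in sites.items():
                lev = arrays[stage][chrom][np.asarray(pos) - 1] / 100.0
                eff = lev + (1.0 - lev) * fail
                if exact:
                    cov = np.full(len(pos), 100, dtype=int)
                    meth = np.rint(eff * cov).astype(int)
                else:
                    cov = rng.poisson(mean_coverage, size=len(pos))
                    meth = _beta_binomial(rng, cov, eff, rho)
                for pp, cc, mm in zip(pos, cov, meth):
                    records.append(CpGRecord(chrom, int(pp), "+", int(mm), int(cc - mm)))
            # spike-in controls
            for ctrl, size in CONTROL_SIZES.items():
                true = truth.spikein_levels[ctrl] / 100.0
                eff_scalar = true + (1.0 - true) * fail
                cpos = np.arange(1, size, CONTROL_CPG_SPACING)
                if exact:
                    cov = np.full(len(cpos), 100, dtype=int)
                    meth = np.rint(eff_scalar * cov).astype(int)
                else:
                    cov = rng.poisson(mean_coverage, size=len(cpos))
                    meth = rng.binomial(cov, eff_scalar)
                for pp, cc, mm in zip(cpos, cov, meth):
                    records.append(CpGRecord(ctrl, int(pp), "+", int(mm), int(cc - mm)))
            out[f"{stage}_{rep}"] = records
    return out


def _gaussian_bump(centers: np.ndarray, center: int, height: float, sigma: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((centers - center) / sigma) ** 2)


def simulate_expression_and_tracks(
    ann: GenomeAnnotation,
    truth: SimTruth,
    n_replicates: int = 3,
    n_track_replicates: int = 2,
    seed: int = 0,
    noise: bool = True,
) -> dict:
    """FPKM tables, DE table and histone-mark bedGraph tracks.

    Returns a dict with ``fpkm`` ({stage: DataFrame genes x reps}),
    ``deg`` (gene, log2fc, padj), and ``tracks``
    ({(mark, replicate): SignalTrack}) for the embryo stage.  With
    ``noise=False`` replicate values equal the truth and tracks carry
    no background blobs.
    """
    p = truth.params
    rng = np.random.default_rng(seed)
    fpkm: dict[str, pd.DataFrame] = {}
    for stage in STAGES:
        base = truth.genes[f"fpkm_{stage}"]
        cols = {}
        for rep in range(1, n_replicates + 1):
            if noise:
                factor = 10.0 ** rng.normal(0.0, p.fpkm_rep_sd, size=len(base))
            else:
                factor = np.ones(len(base))
            vals = base.to_numpy() * factor
            if not noise:
                # keep silent genes at/below the threshold exactly
                vals = np.where(
                    truth.genes[f"expr_{stage}"].to_numpy(), vals, np.minimum(vals, 1.0)
                )
            cols[f"{stage}_{rep}"] = vals
        fpkm[stage] = pd.DataFrame(cols, index=base.index)

    log2fc = np.log2(
        truth.genes["fpkm_adult"].to_numpy() / truth.genes["fpkm_embryo"].to_numpy()
    )
    changed = truth.genes["expr_embryo"] != truth.genes["expr_adult"]
    padj = np.where(changed | (np.abs(log2fc) > 2.0), 1e-4, 0.9)
    deg = pd.DataFrame(
        {"gene_id": truth.genes.index, "log2fc": log2fc, "padj": padj}
    ).set_index("gene_id")

    tracks: dict[tuple[str, int], SignalTrack] = {}
    bin_ = p.track_bin
    for mark in MARKS:
        for rep in range(1, n_track_replicates + 1):
            track = SignalTrack()
            for chrom, size in ann.chrom_sizes.items():
                n_bins = size // bin_
                centers = np.arange(n_bins) * bin_ + bin_ // 2
                vals = np.zeros(n_bins)
                if noise:
                    blob = rng.random(n_bins) < p.noise_blob_p
                    vals[blob] += rng.exponential(p.noise_blob_scale, size=blob.sum())
                for g in ann.genes_on(chrom):
                    row = truth.genes.loc[g.gene_id]
                    expressed = bool(row["expr_embryo"])
                    methylated = row["level_embryo"] >= 10
                    amp = 1.0 + (rng.normal(0.0, p.track_rep_sd) if noise else 0.0)
                    if mark == "H3K27ac" and expressed:
                        vals += amp * _gaussian_bump(
                            centers, g.tss, p.k27ac_height, p.k27ac_sigma
                        )
                    if mark == "H3K36me3" and (expressed or methylated):
                        inside = (centers >= g.start) & (centers < g.end)
                        frac = (centers[inside] - g.start) / max(g.length, 1)
                        if g.strand == "-":
                            frac = 1.0 - frac
                        vals[inside] += amp * (
                            p.k36me3_base + (p.k36me3_max - p.k36me3_base) * frac
                        )
                        # exponential decay into the 3' flank
                        if g.strand == "+":
                            after = centers >= g.end
                            dist = centers[after] - g.end
                        else:
                            after = centers < g.start
                            dist = g.start - centers[after]
                        decay = amp * p.k36me3_max * np.exp(-dist / p.k36me3_decay)
                        decay[dist > p.k36me3_decay_reach] = 0.0
                        vals[after] += decay
                vals[vals < 1e-9] = 0.0
                ivs = [
                    (int(i * bin_), int((i + 1) * bin_), float(v))
                    for i, v in enumerate(vals)
                    if v > 0
                ]
                track.intervals[chrom] = ivs
            tracks[(mark, rep)] = track
    return {"fpkm": fpkm, "deg": deg, "tracks": tracks}


def simulate_gene2go(
    truth: SimTruth,
    n_terms: int = 40,
    mean_terms_per_gene: float = 2.0,
    bias: float = 4.0,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random gene -> GO term annotations with category structure.

    The first eight terms are enriched in one of the four
    embryo-stage categories (two terms each): genes of the favoured
    category pick them ``bias`` times more often.  The remainder are
    assigned uniformly, giving a null background for the enrichment
    test.
    """
    rng = np.random.default_rng(seed)
    terms = [f"GO:{7000000 + i}" for i in range(n_terms)]
    cats = ["not methylated/expressed", "methylated/expressed",
            "not methylated/not expressed", "methylated/not expressed"]
    favoured = {terms[i]: cats[i // 2] for i in range(min(8, n_terms))}
    out: dict[str, set[str]] = {}
    for gid in truth.genes.index:
        cat = truth.category("embryo", gid)
        weights = np.array(
            [bias if favoured.get(t) == cat else 1.0 for t in terms]
        )
        weights = weights / weights.sum()
        k = min(rng.poisson(mean_terms_per_gene), n_terms)
        if k > 0:
            chosen = rng.choice(terms, size=k, replace=False, p=weights)
            out[gid] = set(str(t) for t in chosen)
        else:
            out[gid] = set()
    return out


def write_dataset(
    outdir: str | Path,
    ann: GenomeAnnotation,
    sites: Mapping[str, np.ndarray],
    truth: SimTruth,
    methylome: Mapping[str, Sequence[CpGRecord]],
    expression: dict,
) -> dict[str, Path]:
    """Write the full dataset through the io_formats writers.

    Produces annotation.gff3, per-sample cytosine reports, per-stage
    FPKM TSVs, a DE table, per-mark/replicate bedGraphs and the
    truth.json sidecar.  Returns the path of every file written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["annotation"] = outdir / "annotation.gff3"
    write_annotation(ann, paths["annotation"])
    for sample, records in methylome.items():
        key = f"methylome/{sample}"
        paths[key] = outdir / f"{sample}.CpG_report.txt"
        write_cytosine_report(records, paths[key])
    for stage, df in expression["fpkm"].items():
        key = f"fpkm/{stage}"
        paths[key] = outdir / f"fpkm_{stage}.tsv"
        df.to_csv(paths[key], sep="\t")
    paths["deg"] = outdir / "deg.tsv"
    expression["deg"].to_csv(paths["deg"], sep="\t")
    for (mark, rep), track in expression["tracks"].items():
        key = f"track/{mark}_{rep}"
        paths[key] = outdir / f"{mark}_rep{rep}.bedgraph"
        write_bedgraph(track, paths[key])
    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    sites_path = outdir / "cpg_sites.json"
    with open(sites_path, "w") as fh:
        json.dump({c: [int(x) for x in v] for c, v in sites.items()}, fh)
    paths["sites"] = sites_path
    return paths
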