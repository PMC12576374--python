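"""Per-CpG methylation calling, spike-in QC and feature aggregation.

A CpG site is *called* when covered by at least ``min_coverage`` reads
(default 5); its level is ``100 * meth / (meth + unmeth)`` percent.  A
feature's methylation is the unweighted mean of per-CpG levels over the
covered CpGs it contains, defined only when at least ``min_cpgs``
(default 3) CpGs are covered.  The *consolidated* gene set keeps genes
whose methylation is defined in every sample; it is the universe for
all categorical analyses downstream.

Conversion efficiency of the enzymatic conversion is estimated from the
unmethylated Lambda spike-in as 100 minus the pooled percent of
methylated calls on the control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CpGRecord, GenomeAnnotation

__all__ = [
    "MethylationCall",
    "call_cpg_levels",
    "conversion_efficiency",
    "consolidated_gene_set",
    "feature_methylation",
    "merge_dyads",
    "methylation_status",
    "region_class_summary",
    "split_control_records",
]


@dataclass(frozen=True)
class MethylationCall:
    """A covered CpG with its percent methylation level."""

    chrom: str
    pos: int  # 1-based cytosine position
    level: float  # percent in [0, 100]
    coverage: int


def call_cpg_levels(
    records: Iterable[CpGRecord], min_coverage: int = 5
) -> list[MethylationCall]:
    """Call per-CpG methylation levels for one sample.

    Sites with coverage below ``min_coverage`` are dropped.  Negative
    counts raise (already enforced on :class:`CpGRecord` construction,
    re-checked here for records built elsewhere).
    """
    calls = []
    for r in records:
        if r.count_meth < 0 or r.count_unmeth < 0:
            raise ValueError(f"negative read count at {r.chrom}:{r.pos}")
        cov = r.count_meth + r.count_unmeth
        if cov < min_coverage:
            continue
        calls.append(
            MethylationCall(r.chrom, r.pos, 100.0 * r.count_meth / cov, cov)
        )
    return calls


def merge_dyads(records: Sequence[CpGRecord]) -> list[CpGRecord]:
    """Merge + and - strand calls of one CpG dyad into a single site.

    The minus-strand cytosine of a CpG sits one base downstream of the
    plus-strand one; counts are summed onto the plus-strand position.
    Records with unknown strand are passed through unchanged.
    """
    pooled: dict[tuple[str, int], list[int]] = {}
    passthrough: list[CpGRecord] = []
    for r in records:
        if r.strand == "+":
            key = (r.chrom, r.pos)
        elif r.strand == "-":
            key = (r.chrom, r.pos - 1)
        else:
            passthrough.append(r)
            continue
        agg = pooled.setdefault(key, [0, 0])
        agg[0] += r.count_meth
        agg[1] += r.count_unmeth
    merged = [
        CpGRecord(chrom, pos, "+", m, u) for (chrom, pos), (m, u) in pooled.items()
    ]
    merged.sort(key=lambda r: (r.chrom, r.pos))
    return merged + passthrough


def split_control_records(
    records: Iterable[CpGRecord], control_chroms: Sequence[str] = ("Lambda", "pUC19")
) -> tuple[list[CpGRecord], dict[str, list[CpGRecord]]]:
    """Separate genomic records from spike-in control records."""
    controls: dict[str, list[CpGRecord]] = {c: [] for c in control_chroms}
    genomic = []
    for r in records:
        if r.chrom in controls:
            controls[r.chrom].append(r)
        else:
            genomic.append(r)
    return genomic, controls


def conversion_efficiency(control_records: Iterable[CpGRecord]) -> float | None:
    """Percent conversion efficiency from the unmethylated control.

    100 minus the pooled percent of methylated calls over all control
    cytosines.  Returns ``None`` when the control has no coverage.
    """
    meth = total = 0
    for r in control_records:
        meth += r.count_meth
        total += r.count_meth + r.count_unmeth
    if total == 0:
        return None
    return 100.0 - 100.0 * meth / total


def methylation_status(mean_level: float, threshold: float = 10.0) -> str:
    """"not methylated" strictly below ``threshold`` percent, else "methylated"."""
    return "not methylated" if mean_level < threshold else "methylated"


def feature_methylation(
    calls: Sequence[MethylationCall],
    features: Mapping[str, Sequence[tuple[str, int, int]]],
    min_cpgs: int = 3,
) -> pd.DataFrame:
    """Mean percent methylation per feature.

    ``features`` maps feature id to a list of ``(chrom, start, end)``
    blocks in 0-based half-open coordinates (a gene span is one block;
    an exon chain is several).  Returns a DataFrame indexed by feature
    id with columns ``n_cpgs_covered``, ``mean_level`` (NaN when
    undefined) and ``defined``.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in _calls_frame(calls).groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        by_chrom[chrom] = (sub["pos"].to_numpy(), sub["level"].to_numpy())

    ids, n_cpgs, means = [], [], []
    for fid, blocks in features.items():
        levels: list[np.ndarray] = []
        for chrom, start, end in blocks:
            if chrom not in by_chrom:
                continue
            pos, lev = by_chrom[chrom]
            # CpG at 1-based pos p occupies 0-based base p-1
            lo = np.searchsorted(pos, start + 1, side="left")
            hi = np.searchsorted(pos, end, side="right")
            if hi > lo:
                levels.append(lev[lo:hi])
        n = int(sum(len(x) for x in levels))
        ids.append(fid)
        n_cpgs.append(n)
        means.append(float(np.concatenate(levels).mean()) if n >= min_cpgs else np.nan)
    df = pd.DataFrame(
        {"n_cpgs_covered": n_cpgs, "mean_level": means},
        index=pd.Index(ids, name="feature_id"),
    )
    df["defined"] = df["n_cpgs_covered"] >= min_cpgs
    return df


def _calls_frame(calls: Sequence[MethylationCall]) -> pd.DataFrame:
    if len(calls) == 0:
        return pd.DataFrame(columns=["chrom", "pos", "level", "coverage"])
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "pos": [c.pos for c in calls],
            "level": [c.level for c in calls],
            "coverage": [c.coverage for c in calls],
        }
    )


def gene_feature_map(
    ann: GenomeAnnotation, span: str = "gene"
) -> dict[str, list[tuple[str, int, int]]]:
    """Per-gene block lists for :func:`feature_methylation`.

    ``span="gene"`` uses the full gene span (exons + introns);
    ``span="exons"`` restricts to exonic blocks.
    """
    if span == "gene":
        return {g.gene_id: [(g.chrom, g.start, g.end)] for g in ann}
    if span == "exons":
        return {g.gene_id: [(g.chrom, s, e) for s, e in g.exons] for g in ann}
    raise ValueError(f"unknown span {span!r}")


def consolidated_gene_set(
    per_sample_feature_meth: Mapping[str, pd.DataFrame],
) -> set[str]:
    """Genes whose methylation is defined in *every* sample.

    All samples must share one gene universe; mismatched universes
    raise, since a silent intersection would hide an annotation mixup.
    """
    if not per_sample_feature_meth:
        raise ValueError("no samples given")
    tables = list(per_sample_feature_meth.values())
    universe = set(tables[0].index)
    for name, df in per_sample_feature_meth.items():
        if set(df.index) != universe:
            raise ValueError(f"sample {name!r} has a mismatched gene universe")
    keep = universe
    for df in tables:
        keep &= set(df.index[df["defined"]])
    return keep


# ---------------------------------------------------------------------------
# region-class summary (exon / intron / intergenic / repeats)
# ---------------------------------------------------------------------------


def _class_arrays(ann: GenomeAnnotation) -> dict[str, np.ndarray]:
    """Per-chromosome class code per base: 0 intergenic, 1 intron, 2 exon."""
    out = {}
    for chrom, size in ann.chrom_sizes.items():
        codes = np.zeros(size, dtype=np.int8)
        for g in ann.genes_on(chrom):
            for s, e in g.introns:
                codes[s:e] = np.maximum(codes[s:e], 1)
        for g in ann.genes_on(chrom):
            for s, e in g.exons:
                codes[s:e] = 2  # exon wins over intron (overlapping isoforms)
        # non-exon, non-intron bases inside a gene span count as intron
        for g in ann.genes_on(chrom):
            span = codes[g.start:g.end]
            span[span == 0] = 1
        out[chrom] = codes
    return out


def region_class_summary(
    calls: Sequence[MethylationCall],
    ann: GenomeAnnotation,
    repeats: Sequence | None = None,
) -> pd.DataFrame:
    """Mean CpG level, CpG count and genome fraction per region class.

    Classes are exon, intron and intergenic, with positions in both an
    exon and an intron of overlapping isoforms counted as exon.  When a
    repeat BED is supplied, a ``repeat`` row summarises CpGs inside
    repeat intervals (repeats overlay the three base classes and are
    not part of the genome-fraction partition).
    """
    class_of = _class_arrays(ann)
    names = {0: "intergenic", 1: "intron", 2: "exon"}
    sums = {n: 0.0 for n in names.values()}
    counts = {n: 0 for n in names.values()}
    for c in calls:
        codes = class_of.get(c.chrom)
        if codes is None:
            continue
        cls = names[int(codes[c.pos - 1])]
        sums[cls] += c.level
        counts[cls] += 1

    genome_bp = sum(ann.chrom_sizes.values())
    bp = {
        names[code]: int(sum((arr == code).sum() for arr in class_of.values()))
        for code in names
    }
    rows = []
    for cls in ("exon", "intron", "intergenic"):
        rows.append(
            {
                "region_class": cls,
                "mean_level": sums[cls] / counts[cls] if counts[cls] else np.nan,
                "n_cpgs": counts[cls],
                "genome_fraction_pct": 100.0 * bp[cls] / genome_bp,
            }
        )

    if repeats:
        rep_pos: dict[str, list[tuple[int, int]]] = {}
        for iv in repeats:
            rep_pos.setdefault(iv.chrom, []).append((iv.start, iv.end))
        rep_bases = 0
        masks = {}
        for chrom, ivs in rep_pos.items():
            size = ann.chrom_sizes.get(chrom, max(e for _s, e in ivs))
            mask = np.zeros(size, dtype=bool)
            for s, e in ivs:
                mask[s:e] = True
            masks[chrom] = mask
            rep_bases += int(mask.sum())
        s = n = 0
        for c in calls:
            mask = masks.get(c.chrom)
            if mask is not None and c.pos - 1 < len(mask) and mask[c.pos - 1]:
                s += c.level
                n += 1
        rows.append(
            {
                "region_class": "repeat",
                "mean_level": s / n if n else np.nan,
                "n_cpgs": n,
                "genome_fraction_pct": 100.0 * rep_bases / genome_bp,
            }
        )
    return pd.DataFrame(rows)


def genome_wide_methylation(
    calls: Sequence[MethylationCall], threshold: float = 10.0
) -> dict[str, float]:
    """Two readings of "percent of all CpGs methylated".

    ``mean_level``: mean per-CpG percent level over covered CpGs.
    ``fraction_methylated``: percent of covered CpGs at or above
    ``threshold``.  Both are reported because the genome-wide summary
    statistic can be defined either way.
    """
    if len(calls) == 0:
        return {"mean_level": float("nan"), "fraction_methylated": float("nan")}
    levels = np.array([c.level for c in calls])
    return {
        "mean_level": float(levels.mean()),
        "fraction_methylated": float(100.0 * (levels >= threshold).mean()),
    }
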