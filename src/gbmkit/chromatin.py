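"""CUT&Tag peak calling, consolidation and gene-mark overlap statistics.

Peak calling follows the sparse-enrichment idea: maximal runs of
positive signal in a coverage track become blocks scored by their area
under the curve (AUC); the top fraction of blocks by AUC (default
2.5%) are kept per replicate.  High-confidence peaks are the merged
regions covered by a retained peak in *every* replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GenomeAnnotation, Interval, SignalTrack
from .integration import hypergeom_overlap_p

__all__ = [
    "Peak",
    "assign_peaks",
    "call_peaks",
    "category_mark_enrichment",
    "consolidate_replicates",
    "gene_mark_overlap",
    "peaks_to_bed",
    "select_top_fraction",
    "signal_blocks",
]


@dataclass(frozen=True)
class Peak:
    """A scored signal block, 0-based half-open."""

    chrom: str
    start: int
    end: int
    auc: float
    max_value: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty peak")
        if self.auc <= 0:
            raise ValueError("peak with non-positive AUC")


def signal_blocks(track: SignalTrack) -> list[Peak]:
    """Maximal runs of adjacent positive-signal intervals.

    Adjacent means touching coordinates; a zero-valued or absent
    stretch ends the block.  AUC is the sum of value x width over the
    member intervals.
    """
    peaks: list[Peak] = []
    for chrom, ivs in track.intervals.items():
        cur_start = cur_end = None
        auc = peak_max = 0.0
        for start, end, value in ivs:
            if value <= 0:
                continue
            if cur_end is not None and start == cur_end:
                cur_end = end
                auc += value * (end - start)
                peak_max = max(peak_max, value)
            else:
                if cur_end is not None:
                    peaks.append(Peak(chrom, cur_start, cur_end, auc, peak_max))
                cur_start, cur_end = start, end
                auc = value * (end - start)
                peak_max = value
        if cur_end is not None:
            peaks.append(Peak(chrom, cur_start, cur_end, auc, peak_max))
    return peaks


def select_top_fraction(blocks: Sequence[Peak], fraction: float = 0.025) -> list[Peak]:
    """Keep the ceil(fraction x n) blocks with the highest AUC.

    Ties at the cutoff break by max_value, then genomic order, so the
    retained set is independent of input order.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not blocks:
        return []
    k = math.ceil(fraction * len(blocks))
    ranked = sorted(
        blocks, key=lambda p: (-p.auc, -p.max_value, p.chrom, p.start, p.end)
    )
    top = ranked[:k]
    top.sort(key=lambda p: (p.chrom, p.start, p.end))
    return top


def call_peaks(track: SignalTrack, fraction: float = 0.025) -> list[Peak]:
    """signal_blocks + select_top_fraction in one call."""
    return select_top_fraction(signal_blocks(track), fraction)


def _merge(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Merge overlapping-or-touching intervals into maximal ones."""
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out.pop()
            out.append((chrom, prev[1], max(prev[2], end)))
        else:
            out.append((chrom, start, end))
    return out


def consolidate_replicates(peak_sets: Sequence[Sequence[Peak]]) -> list[Peak]:
    """High-confidence peaks: regions covered in every replicate, merged.

    The n-way intersection (>= 1 bp overlap) of the replicate peak
    sets is computed and overlapping fragments are merged into maximal
    intervals.  Each output peak carries the summed AUC of its source
    fragments weighted by the first replicate's peaks (AUC bookkeeping
    only; downstream use is interval overlap).
    """
    if len(peak_sets) < 2:
        raise ValueError("need at least two replicate peak sets")

    def cover(peaks: Sequence[Peak]) -> list[tuple[str, int, int]]:
        return _merge([(p.chrom, p.start, p.end) for p in peaks])

    common = cover(peak_sets[0])
    for other in peak_sets[1:]:
        other_cov = cover(other)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in other_cov:
            by_chrom.setdefault(chrom, []).append((s, e))
        next_common = []
        for chrom, s, e in common:
            for os, oe in by_chrom.get(chrom, []):
                lo, hi = max(s, os), min(e, oe)
                if lo < hi:
                    next_common.append((chrom, lo, hi))
        common = _merge(next_common)

    # score merged regions by AUC of overlapping replicate-1 peaks
    out = []
    for chrom, s, e in common:
        auc = sum(
            p.auc for p in peak_sets[0] if p.chrom == chrom and p.start < e and p.end > s
        )
        mx = max(
            (p.max_value for p in peak_sets[0] if p.chrom == chrom and p.start < e and p.end > s),
            default=0.0,
        )
        out.append(Peak(chrom, s, e, max(auc, 1e-12), mx))
    return out


def _gene_trees(ann: GenomeAnnotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in ann:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
    return trees


def assign_peaks(
    peaks: Sequence[Peak], ann: GenomeAnnotation
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Classify peaks as genic (>= 1 bp gene overlap) or intergenic.

    Returns the per-peak table and the genic/intergenic percentages.
    """
    trees = _gene_trees(ann)
    rows = []
    for p in peaks:
        tree = trees.get(p.chrom)
        genic = bool(tree is not None and tree.overlap(p.start, p.end))
        rows.append(
            {"chrom": p.chrom, "start": p.start, "end": p.end, "auc": p.auc, "genic": genic}
        )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "auc", "genic"])
    n = len(df)
    genic_pct = 100.0 * df["genic"].sum() / n if n else float("nan")
    return df, {
        "genic_pct": genic_pct,
        "intergenic_pct": 100.0 - genic_pct if n else float("nan"),
    }


def gene_mark_overlap(
    ann: GenomeAnnotation,
    peaks_by_mark: Mapping[str, Sequence[Peak]],
    gene_sets: Mapping[str, set[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene mark overlap booleans plus per-set summaries.

    A gene carries a mark when its span overlaps any high-confidence
    peak of that mark by >= 1 bp.  ``gene_sets`` (e.g. the four
    methylation x expression categories or expressed/not expressed)
    receive percent-with-either-mark and percent-with-both-marks
    summaries.
    """
    marks = list(peaks_by_mark)
    flags = pd.DataFrame(
        False, index=pd.Index(ann.gene_ids(), name="gene_id"), columns=marks
    )
    for mark, peaks in peaks_by_mark.items():
        trees: dict[str, IntervalTree] = {}
        for p in peaks:
            trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
        for g in ann:
            tree = trees.get(g.chrom)
            if tree is not None and tree.overlap(g.start, g.end):
                flags.loc[g.gene_id, mark] = True
    flags["either"] = flags[marks].any(axis=1)
    flags["both"] = flags[marks].all(axis=1) if len(marks) > 1 else flags[marks[0]]

    rows = []
    for name, genes in (gene_sets or {}).items():
        sub = flags.loc[flags.index.intersection(list(genes))]
        n = len(sub)
        row = {"gene_set": name, "n_genes": n}
        for col in (*marks, "either", "both"):
            row[f"{col}_pct"] = 100.0 * sub[col].mean() if n else float("nan")
        rows.append(row)
    return flags, pd.DataFrame(rows)


def category_mark_enrichment(
    category_sets: Mapping[str, set[str]],
    marked_gene_set: set[str],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a mark in each category."""
    marked = marked_gene_set & universe
    rows = []
    for cat, genes in category_sets.items():
        a = genes & universe
        k = len(a & marked)
        rows.append(
            {
                "category": cat,
                "n_category": len(a),
                "n_marked": len(marked),
                "n_overlap": k,
                "p": hypergeom_overlap_p(len(universe), len(a), len(marked), k),
            }
        )
    return pd.DataFrame(rows)


def peaks_to_bed(peaks: Sequence[Peak]) -> list[Interval]:
    return [
        Interval(p.chrom, p.start, p.end, f"peak_{i + 1}", float(p.auc), ".")
        for i, p in enumerate(peaks)
    ]
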