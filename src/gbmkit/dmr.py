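"""Differentially methylated region (DMR) calling between two stages.

Input CpGs must be covered by 5-100 reads in every replicate of both
groups.  CpG runs (broken at inter-CpG gaps above ``max_gap`` bp) are
segmented by recursive binary splitting on the per-CpG group mean
difference; leaves with at least ``min_cpgs`` CpGs and an absolute mean
difference of at least ``min_diff`` percentage points become
candidates.  Candidates are tested with a two-sided Mann-Whitney U on
the pooled per-CpG replicate levels of the two groups and
Benjamini-Hochberg corrected; regions with q below ``alpha`` are
reported as DMRs, *hypomethylated* when the second group (adult) is
lower than the first (embryo) and *hypermethylated* otherwise.

Because segmentation *selects* the most extreme regions, raw
Mann-Whitney p-values computed on the same data are anti-conservative.
By default the test is therefore permutation-calibrated: candidate
regions are re-derived under all balanced relabelings of the samples,
their raw MWU p-values pooled as the null distribution, and each
observed candidate's p-value is its rank within that pool (the
approach familiar from permutation-based DMR callers).  BH then runs
on the calibrated p-values, restoring type-I control under the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io_formats import CpGRecord, GenomeAnnotation, Interval

__all__ = [
    "DMR",
    "annotate_dmrs",
    "build_cpg_matrix",
    "call_dmrs",
    "dmr_input_filter",
    "segment_candidates",
    "test_dmrs",
    "dmrs_to_bed",
]


@dataclass(frozen=True)
class DMR:
    """A significant differentially methylated region.

    ``mean_diff`` is group2 mean minus group1 mean in percentage
    points (adult minus embryo in the study design); ``direction`` is
    ``hypo`` when group2 is lower.
    """

    chrom: str
    start: int  # 0-based half-open span of member CpGs
    end: int
    n_cpgs: int
    mean_diff: float
    p_raw: float
    q_bh: float

    @property
    def direction(self) -> str:
        return "hypo" if self.mean_diff < 0 else "hyper"


@dataclass(frozen=True)
class Candidate:
    chrom: str
    positions: tuple[int, ...]  # 1-based CpG positions
    mean_diff: float


def build_cpg_matrix(
    per_sample_records: Mapping[str, Sequence[CpGRecord]],
    group1: Sequence[str],
    group2: Sequence[str],
) -> pd.DataFrame:
    """Long-format per-site coverage/level table for all samples.

    Index is (chrom, pos); columns are a MultiIndex (sample, field)
    with fields ``level`` (percent) and ``coverage``.  Sites absent
    from a sample hold NaN.
    """
    frames = {}
    for sample, records in per_sample_records.items():
        if len(records) == 0:
            frames[sample] = pd.DataFrame(
                columns=["level", "coverage"],
                index=pd.MultiIndex.from_tuples([], names=["chrom", "pos"]),
            )
            continue
        idx = pd.MultiIndex.from_arrays(
            [[r.chrom for r in records], [r.pos for r in records]],
            names=["chrom", "pos"],
        )
        cov = np.array([r.count_meth + r.count_unmeth for r in records], dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            level = 100.0 * np.array([r.count_meth for r in records]) / cov
        frames[sample] = pd.DataFrame({"level": level, "coverage": cov}, index=idx)
    mat = pd.concat(frames, axis=1)
    mat.attrs["group1"] = list(group1)
    mat.attrs["group2"] = list(group2)
    return mat.sort_index()


def dmr_input_filter(
    per_sample_records: Mapping[str, Sequence[CpGRecord]],
    group1: Sequence[str],
    group2: Sequence[str],
    min_cov: int = 5,
    max_cov: int = 100,
) -> pd.DataFrame:
    """Keep CpGs covered by ``min_cov``..``max_cov`` reads (inclusive)
    in every replicate of both groups."""
    if len(group1) == 0 or len(group2) == 0:
        raise ValueError("both groups need at least one replicate")
    missing = [s for s in (*group1, *group2) if s not in per_sample_records]
    if missing:
        raise ValueError(f"records missing for samples {missing}")
    mat = build_cpg_matrix(per_sample_records, group1, group2)
    samples = list(group1) + list(group2)
    cov = mat.loc[:, [(s, "coverage") for s in samples]]
    ok = ((cov >= min_cov) & (cov <= max_cov)).all(axis=1)
    return mat.loc[ok]


def _best_split(diffs: np.ndarray, min_cpgs: int) -> tuple[int, float] | None:
    """Split index maximizing |mean(left) - mean(right)|.

    Only splits leaving both children with >= min_cpgs CpGs are
    considered.  Returns (index, criterion) or None.
    """
    n = len(diffs)
    if n < 2 * min_cpgs:
        return None
    csum = np.cumsum(diffs)
    total = csum[-1]
    ks = np.arange(min_cpgs, n - min_cpgs + 1)
    left_mean = csum[ks - 1] / ks
    right_mean = (total - csum[ks - 1]) / (n - ks)
    crit = np.abs(left_mean - right_mean)
    best = int(np.argmax(crit))
    return int(ks[best]), float(crit[best])


def segment_candidates(
    cpg_matrix: pd.DataFrame,
    max_gap: int = 300,
    min_cpgs: int = 10,
    min_diff: float = 10.0,
    groups: tuple[Sequence[str], Sequence[str]] | None = None,
) -> list[Candidate]:
    """Recursive mean-difference segmentation into candidate regions.

    Within each gap-delimited CpG run the split point maximizing the
    absolute difference of child mean differences is taken, recursing
    while both children keep ``min_cpgs`` CpGs and the better child
    improves on the parent's |mean difference|.  Leaves with
    |mean difference| >= ``min_diff`` become candidates.
    """
    if groups is None:
        g1, g2 = cpg_matrix.attrs["group1"], cpg_matrix.attrs["group2"]
    else:
        g1, g2 = groups
    lev1 = cpg_matrix.loc[:, [(s, "level") for s in g1]].to_numpy()
    lev2 = cpg_matrix.loc[:, [(s, "level") for s in g2]].to_numpy()
    diffs = lev2.mean(axis=1) - lev1.mean(axis=1)
    chroms = cpg_matrix.index.get_level_values("chrom").to_numpy()
    poss = cpg_matrix.index.get_level_values("pos").to_numpy()

    candidates: list[Candidate] = []

    def refine(pos: np.ndarray, d: np.ndarray, i0: int, i1: int) -> tuple[int, int]:
        """Local boundary search around a leaf [i0, i1).

        Greedy splitting can shear a few CpGs off a true region or leave
        diluting flanks attached; re-anchor the candidate on the nearby
        window maximizing the *penalized* area
        ``sum(sign * diff - min_diff)``: a CpG joins the window only
        when it contributes beyond the minimum effect size, so noise
        flanks (expected contribution < 0) stop the extension while
        true-region CpGs (effect >> min_diff) extend it.
        """
        w = 2 * min_cpgs
        lo, hi = max(0, i0 - w), min(len(d), i1 + w)
        sign = 1.0 if d[i0:i1].mean() >= 0 else -1.0
        scores = sign * d[lo:hi] - min_diff
        csum = np.concatenate([[0.0], np.cumsum(scores)])
        best_key, best_win = None, (i0, i1)
        for s in range(lo, hi - min_cpgs + 1):
            for e in range(s + min_cpgs, hi + 1):
                if e <= i0 or s >= i1:
                    continue  # stay anchored on the original leaf
                area = csum[e - lo] - csum[s - lo]
                key = (round(area, 9), e - s, -s)
                if best_key is None or key > best_key:
                    best_key, best_win = key, (s, e)
        return best_win

    def leaves(chrom: str, pos: np.ndarray, d: np.ndarray, i0: int, i1: int) -> None:
        seg = d[i0:i1]
        parent_mean = abs(seg.mean())
        split = _best_split(seg, min_cpgs)
        if split is not None:
            k, _ = split
            child_best = max(abs(seg[:k].mean()), abs(seg[k:].mean()))
            if child_best > parent_mean:
                leaves(chrom, pos, d, i0, i0 + k)
                leaves(chrom, pos, d, i0 + k, i1)
                return
        if len(seg) >= min_cpgs and abs(seg.mean()) >= min_diff:
            s, e = refine(pos, d, i0, i1)
            mean = float(d[s:e].mean())
            if abs(mean) >= min_diff:
                candidates.append(
                    Candidate(chrom, tuple(int(p) for p in pos[s:e]), mean)
                )

    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        pos_c, d_c = poss[sel], diffs[sel]
        if len(pos_c) == 0:
            continue
        # break runs at gaps > max_gap
        breaks = np.where(np.diff(pos_c) > max_gap)[0] + 1
        for seg_pos, seg_d in zip(np.split(pos_c, breaks), np.split(d_c, breaks)):
            if len(seg_pos) >= min_cpgs:
                leaves(str(chrom), seg_pos, seg_d, 0, len(seg_pos))

    # refinement can re-anchor neighbouring leaves onto overlapping
    # windows: resolve overlaps in favour of the stronger candidate
    candidates.sort(key=lambda c: (-abs(c.mean_diff), c.chrom, c.positions[0]))
    accepted: list[Candidate] = []
    for cand in candidates:
        clash = any(
            a.chrom == cand.chrom
            and cand.positions[0] <= a.positions[-1]
            and cand.positions[-1] >= a.positions[0]
            for a in accepted
        )
        if not clash:
            accepted.append(cand)
    accepted.sort(key=lambda c: (c.chrom, c.positions[0]))
    return accepted


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(pvals, method="fdr_bh")[1]


def _mwu_pvals(
    candidates: Sequence[Candidate],
    cpg_matrix: pd.DataFrame,
    g1: Sequence[str],
    g2: Sequence[str],
) -> list[float]:
    """Raw two-sided MWU p per candidate on pooled CpG x replicate levels."""
    pvals = []
    for cand in candidates:
        idx = pd.MultiIndex.from_product([[cand.chrom], list(cand.positions)])
        sub = cpg_matrix.loc[idx]
        x = sub.loc[:, [(s, "level") for s in g1]].to_numpy().ravel()
        y = sub.loc[:, [(s, "level") for s in g2]].to_numpy().ravel()
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) == 0 or len(y) == 0 or (np.ptp(np.concatenate([x, y])) == 0):
            pvals.append(1.0)  # constant data: no evidence by convention
            continue
        pvals.append(float(mannwhitneyu(x, y, alternative="two-sided").pvalue))
    return pvals


def _balanced_splits(
    g1: Sequence[str], g2: Sequence[str], max_perms: int = 50
) -> list[tuple[list[str], list[str]]]:
    """Distinct relabelings of the pooled samples into groups of the
    original sizes, excluding the observed labeling (and, for equal
    group sizes, its mirror)."""
    from itertools import combinations

    pooled = list(g1) + list(g2)
    n1 = len(g1)
    observed = {frozenset(g1), frozenset(g2) if len(g2) == n1 else None}
    seen: set[frozenset] = set()
    out = []
    for comb in combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in comb]
        b = [pooled[i] for i in range(len(pooled)) if i not in comb]
        key = frozenset(a)
        mirror = frozenset(b) if len(b) == n1 else None
        if key in observed or key in seen or (mirror is not None and mirror in seen):
            continue
        seen.add(key)
        out.append((a, b))
        if len(out) >= max_perms:
            break
    return out


def test_dmrs(
    candidates: Sequence[Candidate],
    cpg_matrix: pd.DataFrame,
    alpha: float = 0.05,
    min_cpgs: int = 10,
    min_diff: float = 10.0,
    max_gap: int = 300,
    calibrate: bool = True,
    max_perms: int = 50,
) -> list[DMR]:
    """Mann-Whitney U + BH over candidate regions.

    Each candidate is tested two-sided on the pooled per-CpG replicate
    levels of the two groups (replicate x CpG observations).  With
    ``calibrate=True`` (default) the raw MWU p-values are converted to
    permutation p-values: candidates are re-derived under balanced
    sample relabelings, their raw p-values pooled as the null, and
    each observed candidate scored by its rank in the pool — this
    corrects for the segmentation having selected extreme regions.
    BH runs across candidates; survivors must also satisfy the region
    criteria (>= ``min_cpgs`` CpGs, |mean difference| >= ``min_diff``).
    """
    if not candidates:
        return []
    g1, g2 = cpg_matrix.attrs["group1"], cpg_matrix.attrs["group2"]
    raw = _mwu_pvals(candidates, cpg_matrix, g1, g2)
    if calibrate:
        null_pool: list[float] = []
        for pg1, pg2 in _balanced_splits(g1, g2, max_perms):
            perm_cands = segment_candidates(
                cpg_matrix, max_gap=max_gap, min_cpgs=min_cpgs,
                min_diff=min_diff, groups=(pg1, pg2),
            )
            null_pool.extend(_mwu_pvals(perm_cands, cpg_matrix, pg1, pg2))
        if null_pool:
            null_arr = np.sort(np.asarray(null_pool))
            pvals = [
                float((1 + np.searchsorted(null_arr, p, side="right"))
                      / (1 + len(null_arr)))
                for p in raw
            ]
        else:
            pvals = raw  # no permuted candidates anywhere: raw p stands
    else:
        pvals = raw
    qvals = bh_adjust(pvals)

    dmrs = []
    for cand, p, q in zip(candidates, pvals, qvals):
        if q >= alpha:
            continue
        if len(cand.positions) < min_cpgs or abs(cand.mean_diff) < min_diff:
            continue
        dmrs.append(
            DMR(
                chrom=cand.chrom,
                start=cand.positions[0] - 1,
                end=cand.positions[-1],
                n_cpgs=len(cand.positions),
                mean_diff=cand.mean_diff,
                p_raw=float(p),
                q_bh=float(q),
            )
        )
    dmrs.sort(key=lambda d: (d.chrom, d.start))
    return dmrs


def call_dmrs(
    per_sample_records: Mapping[str, Sequence[CpGRecord]],
    group1: Sequence[str],
    group2: Sequence[str],
    min_cov: int = 5,
    max_cov: int = 100,
    max_gap: int = 300,
    min_cpgs: int = 10,
    min_diff: float = 10.0,
    alpha: float = 0.05,
    calibrate: bool = True,
    max_perms: int = 50,
) -> list[DMR]:
    """Filter, segment and test in one call."""
    mat = dmr_input_filter(per_sample_records, group1, group2, min_cov, max_cov)
    cands = segment_candidates(mat, max_gap=max_gap, min_cpgs=min_cpgs, min_diff=min_diff)
    return test_dmrs(
        cands, mat, alpha=alpha, min_cpgs=min_cpgs, min_diff=min_diff,
        max_gap=max_gap, calibrate=calibrate, max_perms=max_perms,
    )


# ---------------------------------------------------------------------------
# feature annotation
# ---------------------------------------------------------------------------


def annotate_dmrs(
    dmrs: Sequence[DMR], ann: GenomeAnnotation
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify DMRs by the genic features they overlap.

    Per-DMR classes: ``exon-only``, ``intron-only``, ``exon+intron``
    (overlaps both feature types, possibly across genes) and
    ``intergenic``.  Returns (per-DMR table, per-class count table);
    the count table also carries genic/intergenic counts per direction.
    """
    rows = []
    for d in dmrs:
        hits_exon = hits_intron = in_gene = False
        for g in ann.genes_on(d.chrom):
            if g.end <= d.start or g.start >= d.end:
                continue
            in_gene = True
            for s, e in g.exons:
                if s < d.end and e > d.start:
                    hits_exon = True
            for s, e in g.introns:
                if s < d.end and e > d.start:
                    hits_intron = True
        if not in_gene:
            cls = "intergenic"
        elif hits_exon and hits_intron:
            cls = "exon+intron"
        elif hits_exon:
            cls = "exon-only"
        elif hits_intron:
            cls = "intron-only"
        else:  # inside a gene span but in no modelled feature: treat as intron
            cls = "intron-only"
        rows.append(
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "direction": d.direction,
                "feature_class": cls,
                "genic": in_gene,
            }
        )
    per_dmr = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "direction", "feature_class", "genic"],
    )
    if len(per_dmr):
        counts = (
            per_dmr.groupby(["direction", "feature_class"]).size().rename("n").reset_index()
        )
    else:
        counts = pd.DataFrame(columns=["direction", "feature_class", "n"])
    return per_dmr, counts


def dmrs_to_bed(dmrs: Sequence[DMR]) -> list[Interval]:
    """BED6 representation: name=direction, score=-log10 q."""
    out = []
    for d in dmrs:
        score = -np.log10(d.q_bh) if d.q_bh > 0 else 999.0
        out.append(Interval(d.chrom, d.start, d.end, d.direction, float(score), "."))
    return out
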