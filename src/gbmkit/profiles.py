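"""Metagene, anchored and exon/intron segment profiles.

Metagene matrices scale every gene body to a common length (default
5 kb) flanked by fixed 3 kb windows, binned at 50 bp; minus-strand
genes are reversed so column 0 is always the 5'-most bin.  Body
scaling assigns each scaled base the value of its pre-image base
(floor mapping), making the operation exactly reproducible by hand on
small inputs.  Methylation profiles average per-CpG percent levels per
bin and leave bins without covered CpGs missing; signal profiles
average per-base track values.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import Gene, GenomeAnnotation, SignalTrack
from .methylome import MethylationCall

__all__ = [
    "anchored_profile",
    "metagene_matrix",
    "segment_profile",
    "set_mean_profile",
]


def _index_calls(calls: Iterable[MethylationCall]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by: dict[str, tuple[list[int], list[float]]] = {}
    for c in calls:
        by.setdefault(c.chrom, ([], []))[0].append(c.pos - 1)
        by[c.chrom][1].append(c.level)
    out = {}
    for chrom, (pos, lev) in by.items():
        order = np.argsort(pos)
        out[chrom] = (np.asarray(pos)[order], np.asarray(lev)[order])
    return out


class _TrackSource:
    """Random-access per-base view over a step-function signal track."""

    def __init__(self, track: SignalTrack):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivs in track.intervals.items():
            if ivs:
                arr = np.asarray(ivs, dtype=float)
                self.by_chrom[chrom] = (
                    arr[:, 0].astype(int),
                    arr[:, 1].astype(int),
                    arr[:, 2],
                )

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        vals = np.zeros(end - start)
        got = self.by_chrom.get(chrom)
        if got is not None:
            starts, ends, values = got
            lo_i = int(np.searchsorted(ends, start, side="right"))
            hi_i = int(np.searchsorted(starts, end, side="left"))
            for s, e, v in zip(starts[lo_i:hi_i], ends[lo_i:hi_i], values[lo_i:hi_i]):
                lo, hi = max(s, start), min(e, end)
                if lo < hi:
                    vals[lo - start : hi - start] = v
        if start < 0:
            vals[: -start] = np.nan
        return vals


class _CallSource:
    """Random-access per-base view over methylation calls."""

    def __init__(self, calls: Iterable[MethylationCall]):
        self.by_chrom = _index_calls(calls)

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        vals = np.full(end - start, np.nan)
        got = self.by_chrom.get(chrom)
        if got is not None:
            pos, lev = got
            lo = np.searchsorted(pos, max(start, 0))
            hi = np.searchsorted(pos, end)
            for p, v in zip(pos[lo:hi], lev[lo:hi]):
                vals[p - start] = v
        return vals


def _make_source(source):
    if isinstance(source, (_CallSource, _TrackSource)):
        return source
    if isinstance(source, SignalTrack):
        return _TrackSource(source)
    return _CallSource(source)


def _window(source, chrom: str, start: int, end: int) -> np.ndarray:
    return _make_source(source).window(chrom, start, end)


def _bin_means(values: np.ndarray, bin_size: int) -> np.ndarray:
    """Mean of non-missing values per bin; NaN when a bin is all-missing."""
    n_bins = len(values) // bin_size
    chunks = values[: n_bins * bin_size].reshape(n_bins, bin_size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins stay NaN
        return np.nanmean(chunks, axis=1)


def _scale_body(values: np.ndarray, target: int) -> np.ndarray:
    """Map per-base values onto ``target`` bases by floor pre-image lookup."""
    n = len(values)
    if n == 0:
        raise ValueError("zero-length gene body")
    src = (np.arange(target) * n) // target
    return values[src]


def metagene_matrix(
    source,
    genes: Sequence[Gene],
    body: int = 5000,
    flank: int = 3000,
    bin_size: int = 50,
) -> pd.DataFrame:
    """Genes x bins matrix: 5' flank, scaled body, 3' flank.

    ``source`` is a :class:`SignalTrack` or an iterable of
    :class:`MethylationCall`.  Rows of minus-strand genes are reversed
    so bins run 5' to 3' in transcription order.
    """
    if body % bin_size or flank % bin_size:
        raise ValueError("body and flank must be multiples of bin_size")
    src = _make_source(source)
    n_bins = (2 * flank + body) // bin_size
    rows, ids = [], []
    for g in genes:
        if g.length < 1:
            raise ValueError(f"zero-length gene {g.gene_id}")
        left = _window(src, g.chrom, g.start - flank, g.start)
        bod = _window(src, g.chrom, g.start, g.end)
        right = _window(src, g.chrom, g.end, g.end + flank)
        # orient to transcription direction *before* scaling so the
        # floor pre-image map treats both strands mirror-symmetrically
        if g.strand == "-":
            up, bod, down = right[::-1], bod[::-1], left[::-1]
        else:
            up, down = left, right
        per_base = np.concatenate([up, _scale_body(bod, body), down])
        rows.append(_bin_means(per_base, bin_size))
        ids.append(g.gene_id)
    mat = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, n_bins)),
        index=pd.Index(ids, name="gene_id"),
        columns=[f"bin{i}" for i in range(n_bins)],
    )
    mat.attrs.update({"body": body, "flank": flank, "bin_size": bin_size})
    return mat


def anchored_profile(
    source,
    genes: Sequence[Gene],
    anchor: str = "TSS",
    flank: int = 500,
    bin_size: int = 50,
) -> pd.DataFrame:
    """Fixed +-``flank`` window around the strand-aware TSS or TES.

    No scaling; bins run 5' to 3'.  Windows truncated by a chromosome
    start hold NaN in the out-of-range bins.
    """
    if anchor not in ("TSS", "TES"):
        raise ValueError("anchor must be 'TSS' or 'TES'")
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin_size")
    src = _make_source(source)
    rows, ids = [], []
    for g in genes:
        center = g.tss if anchor == "TSS" else g.tes
        per_base = _window(src, g.chrom, center - flank, center + flank)
        if g.strand == "-":
            per_base = per_base[::-1]
        rows.append(_bin_means(per_base, bin_size))
        ids.append(g.gene_id)
    n_bins = 2 * flank // bin_size
    mat = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, n_bins)),
        index=pd.Index(ids, name="gene_id"),
        columns=[f"bin{i}" for i in range(n_bins)],
    )
    mat.attrs.update({"anchor": anchor, "flank": flank, "bin_size": bin_size})
    return mat


def set_mean_profile(matrix: pd.DataFrame, gene_set: Iterable[str]) -> pd.DataFrame:
    """Column-wise mean +- SE over a gene set, ignoring missing cells."""
    sub = matrix.loc[matrix.index.intersection(list(gene_set))]
    vals = sub.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(vals, axis=0) if len(sub) else np.full(matrix.shape[1], np.nan)
        n = np.sum(~np.isnan(vals), axis=0)
        sd = np.nanstd(vals, axis=0, ddof=1) if len(sub) > 1 else np.full(matrix.shape[1], np.nan)
    se = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return pd.DataFrame({"mean": mean, "se": se, "n": n}, index=matrix.columns)


SEGMENTS = ("U", "E1", "E2", "E3", "E4", "E5", "I1", "I2", "I3", "I4", "D")


def segment_profile(
    calls: Sequence[MethylationCall],
    annotation: GenomeAnnotation,
    gene_set: Iterable[str],
    flank: int = 3000,
    min_cpgs: int = 3,
    max_exons: int = 5,
) -> pd.DataFrame:
    """Mean methylation per genic segment over a gene set.

    Segments are the upstream flank (U), the first five exons (E1..E5)
    and first four introns (I1..I4) in transcription order, and the
    downstream flank (D).  Per gene, a segment mean is defined only
    when the segment holds >= ``min_cpgs`` covered CpGs; the set-level
    value is the unweighted mean over genes where the segment is
    defined.
    """
    src = _CallSource(calls)
    gene_ids = set(gene_set)
    acc: dict[str, list[float]] = {s: [] for s in SEGMENTS}
    for gid in gene_ids:
        g = annotation.genes.get(gid)
        if g is None:
            continue
        segs: dict[str, tuple[int, int]] = {}
        if g.strand == "+":
            segs["U"] = (g.start - flank, g.start)
            segs["D"] = (g.end, g.end + flank)
        else:
            segs["U"] = (g.end, g.end + flank)
            segs["D"] = (g.start - flank, g.start)
        for i, (s, e) in enumerate(g.exons_tx_order()[:max_exons]):
            segs[f"E{i + 1}"] = (s, e)
        for i, (s, e) in enumerate(g.introns_tx_order()[: max_exons - 1]):
            segs[f"I{i + 1}"] = (s, e)
        for name, (s, e) in segs.items():
            vals = src.window(g.chrom, s, e)
            vals = vals[~np.isnan(vals)]
            if len(vals) >= min_cpgs:
                acc[name].append(float(vals.mean()))
    rows = []
    for name in SEGMENTS:
        vals = acc[name]
        rows.append(
            {
                "segment": name,
                "mean_level": float(np.mean(vals)) if vals else np.nan,
                "n_genes": len(vals),
            }
        )
    return pd.DataFrame(rows)
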