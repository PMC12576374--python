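"""Expression ingestion, expressed/not-expressed calling and replicate QC.

A gene is *expressed* in a stage when its summary FPKM (mean over
retained replicates by default) exceeds 1.  Differential-expression
results are consumed as tables (gene, log2 fold change adult vs
embryo, BH-adjusted p); genes with adjusted p below 0.05 are counted
as up- or downregulated by the sign of the fold change, "down" meaning
higher expression in the embryo.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "compute_fpkm",
    "deg_accounting",
    "expression_status",
    "replicate_qc",
    "summarize_fpkm",
]


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: Mapping[str, int],
    library_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """FPKM = count / (gene length in kb x library size in millions).

    ``counts`` is genes x samples.  Library sizes default to the column
    sums of ``counts``.
    """
    lengths = pd.Series(gene_lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"genes without length: {missing} ...")
    if (lengths <= 0).any():
        raise ValueError("zero or negative gene length")
    if library_sizes is None:
        libsizes = counts.sum(axis=0)
    else:
        libsizes = pd.Series(library_sizes).reindex(counts.columns)
    if (libsizes <= 0).any():
        raise ValueError("zero or negative library size")
    return counts.div(lengths / 1e3, axis=0).div(libsizes / 1e6, axis=1)


def expression_status(summary_fpkm: float, threshold: float = 1.0) -> str:
    """"not expressed" at FPKM ``threshold`` or below, else "expressed"."""
    return "expressed" if summary_fpkm > threshold else "not expressed"


def summarize_fpkm(
    fpkm: pd.DataFrame,
    excluded_replicates: Sequence[str] = (),
    how: str = "mean",
) -> pd.Series:
    """Per-gene summary FPKM over retained replicate columns."""
    keep = [c for c in fpkm.columns if c not in set(excluded_replicates)]
    if not keep:
        raise ValueError("all replicates excluded")
    sub = fpkm[keep]
    if how == "mean":
        return sub.mean(axis=1)
    if how == "median":
        return sub.median(axis=1)
    raise ValueError(f"unknown summary {how!r}")


def replicate_qc(
    expression_matrix: pd.DataFrame,
    groups: Mapping[str, Sequence[str]] | None = None,
    correlation_floor: float = 0.8,
    n_components: int = 2,
) -> dict:
    """Pairwise Pearson correlation, PCA coordinates and outlier flags.

    Correlations and the PCA run on log2(FPKM + 1).  A replicate is
    flagged when its *best* Pearson correlation with any other member
    of its group falls below ``correlation_floor`` (with three
    replicates and one outlier, a median-based rule would also drag
    down the two good members; the max isolates the outlier).  Flagged
    replicates are only reported — exclusion is a configuration
    decision.
    """
    if expression_matrix.shape[1] < 2:
        warnings.warn("fewer than 2 replicates: replicate QC skipped")
        return {"correlation": None, "pca": None, "flagged": []}
    logx = np.log2(expression_matrix + 1.0)
    corr = logx.corr(method="pearson")
    n_comp = min(n_components, logx.shape[1], logx.shape[0])
    coords = PCA(n_components=n_comp, random_state=0).fit_transform(logx.T.to_numpy())
    pca = pd.DataFrame(
        coords,
        index=logx.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    if groups is None:
        groups = {"all": list(expression_matrix.columns)}
    flagged = []
    for _name, members in groups.items():
        for rep in members:
            others = [m for m in members if m != rep]
            if not others:
                continue
            if float(corr.loc[rep, others].max()) < correlation_floor:
                flagged.append(rep)
    return {"correlation": corr, "pca": pca, "flagged": flagged}


def deg_accounting(deg_table: pd.DataFrame, alpha: float = 0.05) -> dict[str, int]:
    """Counts of significant DEGs: total, upregulated, downregulated.

    Expects columns ``log2fc`` (adult vs embryo) and ``padj``.  A gene
    is significant at ``padj < alpha``; "down" means higher in embryo
    (negative log2fc).
    """
    required = {"log2fc", "padj"}
    if not required.issubset(deg_table.columns):
        raise ValueError(f"DEG table needs columns {sorted(required)}")
    sig = deg_table[deg_table["padj"] < alpha]
    up = int((sig["log2fc"] > 0).sum())
    down = int((sig["log2fc"] < 0).sum())
    return {"total": up + down, "up": up, "down": down}
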