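"""Four-way gene classification and methylation-expression integration.

Genes are crossed into four mutually exclusive categories per stage:
``not methylated/expressed``, ``methylated/expressed``,
``not methylated/not expressed`` and ``methylated/not expressed``
(methylated at mean gene-body level >= 10%, expressed at FPKM > 1).
Stage transitions, per-category summaries, the methylation-expression
regression on methylated/expressed genes, hypergeometric DMR x DEG
overlap tests and the methylation-change-vs-level profile live here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeAnnotation

__all__ = [
    "CATEGORIES",
    "TransitionSummary",
    "build_gene_status_table",
    "category_stats",
    "classify_four_sets",
    "dmr_deg_overlap",
    "gbm_expression_regression",
    "hypergeom_overlap_p",
    "methylation_change_profile",
    "transition_counts",
]

CATEGORIES = (
    "not methylated/expressed",
    "methylated/expressed",
    "not methylated/not expressed",
    "methylated/not expressed",
)


def classify_four_sets(meth_status: str, expr_status: str) -> str:
    """Cross a methylation status with an expression status."""
    if meth_status not in ("methylated", "not methylated"):
        raise ValueError(f"bad methylation status {meth_status!r}")
    if expr_status not in ("expressed", "not expressed"):
        raise ValueError(f"bad expression status {expr_status!r}")
    return f"{meth_status}/{expr_status}"


def build_gene_status_table(
    mean_level: Mapping[str, float],
    summary_fpkm: Mapping[str, float],
    consolidated: Sequence[str],
    meth_threshold: float = 10.0,
    fpkm_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-gene status table for one stage, restricted to the
    consolidated gene set."""
    genes = sorted(consolidated)
    level = pd.Series(mean_level).reindex(genes)
    fpkm = pd.Series(summary_fpkm).reindex(genes)
    if level.isna().any() or fpkm.isna().any():
        bad = [g for g in genes if pd.isna(level[g]) or pd.isna(fpkm[g])]
        raise ValueError(f"missing level/FPKM for consolidated genes, e.g. {bad[:5]}")
    meth = np.where(level < meth_threshold, "not methylated", "methylated")
    expr = np.where(fpkm > fpkm_threshold, "expressed", "not expressed")
    return pd.DataFrame(
        {
            "mean_level": level,
            "summary_fpkm": fpkm,
            "meth_status": meth,
            "expr_status": expr,
            "category": [f"{m}/{e}" for m, e in zip(meth, expr)],
        },
        index=pd.Index(genes, name="gene_id"),
    )


@dataclass
class TransitionSummary:
    """Embryo-to-adult category flows and their marginals."""

    flows: pd.DataFrame  # 4x4, index=embryo category, columns=adult category
    n_genes: int
    become_active: int
    become_inactive: int
    gain_methylation: int
    lose_methylation: int
    maintain_methylation: int
    embryo_expressed: int
    adult_expressed: int

    @property
    def expression_changers(self) -> int:
        return self.become_active + self.become_inactive

    def percentages(self) -> dict[str, float]:
        n = self.n_genes
        return {
            "embryo_expressed_pct": 100.0 * self.embryo_expressed / n,
            "adult_expressed_pct": 100.0 * self.adult_expressed / n,
            "gain_methylation_pct": 100.0 * self.gain_methylation / n,
            "lose_methylation_pct": 100.0 * self.lose_methylation / n,
            "maintain_methylation_pct": 100.0 * self.maintain_methylation / n,
        }

    def long_flows(self) -> pd.DataFrame:
        """source,target,count rows for Sankey-style plotting."""
        rows = [
            {"source": src, "target": tgt, "count": int(self.flows.loc[src, tgt])}
            for src in self.flows.index
            for tgt in self.flows.columns
        ]
        return pd.DataFrame(rows)


def transition_counts(
    status_embryo: pd.DataFrame, status_adult: pd.DataFrame
) -> TransitionSummary:
    """All 16 category flows between stages plus marginal counts.

    Both tables must cover the same (consolidated) gene set; genes
    present in only one stage are excluded and reported via the
    ``dropped`` attribute on the flows table.
    """
    common = status_embryo.index.intersection(status_adult.index)
    dropped = len(status_embryo.index.union(status_adult.index)) - len(common)
    e = status_embryo.loc[common]
    a = status_adult.loc[common]
    flows = pd.crosstab(
        pd.Categorical(e["category"], categories=CATEGORIES),
        pd.Categorical(a["category"], categories=CATEGORIES),
        dropna=False,
    )
    flows.index = pd.Index(CATEGORIES, name="embryo")
    flows.columns = pd.Index(CATEGORIES, name="adult")
    flows.attrs["dropped"] = dropped

    e_expr = e["expr_status"] == "expressed"
    a_expr = a["expr_status"] == "expressed"
    e_meth = e["meth_status"] == "methylated"
    a_meth = a["meth_status"] == "methylated"
    return TransitionSummary(
        flows=flows,
        n_genes=len(common),
        become_active=int((~e_expr & a_expr).sum()),
        become_inactive=int((e_expr & ~a_expr).sum()),
        gain_methylation=int((~e_meth & a_meth).sum()),
        lose_methylation=int((e_meth & ~a_meth).sum()),
        maintain_methylation=int((e_meth == a_meth).sum()),
        embryo_expressed=int(e_expr.sum()),
        adult_expressed=int(a_expr.sum()),
    )


def category_stats(
    statuses: pd.DataFrame, annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Gene count and mean/SD gene length (bp) per category."""
    lengths = pd.Series(annotation.gene_lengths())
    rows = []
    for cat in CATEGORIES:
        genes = statuses.index[statuses["category"] == cat]
        ls = lengths.reindex(genes).dropna()
        rows.append(
            {
                "category": cat,
                "n_genes": len(genes),
                "mean_length": float(ls.mean()) if len(ls) else np.nan,
                "sd_length": float(ls.std(ddof=1)) if len(ls) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def gbm_expression_regression(
    status_table: pd.DataFrame, log_base: float = 10.0
) -> dict[str, float]:
    """OLS of log FPKM on mean methylation over methylated/expressed genes.

    Genes outside the methylated/expressed category are ignored; zero
    FPKM or zero methylation values are removed before the log
    transform of expression.
    """
    sub = status_table[status_table["category"] == "methylated/expressed"]
    sub = sub[(sub["summary_fpkm"] > 0) & (sub["mean_level"] > 0)]
    if len(sub) < 3:
        raise ValueError("too few methylated/expressed genes for regression")
    x = sub["mean_level"].to_numpy()
    y = np.log(sub["summary_fpkm"].to_numpy()) / np.log(log_base)
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "p": float(fit.pvalue),
        "n": int(len(sub)),
    }


def hypergeom_overlap_p(n_universe: int, n_a: int, n_b: int, n_overlap: int) -> float:
    """Upper-tail hypergeometric P(overlap >= observed).

    Probability that two sets of sizes ``n_a`` and ``n_b`` drawn from a
    universe of ``n_universe`` genes share at least ``n_overlap``
    members.
    """
    if not (0 <= n_a <= n_universe and 0 <= n_b <= n_universe):
        raise ValueError("set sizes exceed universe")
    if n_overlap < 0:
        raise ValueError("negative overlap")
    if n_overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_a, n_b))


def dmr_deg_overlap(
    dmr_gene_sets: Mapping[str, set[str]],
    deg_gene_sets: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Enrichment p for every DMR-direction x DEG-direction pair.

    Typically ``{"hypo": ..., "hyper": ...}`` against ``{"up": ...,
    "down": ...}`` over the consolidated gene universe.  One-sided
    (enrichment); depletion shows as p near 1 and is reported
    descriptively via the expected overlap.
    """
    rows = []
    n_u = len(universe)
    for da, set_a in dmr_gene_sets.items():
        a = set_a & universe
        for db, set_b in deg_gene_sets.items():
            b = set_b & universe
            k = len(a & b)
            expected = len(a) * len(b) / n_u if n_u else float("nan")
            rows.append(
                {
                    "dmr_direction": da,
                    "deg_direction": db,
                    "n_dmr_genes": len(a),
                    "n_deg_genes": len(b),
                    "n_overlap": k,
                    "expected_overlap": expected,
                    "p": hypergeom_overlap_p(n_u, len(a), len(b), k),
                }
            )
    return pd.DataFrame(rows)


def methylation_change_profile(
    embryo_levels: Mapping[str, float],
    adult_levels: Mapping[str, float],
    n_bins: int = 10,
) -> pd.DataFrame:
    """Mean adult-minus-embryo change binned by embryo level.

    Genes are placed into ``n_bins`` equal-width bins over [0, 100] by
    embryo methylation level (the right edge closes the last bin).
    """
    e = pd.Series(embryo_levels)
    a = pd.Series(adult_levels).reindex(e.index)
    if a.isna().any():
        raise ValueError("adult levels missing for some genes")
    delta = a - e
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    which = np.clip(np.digitize(e.to_numpy(), edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n_genes": int(sel.sum()),
                "mean_delta": float(delta.to_numpy()[sel].mean()) if sel.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)
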