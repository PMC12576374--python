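"""GO term enrichment by classic one-sided Fisher's exact test.

For every term annotated to at least one subset gene, a 2x2 table
(in/out of subset x with/without term) is tested for enrichment;
p-values are Benjamini-Hochberg corrected across the tested terms.
The *gene ratio* of a term is the percentage of all universe genes
carrying the term that fall inside the subset.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = ["go_fisher", "read_gene2go", "top_terms", "write_gene2go"]


def read_gene2go(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (gene, term) to gene -> term-set mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    mapping: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        mapping.setdefault(gene, set()).add(term)
    return mapping


def write_gene2go(gene2go: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(gene2go):
            for term in sorted(gene2go[gene]):
                fh.write(f"{gene}\t{term}\n")


def go_fisher(
    subset: set[str],
    universe: set[str],
    gene2go: Mapping[str, set[str]],
    ancestors: Mapping[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Per-term enrichment of ``subset`` within ``universe``.

    ``gene2go`` holds direct annotations; passing ``ancestors``
    (term -> ancestor-term set) propagates annotations up the ontology
    before testing.  Terms with no subset gene are not tested.
    """
    if not subset <= universe:
        raise ValueError("subset is not contained in universe")

    def terms_of(gene: str) -> set[str]:
        direct = gene2go.get(gene, set())
        if ancestors is None:
            return direct
        full = set(direct)
        for t in direct:
            full |= ancestors.get(t, set())
        return full

    term_universe: dict[str, int] = {}
    term_subset: dict[str, int] = {}
    for gene in universe:
        for term in terms_of(gene):
            term_universe[term] = term_universe.get(term, 0) + 1
            if gene in subset:
                term_subset[term] = term_subset.get(term, 0) + 1

    n_u, n_s = len(universe), len(subset)
    rows = []
    for term in sorted(term_subset):
        k = term_subset[term]
        m = term_universe[term]
        table = [[k, n_s - k], [m - k, (n_u - n_s) - (m - k)]]
        p = float(fisher_exact(table, alternative="greater")[1])
        rows.append(
            {
                "term": term,
                "n_subset": k,
                "n_universe": m,
                "gene_ratio": 100.0 * k / m,
                "p_fisher": p,
            }
        )
    df = pd.DataFrame(
        rows, columns=["term", "n_subset", "n_universe", "gene_ratio", "p_fisher"]
    )
    if len(df):
        df["q_bh"] = multipletests(df["p_fisher"], method="fdr_bh")[1]
    else:
        df["q_bh"] = pd.Series(dtype=float)
    return df


def top_terms(results: pd.DataFrame, n: int = 40) -> pd.DataFrame:
    """The ``n`` most significant terms, ties broken by term id."""
    return (
        results.sort_values(["q_bh", "p_fisher", "term"], kind="mergesort")
        .head(n)
        .reset_index(drop=True)
    )
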