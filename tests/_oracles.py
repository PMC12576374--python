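"""Independent brute-force oracles used by the test suite.

These deliberately avoid scipy/statsmodels so they can cross-check the
library-backed implementations.
"""

from itertools import combinations
from math import comb


def hypergeom_tail_enum(n_universe: int, n_a: int, n_b: int, k: int) -> float:
    """P(|A & B| >= k) by exhaustive enumeration of all draws of B.

    A is fixed as the first ``n_a`` universe elements; every size-
    ``n_b`` subset of the universe is enumerated.  Feasible for
    universes up to ~15.
    """
    universe = list(range(n_universe))
    a = set(universe[:n_a])
    hits = total = 0
    for b in combinations(universe, n_b):
        total += 1
        if len(a.intersection(b)) >= k:
            hits += 1
    return hits / total


def fisher_greater_enum(n_universe: int, n_term: int, n_subset: int, k: int) -> float:
    """One-sided (enrichment) Fisher p by hypergeometric closed form.

    P(X >= k) where X counts term genes in a random size-``n_subset``
    draw; written out from binomial coefficients, no scipy.
    """
    total = comb(n_universe, n_subset)
    acc = 0
    for j in range(k, min(n_term, n_subset) + 1):
        acc += comb(n_term, j) * comb(n_universe - n_term, n_subset - j)
    return acc / total


def bh_brute(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the textbook formula."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        value = min(pvals[i] * m / rank_from_end, running_min)
        running_min = value
        adjusted[i] = value
    return adjusted


def best_split_enum(diffs: list[float], min_cpgs: int):
    """Exhaustive search for the split maximizing |mean(L) - mean(R)|."""
    n = len(diffs)
    best = None
    for k in range(min_cpgs, n - min_cpgs + 1):
        left = sum(diffs[:k]) / k
        right = sum(diffs[k:]) / (n - k)
        crit = abs(left - right)
        if best is None or crit > best[1]:
            best = (k, crit)
    return best


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    inter = max(0, hi - lo)
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0
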