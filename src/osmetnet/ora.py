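"""Hypergeometric over-representation analysis of gene lists against GMT sets.

A query list (e.g. up- or down-regulated DEGs) is tested against every set
in a collection: with N universe genes, K of them in the set and n in the
query, the overlap k is referred to the upper tail of the hypergeometric
distribution. Sets pass with raw p < alpha and overlap count >= min_count;
BH-adjusted q-values are reported over all tested sets but not filtered on.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh

__all__ = ["hypergeom_upper_tail", "enrich"]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space.

    k: observed overlap, K: set size, n: query size, N: universe size.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates the tail stably
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query_genes: Iterable[str],
    collection: Mapping[str, set[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
    min_count: int = 1,
) -> pd.DataFrame:
    """Over-representation of ``query_genes`` in each set of ``collection``.

    Query and sets are intersected with the universe first. One row per set
    passing the raw-p and count filters, sorted by p; q is BH over all sets
    with non-empty universe intersection.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query_genes) & universe
    if not query:
        warnings.warn("query is empty after intersection with the universe")
    N, n = len(universe), len(query)

    rows = []
    for name, members in collection.items():
        members_u = members & universe
        if not members_u:
            continue
        overlap = sorted(members_u & query)
        k, K = len(overlap), len(members_u)
        rows.append(
            {
                "set": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_upper_tail(k, K, n, N),
                "overlap": ",".join(overlap),
            }
        )
    result = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p", "overlap"])
    if result.empty:
        result["q"] = pd.Series(dtype=float)
        return result
    result["q"] = adjust_bh(result["p"].to_numpy())
    kept = result[(result["p"] < alpha) & (result["k"] >= min_count)]
    return kept.sort_values("p").reset_index(drop=True)[
        ["set", "k", "K", "n", "N", "p", "q", "overlap"]
    ]
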