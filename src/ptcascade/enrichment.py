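"""Over-representation analysis of cascade gene sets.

Two modes are provided.  Pattern-level enrichment tests all genes of a
temporal pattern against a gene-set collection with the hypergeometric
upper tail.  Temporal enrichment slides a window along the cascade
ordering within one pattern (default: each window holds 20% of the
genes and advances by 10%) and tests each window separately,
localizing functional programs to early, mid or late pseudotime.

Conventions: the universe is the set of filtered genes carrying at
least one annotation; GeneRatio is Count divided by the number of
universe genes annotated to the term (``count / K``; the more common
``count / n`` query-size convention is available via ``ratio='query'``);
BH correction is applied within each test family (per window in
temporal mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection
from .fit import adjust_bh

logger = logging.getLogger(__name__)

__all__ = [
    "SlidingWindowPartition",
    "make_windows",
    "hypergeom_upper_tail",
    "pattern_enrichment",
    "temporal_enrichment",
]


@dataclass
class SlidingWindowPartition:
    """Half-open index windows over a ranked gene list."""

    n: int
    bin_frac: float
    step_frac: float
    windows: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.windows)


def make_windows(n: int, bin: float = 0.20, step: float = 0.10) -> SlidingWindowPartition:
    """Partition ``n`` ranked genes into overlapping windows.

    Window size is ``round(bin * n)`` and the shift ``round(step * n)``
    (nearest integer, floor 1); windows start at 0, s, 2s, ... while the
    start lies inside the list, and the last window may be truncated.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 < step <= bin <= 1):
        raise ValueError("need 0 < step <= bin <= 1")
    b = max(1, round(bin * n))
    s = max(1, round(step * n))
    windows = [(start, min(start + b, n)) for start in range(0, n, s)]
    return SlidingWindowPartition(n, bin, step, windows)


def hypergeom_upper_tail(k: int, n: int, K: int, M: int) -> float:
    """P(X >= k) for X hypergeometric: population M, K successes, n draws."""
    if not (0 <= k <= min(n, K) and K <= M and n <= M):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, M={M}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def _enrich_frame(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str],
    min_term_size: int,
) -> pd.DataFrame:
    M = len(universe)
    n = len(query)
    rows = []
    for term in collection:
        members = collection[term] & universe
        K = len(members)
        if K < min_term_size:
            continue
        count = len(query & members)
        rows.append(
            {
                "term_id": term,
                "name": collection.names[term],
                "Count": count,
                "K": K,
                "n": n,
                "M": M,
                "pvalue": hypergeom_upper_tail(count, n, K, M),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["qvalue"] = adjust_bh(df["pvalue"].to_numpy())
    return df


def pattern_enrichment(
    genes,
    collection: GeneSetCollection,
    universe,
    min_term_size: int = 10,
    ratio: str = "term",
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list against every
    sufficiently large term, BH-corrected across terms.

    Returns one row per tested term with Count, K (term size in the
    universe), n (query size), M (universe size), GeneRatio, p and q,
    sorted by GeneRatio descending.
    """
    universe = set(universe)
    query = set(genes)
    dropped = query - universe
    if dropped:
        logger.warning("pattern_enrichment: %d query genes outside the universe dropped", len(dropped))
    query &= universe
    if not query:
        raise ValueError("empty query after intersecting with the universe")
    df = _enrich_frame(query, collection, universe, min_term_size)
    if df.empty:
        return df
    denom = df["K"] if ratio == "term" else df["n"]
    df["GeneRatio"] = df["Count"] / denom
    return df.sort_values(
        ["GeneRatio", "pvalue", "term_id"], ascending=[False, True, True]
    ).reset_index(drop=True)


def temporal_enrichment(
    ranked_genes,
    collection: GeneSetCollection,
    universe,
    bin: float = 0.20,
    step: float = 0.10,
    q_cut: float = 0.05,
    top: int = 5,
    min_term_size: int = 10,
    ratio: str = "term",
) -> tuple[pd.DataFrame, list[str]]:
    """Sliding-window enrichment along a ranked (cascade-ordered) list.

    Returns the full per-window table (with a ``window`` column,
    1-based) and the reported term set: the union over windows of each
    window's top ``top`` terms by GeneRatio, filtered to ``q < q_cut``.
    """
    ranked_genes = list(ranked_genes)
    universe = set(universe)
    part = make_windows(len(ranked_genes), bin, step)
    tables = []
    for w, (start, end) in enumerate(part.windows, 1):
        window_genes = [g for g in ranked_genes[start:end] if g in universe]
        if not window_genes:
            logger.warning("window %d has no annotated genes; skipped", w)
            continue
        df = pattern_enrichment(
            window_genes, collection, universe, min_term_size=min_term_size, ratio=ratio
        )
        if df.empty:
            continue
        df.insert(0, "window", w)
        tables.append(df)
    if not tables:
        return pd.DataFrame(), []
    full = pd.concat(tables, ignore_index=True)
    reported: set[str] = set()
    for w, df in full.groupby("window"):
        top_terms = df.nlargest(top, "GeneRatio", keep="first")
        reported |= set(top_terms.loc[top_terms["qvalue"] < q_cut, "term_id"])
    return full, sorted(reported)
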