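"""Temporal-pattern classification and pattern-aware cascade ordering.

Each significant gene's switch directions are concatenated into a
pattern string over {I, D} ("I", "D", "ID", "DI", ...).  Genes are
grouped by pattern, blocks are arranged by increasing complexity
(monotonic patterns before nonmonotonic ones), and genes within a block
are sorted by the position of their first switch point — producing the
"staircase" cascade visible in the heatmap.  Two clustering baselines
(Ward hierarchical clustering and k-means) are provided for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .fit import ScaledTrajectory
from .switchpoints import SwitchPointSet

__all__ = [
    "PatternAssignment",
    "CascadeOrdering",
    "classify_pattern",
    "order_genes",
    "select_top_genes",
    "baseline_order_hclust",
    "baseline_order_kmeans",
]


@dataclass
class PatternAssignment:
    """A gene's temporal pattern and the location of its first switch."""

    gene_id: str
    pattern: str
    first_switch_index: int
    first_switch_pseudotime: float
    padj: float

    @property
    def pattern_class(self) -> str:
        if self.pattern == "I":
            return "monotonic-increasing"
        if self.pattern == "D":
            return "monotonic-decreasing"
        return "nonmonotonic"


@dataclass
class CascadeOrdering:
    """Genes in cascade order with per-pattern block boundaries."""

    genes: list[str]
    assignments: dict[str, PatternAssignment]
    blocks: dict[str, tuple[int, int]]  # pattern -> half-open [start, end)

    def __len__(self) -> int:
        return len(self.genes)

    def rank(self, gene_id: str) -> int:
        return self.genes.index(gene_id)

    def block_genes(self, pattern: str) -> list[str]:
        start, end = self.blocks[pattern]
        return self.genes[start:end]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, g in enumerate(self.genes, 1):
            a = self.assignments[g]
            rows.append(
                {
                    "rank": rank,
                    "gene_id": g,
                    "pattern": a.pattern,
                    "class": a.pattern_class,
                    "first_switch_index": a.first_switch_index,
                    "first_switch_pseudotime": a.first_switch_pseudotime,
                    "padj": a.padj,
                }
            )
        return pd.DataFrame(rows)


def classify_pattern(
    sw: SwitchPointSet, x: ScaledTrajectory, padj: float, gamma: float = 0.0
) -> PatternAssignment:
    """Assign a temporal pattern from a gene's switch points.

    A trajectory with no detected crossing (possible under the
    threshold criterion when gamma lies outside the trajectory's range)
    falls back to the overall trend: "I" if the trajectory ends higher
    than it starts, "D" otherwise, with the first switch placed at the
    grid point closest to the threshold level.
    """
    if len(sw) > 0:
        return PatternAssignment(
            sw.gene_id,
            sw.pattern,
            sw.positions[0],
            sw.pseudotimes[0],
            padj,
        )
    v = np.asarray(x.x, dtype=float)
    if v[-1] == v[0]:
        raise ValueError(f"constant trajectory for gene {sw.gene_id!r}")
    pattern = "I" if v[-1] > v[0] else "D"
    idx = int(np.argmin(np.abs(v - gamma))) + 1
    return PatternAssignment(sw.gene_id, pattern, idx, float(x.grid[idx - 1]), padj)


def _pattern_key(pattern: str) -> tuple[int, tuple[int, ...]]:
    # complexity first, then lexicographic with I < D
    return len(pattern), tuple(0 if ch == "I" else 1 for ch in pattern)


def order_genes(assignments: dict[str, PatternAssignment]) -> CascadeOrdering:
    """Arrange genes into the cascade order.

    Blocks sorted by (pattern length, pattern with I before D); within
    a block genes sorted by (first switch index, padj, gene id).
    """
    if not assignments:
        raise ValueError("no pattern assignments to order")
    patterns = sorted({a.pattern for a in assignments.values()}, key=_pattern_key)
    genes: list[str] = []
    blocks: dict[str, tuple[int, int]] = {}
    for pat in patterns:
        members = [a for a in assignments.values() if a.pattern == pat]
        members.sort(key=lambda a: (a.first_switch_index, a.padj, a.gene_id))
        start = len(genes)
        genes.extend(a.gene_id for a in members)
        blocks[pat] = (start, len(genes))
    return CascadeOrdering(genes, dict(assignments), blocks)


def select_top_genes(co: CascadeOrdering, k: int = 1000) -> CascadeOrdering:
    """Keep the ``k`` smallest-padj genes (ties by gene id), re-emitted
    in cascade order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(co) <= k:
        return co
    by_padj = sorted(co.genes, key=lambda g: (co.assignments[g].padj, g))
    kept = set(by_padj[:k])
    genes = [g for g in co.genes if g in kept]
    assignments = {g: co.assignments[g] for g in genes}
    blocks: dict[str, tuple[int, int]] = {}
    pos = 0
    for pat, (start, end) in co.blocks.items():
        n = sum(1 for g in co.genes[start:end] if g in kept)
        if n:
            blocks[pat] = (pos, pos + n)
            pos += n
    return CascadeOrdering(genes, assignments, blocks)


def baseline_order_hclust(x: pd.DataFrame) -> list[str]:
    """Comparison baseline: Ward-linkage hierarchical clustering on
    Euclidean gene-gene distances; returns the dendrogram leaf order.

    ``x`` is a genes-by-grid DataFrame of scaled fitted values.
    """
    if len(x) < 2:
        raise ValueError("hierarchical clustering needs at least 2 genes")
    Z = linkage(pdist(x.to_numpy(dtype=float), metric="euclidean"), method="ward")
    return [x.index[i] for i in leaves_list(Z)]


def baseline_order_kmeans(
    x: pd.DataFrame,
    padj: dict[str, float],
    k: int = 4,
    n_init: int = 50,
    seed: int | None = 0,
) -> list[str]:
    """Comparison baseline: k-means on scaled fitted values.

    Best-inertia solution over ``n_init`` restarts; clusters emitted in
    increasing cluster-id order, genes within a cluster by ascending
    adjusted p-value.
    """
    if len(x) < k:
        raise ValueError(f"k-means with k={k} needs at least {k} genes")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(x.to_numpy(dtype=float))
    out: list[str] = []
    for cid in range(k):
        members = [g for g, lab in zip(x.index, labels) if lab == cid]
        members.sort(key=lambda g: (padj.get(g, np.inf), g))
        out.extend(members)
    return out
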