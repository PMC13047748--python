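"""Readers, writers and input conventions for expression matrices,
cell orderings and gene-set collections.

The pipeline consumes a genes-by-cells matrix of normalized expression
(or pathway-activity scores), a per-sample cell ordering or pseudotime
vector, an optional cell-to-sample map, and gene sets in GMT format.
Filtering and column alignment happen here, before any model fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PseudotimeOrdering",
    "GeneSetCollection",
    "read_expression",
    "read_pseudotime",
    "read_sample_map",
    "read_gmt",
    "filter_genes",
    "align_cells",
]


@dataclass
class ExpressionMatrix:
    """Genes-by-cells numeric matrix with identity attached.

    ``values`` holds normalized expression or pathway-activity scores
    (non-negative for expression; scores may be negative).
    ``sample_labels`` maps each cell to a sample in multi-sample mode.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    sample_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.cell_ids, "cell id")
        if self.sample_labels is not None:
            self.sample_labels = [str(s) for s in self.sample_labels]
            if len(self.sample_labels) != len(self.cell_ids):
                raise ValueError("one sample label per cell required")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {c: k for k, c in enumerate(self.cell_ids)}
        cols = [idx[c] for c in cell_ids]
        labels = None
        if self.sample_labels is not None:
            labels = [self.sample_labels[k] for k in cols]
        return ExpressionMatrix(
            self.values[:, cols], list(self.gene_ids), [self.cell_ids[k] for k in cols], labels
        )


@dataclass
class PseudotimeOrdering:
    """Cells in trajectory order with their pseudotime values.

    When no explicit pseudotime is supplied the i-th ordered cell is
    assigned pseudotime i (1-based rank).
    """

    cell_ids: list[str]
    pseudotime: np.ndarray | None = None
    sample: str | None = None

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        _check_unique(self.cell_ids, "ordering cell id")
        if self.pseudotime is None:
            self.pseudotime = np.arange(1, len(self.cell_ids) + 1, dtype=float)
        else:
            self.pseudotime = np.asarray(self.pseudotime, dtype=float)
            if self.pseudotime.shape != (len(self.cell_ids),):
                raise ValueError("pseudotime length must match cell count")
            if np.any(np.diff(self.pseudotime) < 0):
                # store cells sorted by pseudotime so t is non-decreasing
                order = np.argsort(self.pseudotime, kind="stable")
                self.cell_ids = [self.cell_ids[k] for k in order]
                self.pseudotime = self.pseudotime[order]

    def __len__(self) -> int:
        return len(self.cell_ids)


@dataclass
class GeneSetCollection:
    """Mapping of term id -> member gene set, with display names."""

    sets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {term!r} is empty")
            self.sets[term] = frozenset(str(g) for g in members)
        for term in self.sets:
            self.names.setdefault(term, term)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, term: str) -> frozenset[str]:
        return self.sets[term]

    def restrict(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``, dropping emptied terms."""
        kept = {t: s & universe for t, s in self.sets.items()}
        kept = {t: s for t, s in kept.items() if s}
        return GeneSetCollection(dict(kept), {t: self.names[t] for t in kept})


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what}: {i!r}")
        seen.add(i)


def read_expression(path: str | Path, format: str = "dense") -> ExpressionMatrix:
    """Read a genes-by-cells matrix.

    ``format='dense'``: delimited text (TSV or CSV sniffed from the
    extension), genes as rows, header row of cell ids, first column of
    gene ids.  ``format='sparse'``: MatrixMarket coordinate file with
    sidecar ``genes.txt`` / ``cells.txt`` (one id per line) next to it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dense":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"non-numeric entry in {path}: {exc}") from exc
        return ExpressionMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)))
    if format == "sparse":
        genes_file = path.parent / "genes.txt"
        cells_file = path.parent / "cells.txt"
        for sidecar in (genes_file, cells_file):
            if not sidecar.exists():
                raise FileNotFoundError(f"sidecar name file missing: {sidecar}")
        mat = scipy.io.mmread(path)
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        gene_ids = genes_file.read_text().split()
        cell_ids = cells_file.read_text().split()
        if dense.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"matrix dimensions {dense.shape} do not match name files "
                f"({len(gene_ids)} genes, {len(cell_ids)} cells)"
            )
        return ExpressionMatrix(dense, gene_ids, cell_ids)
    raise ValueError(f"unknown format {format!r}; use 'dense' or 'sparse'")


def read_pseudotime(path: str | Path, sample: str | None = None) -> PseudotimeOrdering:
    """Read a cell ordering: 1 column (ordered ids) or 2 columns (id, t)."""
    path = Path(path)
    rows = [line.split("\t") for line in path.read_text().splitlines() if line.strip()]
    if not rows:
        raise ValueError(f"empty ordering file: {path}")
    ncol = len(rows[0])
    if ncol == 1:
        return PseudotimeOrdering([r[0] for r in rows], None, sample)
    cells = [r[0] for r in rows]
    t = np.array([float(r[1]) for r in rows])
    return PseudotimeOrdering(cells, t, sample)


def read_sample_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column (cell_id, sample) TSV into a dict."""
    path = Path(path)
    out: dict[str, str] = {}
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected 'cell_id<TAB>sample'")
        out[parts[0]] = parts[1]
    return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term TAB description TAB gene1 TAB gene2 ..."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs term, description and >=1 gene")
        term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if term in sets:
            raise ValueError(f"{path}:{ln}: duplicate term {term!r}")
        sets[term] = frozenset(genes)
        names[term] = desc if desc else term
    if not sets:
        raise ValueError(f"no gene sets in {path}")
    return GeneSetCollection(sets, names)


def filter_genes(
    m: ExpressionMatrix, min_expr: float = 0.1, min_frac: float = 0.05
) -> ExpressionMatrix:
    """Retain genes expressed above ``min_expr`` in more than ``min_frac``
    of cells (both inequalities strict).  Gene order is preserved."""
    if min_expr < 0:
        raise ValueError("min_expr must be >= 0")
    if not 0 <= min_frac < 1:
        raise ValueError("min_frac must be in [0, 1)")
    frac = (m.values > min_expr).mean(axis=1)
    keep = frac > min_frac
    if not keep.any():
        raise ValueError(
            "all genes removed by expression filter; relax min_expr/min_frac"
        )
    kept_ids = [g for g, k in zip(m.gene_ids, keep) if k]
    logger.info("filter_genes: retained %d / %d genes", len(kept_ids), m.n_genes)
    return ExpressionMatrix(m.values[keep], kept_ids, list(m.cell_ids), m.sample_labels)


def align_cells(m: ExpressionMatrix, ordering: PseudotimeOrdering) -> ExpressionMatrix:
    """Permute matrix columns to the trajectory order.

    Cells present in the matrix but absent from the ordering are dropped
    (with a logged warning); an ordering cell missing from the matrix is
    an error.
    """
    have = set(m.cell_ids)
    missing = [c for c in ordering.cell_ids if c not in have]
    if missing:
        raise ValueError(f"ordering references unknown cell id(s): {missing[:5]}")
    n_dropped = m.n_cells - len(ordering)
    if n_dropped:
        logger.warning("align_cells: dropping %d cells absent from the ordering", n_dropped)
    return m.subset_cells(ordering.cell_ids)


def split_by_sample(
    m: ExpressionMatrix, orderings: Mapping[str, PseudotimeOrdering]
) -> dict[str, ExpressionMatrix]:
    """Split a labeled multi-sample matrix into per-sample aligned matrices."""
    if m.sample_labels is None:
        raise ValueError("matrix has no sample labels")
    out: dict[str, ExpressionMatrix] = {}
    for sample, ordering in orderings.items():
        cells = [c for c, s in zip(m.cell_ids, m.sample_labels) if s == sample]
        sub = m.subset_cells(cells)
        out[sample] = align_cells(sub, ordering)
    return out
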