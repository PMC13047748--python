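"""Cascade heatmap, enrichment dot plots and switch-point CI plots.

All plotting is deterministic given its inputs; every figure writes a
sidecar TSV with the plotted matrix or table so rendered content can
be checked programmatically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .fit import ScaledTrajectory
from .ordering import CascadeOrdering
from .switchpoints import SwitchPointSet

logger = logging.getLogger(__name__)

__all__ = ["PlotSpec", "plot_cascade_heatmap", "plot_enrichment_dot", "plot_switch_ci"]

FORMATS = ("png", "pdf", "svg")


@dataclass
class PlotSpec:
    """Output options shared by all plots."""

    path: str | Path
    width: float = 8.0
    height: float = 6.0
    markers: list[str] = field(default_factory=list)
    show_switch_points: bool = False
    color_limit: float = 2.0  # symmetric +/- limit for scaled expression

    def __post_init__(self) -> None:
        self.path = Path(self.path)
        fmt = self.path.suffix.lstrip(".").lower()
        if fmt not in FORMATS:
            raise ValueError(f"unsupported format {fmt!r}; use one of {FORMATS}")
        if self.color_limit <= 0:
            raise ValueError("color limit must be positive")
        self.format = fmt


def _save(fig, spec: PlotSpec) -> Path:
    spec.path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(spec.path, format=spec.format, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return spec.path


def plot_cascade_heatmap(
    co: CascadeOrdering,
    scaled: dict[str, ScaledTrajectory],
    spec: PlotSpec,
    switchpoints: dict[str, SwitchPointSet] | None = None,
) -> Path:
    """Heatmap of scaled fitted trajectories in cascade order.

    Rows are genes (first cascade gene on top), columns pseudotime.
    Only marker genes are labeled; switch points can be overlaid as
    dots.  Scaled values are clipped to the symmetric color limit so
    standardized excursions beyond it do not wash out the palette.
    """
    genes = [g for g in co.genes if g in scaled]
    missing = [g for g in co.genes if g not in scaled]
    if missing:
        logger.warning("%d ordered genes missing a trajectory; skipped", len(missing))
    if not genes:
        raise ValueError("no gene of the ordering has a scaled trajectory")
    grid = scaled[genes[0]].grid
    mat = np.vstack([scaled[g].x for g in genes])

    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    vmax = spec.color_limit
    ax.imshow(
        np.clip(mat, -vmax, vmax),
        aspect="auto",
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
        interpolation="nearest",
    )
    known = set(genes)
    for m in spec.markers:
        if m not in known:
            logger.warning("marker gene %s not in the plotted set; skipped", m)
    label_rows = [i for i, g in enumerate(genes) if g in set(spec.markers)]
    ax.set_yticks(label_rows)
    ax.set_yticklabels([genes[i] for i in label_rows], fontsize=7)
    ax.set_xlabel("pseudotime rank")
    ax.set_title("gene expression cascade")
    if spec.show_switch_points and switchpoints:
        xs, ys = [], []
        for i, g in enumerate(genes):
            sw = switchpoints.get(g)
            if sw is None:
                continue
            for p in sw.positions:
                xs.append(p - 0.5)  # crossing lies between grid columns p-1 and p (0-based)
                ys.append(i)
        ax.scatter(xs, ys, s=4, c="black", marker=".")
    out = _save(fig, spec)
    pd.DataFrame(mat, index=genes, columns=[f"{t:g}" for t in grid]).to_csv(
        out.with_suffix(out.suffix + ".tsv"), sep="\t"
    )
    return out


def plot_enrichment_dot(results: pd.DataFrame, spec: PlotSpec, top: int = 10) -> Path:
    """Dot plot of enrichment results.

    Pattern mode (no ``window`` column): top terms by GeneRatio on the
    x axis, dot size = Count, color = q-value.  Temporal mode: x =
    window index, y = term, same size/color encoding.
    """
    if results is None or len(results) == 0:
        raise ValueError("no enrichment results to plot")
    df = results.copy()
    temporal = "window" in df.columns
    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    if temporal:
        terms = list(dict.fromkeys(df["term_id"]))
        ypos = {t: i for i, t in enumerate(terms)}
        sc = ax.scatter(
            df["window"],
            [ypos[t] for t in df["term_id"]],
            s=10 + 8 * df["Count"],
            c=df["qvalue"],
            cmap="viridis_r",
            vmin=0,
            vmax=max(0.05, float(df["qvalue"].max())),
        )
        ax.set_yticks(range(len(terms)))
        ax.set_yticklabels(terms, fontsize=8)
        ax.set_xlabel("window along cascade")
    else:
        df = df.nlargest(min(top, len(df)), "GeneRatio", keep="first")
        df = df.iloc[::-1]  # largest on top
        sc = ax.scatter(
            df["GeneRatio"],
            range(len(df)),
            s=10 + 8 * df["Count"],
            c=df["qvalue"],
            cmap="viridis_r",
        )
        ax.set_yticks(range(len(df)))
        ax.set_yticklabels(df["term_id"], fontsize=8)
        ax.set_xlabel("GeneRatio")
    fig.colorbar(sc, ax=ax, label="q-value")
    out = _save(fig, spec)
    df.to_csv(out.with_suffix(out.suffix + ".tsv"), sep="\t", index=False)
    return out


def plot_switch_ci(ci_rows: pd.DataFrame, spec: PlotSpec) -> Path:
    """Per-gene switch-point intervals: point at the cross-sample mean,
    whiskers at mean +/- 2 SE, genes ordered by mean."""
    if ci_rows is None or len(ci_rows) == 0:
        raise ValueError("no confidence intervals to plot")
    df = ci_rows.sort_values("mean_pseudotime").reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    for i, row in df.iterrows():
        ax.plot([row["ci_lower"], row["ci_upper"]], [i, i], color="steelblue", lw=2)
        ax.plot(row["mean_pseudotime"], i, "o", color="black", ms=4)
        if row.get("n_samples", 2) <= 1:
            ax.annotate("n=1", (row["mean_pseudotime"], i), textcoords="offset points",
                        xytext=(4, 4), fontsize=7)
    ax.set_yticks(range(len(df)))
    ax.set_yticklabels(df["gene_id"], fontsize=8)
    ax.set_xlabel("switch pseudotime")
    out = _save(fig, spec)
    df.to_csv(out.with_suffix(out.suffix + ".tsv"), sep="\t", index=False)
    return out
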