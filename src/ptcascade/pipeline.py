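"""End-to-end orchestration: filter -> fit -> switch -> classify ->
order -> enrich -> plot, for single- or multi-sample inputs."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import io as pio
from . import multisample as ms
from .fit import ScaledTrajectory, TobitFit, fit_all_genes
from .ordering import classify_pattern, order_genes, select_top_genes
from .plots import PlotSpec, plot_cascade_heatmap, plot_enrichment_dot, plot_switch_ci
from .switchpoints import detect_switch_points

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (the defaults are the
    method's published defaults)."""

    matrix: str = ""
    pseudotime: list[str] = field(default_factory=list)
    sample_map: str | None = None
    gmt: str | None = None
    outdir: str = "ptcascade_out"
    matrix_format: str = "dense"
    method: str = "zero"
    gamma: float = 0.0
    alpha: float = 0.05
    min_conf: float = 0.75
    censor: float = 0.1
    spline_df: int = 2
    max_iter: int = 50
    min_expr: float = 0.1
    min_frac: float = 0.05
    bin: float = 0.2
    step: float = 0.1
    top_genes: int = 1000
    min_term_size: int = 10
    q_cut: float = 0.05
    top_terms_per_window: int = 5
    markers: list[str] = field(default_factory=list)
    show_switch_points: bool = True
    plot_format: str = "png"
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _write_fits(fits: dict[str, TobitFit], path: Path) -> None:
    rows = [
        {
            "gene_id": f.gene_id,
            "n_cells": f.n_cells,
            "converged": f.converged,
            "sigma": f.sigma,
            "loglik_full": f.loglik_full,
            "loglik_null": f.loglik_null,
            "pvalue": f.pvalue,
            "padj": f.padj,
        }
        for f in fits.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_scaled(scaled: dict[str, ScaledTrajectory], path: Path) -> None:
    if not scaled:
        return
    first = next(iter(scaled.values()))
    pd.DataFrame(
        {g: tr.x for g, tr in scaled.items()}, index=[f"{t:g}" for t in first.grid]
    ).T.to_csv(path, sep="\t")


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full cascade analysis; returns the output directory.

    Stage funnel counts (filtered, fitted, significant, retained,
    plotted) are logged so the selection at each step is auditable.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.verbosity)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logging.getLogger("ptcascade").addHandler(handler)
    cfg.to_yaml(outdir / "config_resolved.yaml")

    stage = "read"
    try:
        m = pio.read_expression(cfg.matrix, format=cfg.matrix_format)
        sample_map = pio.read_sample_map(cfg.sample_map) if cfg.sample_map else None
        multi = sample_map is not None
        orderings: dict[str, pio.PseudotimeOrdering] = {}
        if multi:
            m = pio.ExpressionMatrix(
                m.values, m.gene_ids, m.cell_ids, [sample_map[c] for c in m.cell_ids]
            )
            samples = sorted(set(m.sample_labels))
            if len(cfg.pseudotime) != len(samples):
                raise ValueError(
                    f"{len(samples)} samples but {len(cfg.pseudotime)} pseudotime files"
                )
            for sample, path in zip(samples, sorted(cfg.pseudotime)):
                orderings[sample] = pio.read_pseudotime(path, sample)
        else:
            if len(cfg.pseudotime) != 1:
                raise ValueError("single-sample mode expects exactly one pseudotime file")
            orderings["sample"] = pio.read_pseudotime(cfg.pseudotime[0])

        stage = "filter"
        m = pio.filter_genes(m, cfg.min_expr, cfg.min_frac)
        logger.info("funnel: %d genes after filtering", m.n_genes)

        stage = "fit"
        if multi:
            fits_by_sample, scaled_by_sample = ms.fit_per_sample(
                m, orderings, alpha=cfg.alpha, c=cfg.censor, df=cfg.spline_df, max_iter=cfg.max_iter
            )
            for s in fits_by_sample:
                _write_fits(fits_by_sample[s], outdir / f"fits_{s}.tsv")
            stage = "consensus"
            consensus = ms.consensus_analysis(
                fits_by_sample,
                scaled_by_sample,
                alpha=cfg.alpha,
                min_conf=cfg.min_conf,
                method=cfg.method,
                gamma=cfg.gamma,
            )
            ms.consensus_frame(consensus).to_csv(outdir / "consensus.tsv", sep="\t", index=False)
            ms.ci_frame(consensus).to_csv(outdir / "switchpoint_ci.tsv", sep="\t", index=False)
            retained = {g: c for g, c in consensus.items() if c.retained}
            logger.info("funnel: %d genes retained by consensus", len(retained))
            scaled = {g: c.mean_traj for g, c in retained.items()}
            switch = {g: c.switch_points for g, c in retained.items()}
            padj = {
                g: float(np.median([p for p in c.per_sample_padj.values()]))
                for g, c in retained.items()
            }
        else:
            aligned = pio.align_cells(m, orderings["sample"])
            fits, scaled = fit_all_genes(
                aligned,
                orderings["sample"],
                alpha=cfg.alpha,
                c=cfg.censor,
                df=cfg.spline_df,
                max_iter=cfg.max_iter,
            )
            _write_fits(fits, outdir / "fits.tsv")
            logger.info("funnel: %d fitted, %d significant", len(fits), len(scaled))
            stage = "switch"
            switch = {
                g: detect_switch_points(tr, method=cfg.method, gamma=cfg.gamma)
                for g, tr in scaled.items()
            }
            padj = {g: fits[g].padj for g in scaled}
        _write_scaled(scaled, outdir / "scaled_trajectories.tsv")

        stage = "switch"
        sw_rows = []
        for g, sw in switch.items():
            for k, (pos, pt, d) in enumerate(
                zip(sw.positions, sw.pseudotimes, sw.directions), 1
            ):
                sw_rows.append(
                    {
                        "gene_id": g,
                        "method": sw.method,
                        "gamma": sw.gamma if sw.gamma is not None else "",
                        "k": k,
                        "index": pos,
                        "pseudotime": pt,
                        "direction": d,
                    }
                )
        pd.DataFrame(sw_rows).to_csv(outdir / "switchpoints.tsv", sep="\t", index=False)

        stage = "order"
        assignments = {}
        for g, sw in switch.items():
            try:
                assignments[g] = classify_pattern(sw, scaled[g], padj[g], gamma=cfg.gamma)
            except ValueError as exc:
                logger.warning("gene %s unclassifiable: %s", g, exc)
        if not assignments:
            raise ValueError("no gene survived to the ordering stage")
        co = order_genes(assignments)
        plotted = select_top_genes(co, cfg.top_genes)
        co.to_frame().to_csv(outdir / "cascade_order.tsv", sep="\t", index=False)
        logger.info("funnel: %d ordered, %d plotted", len(co), len(plotted))

        stage = "enrich"
        if cfg.gmt:
            collection = pio.read_gmt(cfg.gmt)
            annotated = set().union(*(collection[t] for t in collection))
            universe = [g for g in m.gene_ids if g in annotated]
            pattern_tables = []
            temporal_tables = []
            for pattern in co.blocks:
                block = [g for g in co.block_genes(pattern) if g in annotated]
                if not block:
                    continue
                try:
                    tab = enr.pattern_enrichment(
                        block, collection, universe, min_term_size=cfg.min_term_size
                    )
                except ValueError as exc:
                    logger.warning("pattern %s enrichment skipped: %s", pattern, exc)
                    continue
                if not tab.empty:
                    tab.insert(0, "pattern", pattern)
                    pattern_tables.append(tab)
                full, reported = enr.temporal_enrichment(
                    co.block_genes(pattern),
                    collection,
                    universe,
                    bin=cfg.bin,
                    step=cfg.step,
                    q_cut=cfg.q_cut,
                    top=cfg.top_terms_per_window,
                    min_term_size=cfg.min_term_size,
                )
                if not full.empty:
                    full.insert(0, "pattern", pattern)
                    full["reported"] = full["term_id"].isin(reported)
                    temporal_tables.append(full)
            if pattern_tables:
                pd.concat(pattern_tables, ignore_index=True).to_csv(
                    outdir / "enrichment_pattern.tsv", sep="\t", index=False
                )
            if temporal_tables:
                pd.concat(temporal_tables, ignore_index=True).to_csv(
                    outdir / "enrichment_temporal.tsv", sep="\t", index=False
                )
        else:
            logger.warning("no GMT supplied; enrichment skipped")
            pattern_tables, temporal_tables = [], []

        stage = "plot"
        fmt = cfg.plot_format
        plot_cascade_heatmap(
            plotted,
            scaled,
            PlotSpec(
                outdir / f"cascade_heatmap.{fmt}",
                markers=cfg.markers,
                show_switch_points=cfg.show_switch_points,
            ),
            switchpoints=switch,
        )
        if pattern_tables:
            plot_enrichment_dot(
                pd.concat(pattern_tables, ignore_index=True),
                PlotSpec(outdir / f"enrichment_pattern.{fmt}"),
            )
        if temporal_tables:
            plot_enrichment_dot(
                pd.concat(temporal_tables, ignore_index=True),
                PlotSpec(outdir / f"enrichment_temporal.{fmt}"),
            )
        if multi:
            cis = ms.ci_frame(consensus)
            firsts = cis.loc[cis["switch_rank"] == 1]
            if len(firsts):
                plot_switch_ci(firsts, PlotSpec(outdir / f"switch_ci.{fmt}"))
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise
    finally:
        logging.getLogger("ptcascade").removeHandler(handler)
        handler.close()
    return outdir
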