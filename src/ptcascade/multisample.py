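"""Multi-sample consensus: per-sample fits, pattern agreement,
mean trajectories and switch-point confidence intervals.

Each sample is fitted independently (its own BH family) on its own
cells, with pseudotime min-max rescaled to [0, 1] and trajectories
evaluated on a shared uniform grid so samples are comparable.  A gene's
overall pattern is the modal pattern among valid samples (adjusted
p < alpha), its confidence the fraction of valid samples supporting
that mode; genes below the confidence cutoff (default 0.75, allowing
one of four samples to deviate) are dropped.  Consensus switch points
come from the standardized mean trajectory over supporting samples,
and each consensus point gets a cross-sample confidence interval
mean ± 2 SE from the matched per-sample switch pseudotimes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fit import ScaledTrajectory, TobitFit, fit_all_genes
from .io import ExpressionMatrix, PseudotimeOrdering, split_by_sample
from .ordering import _pattern_key
from .switchpoints import SwitchPointSet, detect_switch_points

logger = logging.getLogger(__name__)

__all__ = [
    "SwitchPointCI",
    "SampleConsensus",
    "fit_per_sample",
    "consensus_pattern",
    "mean_trajectory",
    "switchpoint_ci",
    "compare_switch_order",
    "consensus_analysis",
]

#: number of uniform grid points on the rescaled [0, 1] pseudotime axis
GRID_SIZE = 100

#: samples with fewer cells than this are excluded from the analysis
MIN_CELLS_PER_SAMPLE = 10


@dataclass
class SwitchPointCI:
    """Cross-sample confidence interval of one consensus switch point."""

    gene_id: str
    switch_rank: int
    direction: str
    mean: float
    se: float | None
    ci_lower: float
    ci_upper: float
    n_samples: int
    sample_times: dict[str, float] = field(default_factory=dict)

    @property
    def degenerate(self) -> bool:
        """True when only one sample contributed (SE undefined)."""
        return self.se is None


@dataclass
class SampleConsensus:
    """Cross-sample consensus record for one gene."""

    gene_id: str
    per_sample_pattern: dict[str, str]
    per_sample_padj: dict[str, float]
    valid_samples: list[str]
    supporting_samples: list[str]
    overall_pattern: str
    confidence: float
    retained: bool
    mean_traj: ScaledTrajectory | None = None
    switch_points: SwitchPointSet | None = None
    cis: list[SwitchPointCI] = field(default_factory=list)


def common_grid(n: int = GRID_SIZE) -> np.ndarray:
    return np.linspace(0.0, 1.0, n)


def rescale_pseudotime(t: np.ndarray) -> np.ndarray:
    """Min-max rescale a pseudotime vector to [0, 1]."""
    t = np.asarray(t, dtype=float)
    span = t.max() - t.min()
    if span <= 0:
        raise ValueError("degenerate pseudotime range")
    return (t - t.min()) / span


def fit_per_sample(
    m: ExpressionMatrix,
    orderings: dict[str, PseudotimeOrdering],
    alpha: float = 0.05,
    c: float = 0.1,
    df: int = 2,
    max_iter: int = 50,
) -> tuple[dict[str, dict[str, TobitFit]], dict[str, dict[str, ScaledTrajectory]]]:
    """Fit every gene separately within each sample.

    Pseudotimes are rescaled to [0, 1] per sample and trajectories
    evaluated on the shared uniform grid.  Samples with fewer than
    ``MIN_CELLS_PER_SAMPLE`` cells are excluded with a warning.
    Returns per-sample fit and scaled-trajectory dictionaries.
    """
    if len(orderings) < 2:
        raise ValueError(
            "multi-sample mode needs >= 2 samples; use the single-sample pipeline instead"
        )
    per_sample = split_by_sample(m, orderings)
    grid = common_grid()
    fits: dict[str, dict[str, TobitFit]] = {}
    scaled: dict[str, dict[str, ScaledTrajectory]] = {}
    for sample, sub in per_sample.items():
        if sub.n_cells < MIN_CELLS_PER_SAMPLE:
            logger.warning("sample %s has %d cells (<%d); excluded", sample, sub.n_cells, MIN_CELLS_PER_SAMPLE)
            continue
        t01 = rescale_pseudotime(orderings[sample].pseudotime)
        ordering = PseudotimeOrdering(list(orderings[sample].cell_ids), t01, sample)
        fits[sample], scaled[sample] = fit_all_genes(
            sub, ordering, alpha=alpha, c=c, df=df, max_iter=max_iter, grid=grid
        )
    return fits, scaled


def consensus_pattern(
    labels: dict[str, str],
    padj: dict[str, float],
    alpha: float = 0.05,
    min_conf: float = 0.75,
) -> tuple[str | None, float, list[str], bool]:
    """Modal pattern among valid samples and its confidence score.

    A sample is valid if its adjusted p-value is below ``alpha``; the
    overall pattern is the most frequent pattern among valid samples
    (ties resolved toward the less complex pattern, then
    lexicographically with I before D); confidence = supporting/valid.
    Returns (pattern, confidence, supporting samples, retained flag).
    """
    valid = [s for s in labels if padj.get(s, 1.0) < alpha]
    if not valid:
        return None, 0.0, [], False
    counts = Counter(labels[s] for s in valid)
    top = max(counts.values())
    candidates = sorted((p for p, c in counts.items() if c == top), key=_pattern_key)
    overall = candidates[0]
    supporting = [s for s in valid if labels[s] == overall]
    confidence = len(supporting) / len(valid)
    return overall, confidence, supporting, confidence >= min_conf


def mean_trajectory(trajectories: list[ScaledTrajectory]) -> ScaledTrajectory:
    """Pointwise mean of scaled trajectories on a shared grid,
    re-standardized to mean 0 / sd 1 before switch detection."""
    if not trajectories:
        raise ValueError("no supporting trajectories")
    grid = trajectories[0].grid
    stack = np.vstack([tr.x for tr in trajectories])
    avg = stack.mean(axis=0)
    sd = avg.std()
    if sd < 1e-12:
        raise ValueError("mean trajectory is constant: cannot scale")
    return ScaledTrajectory(trajectories[0].gene_id, grid, (avg - avg.mean()) / sd)


def _match_key(sw: SwitchPointSet) -> list[tuple[str, int]]:
    """(direction, rank among same-direction switches) for each point."""
    seen: Counter[str] = Counter()
    keys = []
    for d in sw.directions:
        keys.append((d, seen[d]))
        seen[d] += 1
    return keys


def switchpoint_ci(
    consensus_sw: SwitchPointSet,
    per_sample_sw: dict[str, SwitchPointSet],
) -> list[SwitchPointCI]:
    """Confidence intervals for consensus switch points.

    Per-sample points are matched to consensus points by direction and
    rank among same-direction switches; samples lacking a matching
    point are excluded from that point's interval.  SE uses the sample
    standard deviation (n-1); with a single contributing sample the
    interval collapses to the point and is flagged.
    """
    sample_keys = {s: dict(zip(_match_key(sw), sw.pseudotimes)) for s, sw in per_sample_sw.items()}
    out: list[SwitchPointCI] = []
    for rank, (key, direction) in enumerate(
        zip(_match_key(consensus_sw), consensus_sw.directions), 1
    ):
        matched = {s: keys[key] for s, keys in sample_keys.items() if key in keys}
        times = np.array(list(matched.values()), dtype=float)
        n = len(times)
        if n == 0:
            # no sample reproduces this consensus point; report the
            # consensus pseudotime itself, degenerate
            ct = consensus_sw.pseudotimes[rank - 1]
            out.append(SwitchPointCI(consensus_sw.gene_id, rank, direction, ct, None, ct, ct, 0))
            continue
        mean = float(times.mean())
        if n == 1:
            out.append(
                SwitchPointCI(consensus_sw.gene_id, rank, direction, mean, None, mean, mean, 1, matched)
            )
            continue
        se = float(times.std(ddof=1) / np.sqrt(n))
        out.append(
            SwitchPointCI(
                consensus_sw.gene_id, rank, direction, mean, se,
                mean - 2.0 * se, mean + 2.0 * se, n, matched,
            )
        )
    return out


def compare_switch_order(a: SwitchPointCI | None, b: SwitchPointCI | None) -> str:
    """Order two genes' first switch points by their CI bounds.

    Returns ``"A-earlier"`` if A's upper CI bound precedes B's lower
    bound, ``"B-earlier"`` symmetrically, else ``"indeterminate"``.
    """
    if a is None or b is None:
        return "indeterminate"
    if a.ci_upper < b.ci_lower:
        return "A-earlier"
    if b.ci_upper < a.ci_lower:
        return "B-earlier"
    return "indeterminate"


def consensus_analysis(
    fits: dict[str, dict[str, TobitFit]],
    scaled: dict[str, dict[str, ScaledTrajectory]],
    alpha: float = 0.05,
    min_conf: float = 0.75,
    method: str = "zero",
    gamma: float = 0.0,
) -> dict[str, SampleConsensus]:
    """Run the full cross-sample consensus for every gene.

    For each gene: per-sample patterns from per-sample switch points,
    modal-pattern consensus with confidence, mean trajectory over
    supporting samples, consensus switch points re-identified on it,
    and per-point CIs.  Genes without a valid sample or below the
    confidence cutoff are returned with ``retained=False`` (no
    trajectory aggregation).
    """
    samples = sorted(scaled)
    genes = sorted({g for s in samples for g in scaled[s]})
    out: dict[str, SampleConsensus] = {}
    for gene in genes:
        labels: dict[str, str] = {}
        padj: dict[str, float] = {}
        sw_by_sample: dict[str, SwitchPointSet] = {}
        for s in samples:
            if gene not in fits[s]:
                continue
            padj[s] = fits[s][gene].padj
            if gene in scaled[s]:
                sw = detect_switch_points(scaled[s][gene], method=method, gamma=gamma)
                if len(sw) == 0:
                    continue
                labels[s] = sw.pattern
                sw_by_sample[s] = sw
        overall, conf, supporting, retained = consensus_pattern(labels, padj, alpha, min_conf)
        cons = SampleConsensus(
            gene_id=gene,
            per_sample_pattern=labels,
            per_sample_padj=padj,
            valid_samples=[s for s in labels if padj.get(s, 1.0) < alpha],
            supporting_samples=supporting,
            overall_pattern=overall or "",
            confidence=conf,
            retained=retained,
        )
        if retained:
            try:
                cons.mean_traj = mean_trajectory([scaled[s][gene] for s in supporting])
            except ValueError as exc:
                logger.warning("gene %s dropped: %s", gene, exc)
                cons.retained = False
                out[gene] = cons
                continue
            cons.switch_points = detect_switch_points(cons.mean_traj, method=method, gamma=gamma)
            cons.cis = switchpoint_ci(
                cons.switch_points, {s: sw_by_sample[s] for s in supporting}
            )
        elif overall is None:
            logger.info("gene %s has no valid sample; dropped", gene)
        out[gene] = cons
    return out


def consensus_frame(consensus: dict[str, SampleConsensus]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "overall_pattern": c.overall_pattern,
            "confidence": c.confidence,
            "n_valid": len(c.valid_samples),
            "n_supporting": len(c.supporting_samples),
            "retained": c.retained,
        }
        for c in consensus.values()
    ]
    return pd.DataFrame(rows)


def ci_frame(consensus: dict[str, SampleConsensus]) -> pd.DataFrame:
    rows = []
    for c in consensus.values():
        for ci in c.cis:
            rows.append(
                {
                    "gene_id": ci.gene_id,
                    "switch_rank": ci.switch_rank,
                    "direction": ci.direction,
                    "mean_pseudotime": ci.mean,
                    "se": np.nan if ci.se is None else ci.se,
                    "ci_lower": ci.ci_lower,
                    "ci_upper": ci.ci_upper,
                    "n_samples": ci.n_samples,
                }
            )
    return pd.DataFrame(rows)
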