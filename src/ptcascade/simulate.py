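"""Synthetic expression cascades with known ground truth.

The generator emulates the structure the pipeline is designed to
detect: genes whose expression switches on (sigmoidal increase), off
(sigmoidal decrease), or transiently peaks/dips at a known pseudotime
``t0``, plus flat null genes, observed with Gaussian noise and
left-censoring near zero (values below the censor floor are recorded
as 0, emulating dropout).  In multi-sample mode each sample re-draws
its cells and jitters every gene's switch time by a small Gaussian
perturbation, mimicking biological replicates that traverse the same
program at slightly shifted paces.

True switch times are drawn uniformly on (0.1, 0.9): a switch at the
extreme ends of a trajectory is not identifiable from data covering
[0, 1], so boundary switches are excluded by construction rather than
generated and discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection, PseudotimeOrdering

__all__ = ["SyntheticTruth", "simulate_cascade", "make_toy_gmt"]

#: sigmoid transition width on the [0, 1] pseudotime scale
SIGMOID_STEEPNESS = 0.05

GENE_CLASSES = ("increasing", "decreasing", "transient-up", "transient-down", "flat")


@dataclass
class SyntheticTruth:
    """Per-gene ground truth of a simulated cascade."""

    table: pd.DataFrame  # gene_id, class, t0, amplitude, baseline
    noise_sd: float
    jitter_sd: float
    censor_floor: float
    sample_t0: pd.DataFrame | None = None  # gene_id x sample jittered t0

    def t0_of(self, gene_id: str) -> float:
        row = self.table.loc[self.table["gene_id"] == gene_id]
        return float(row["t0"].iloc[0])

    def classes(self) -> dict[str, str]:
        return dict(zip(self.table["gene_id"], self.table["class"]))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _mean_curve(cls: str, t: np.ndarray, t0: float, amplitude: float, baseline: float) -> np.ndarray:
    if cls == "increasing":
        return baseline + amplitude * _sigmoid((t - t0) / SIGMOID_STEEPNESS)
    if cls == "decreasing":
        return baseline + amplitude * _sigmoid(-(t - t0) / SIGMOID_STEEPNESS)
    if cls == "transient-up":
        return baseline + amplitude * np.exp(-0.5 * ((t - t0) / 0.1) ** 2)
    if cls == "transient-down":
        return baseline + amplitude * (1.0 - np.exp(-0.5 * ((t - t0) / 0.1) ** 2))
    if cls == "flat":
        return np.full_like(t, baseline + 0.5 * amplitude)
    raise ValueError(f"unknown gene class {cls!r}")


def true_switch_time(cls: str, t0: float, amplitude: float, baseline: float) -> float:
    """First zero-crossing of the standardized noise-free curve.

    This is the quantity a zero-crossing switch detector estimates: the
    pseudotime where the mean-0/sd-1 standardized population curve
    crosses zero.  For a sigmoid it differs from the construction
    midpoint ``t0`` by ``w * logit(1 - t0)`` (w = transition width), so
    off-center switches carry an intrinsic offset that no fitting
    method can remove; both quantities are recorded in the truth table.
    """
    if cls == "flat" or not np.isfinite(t0):
        return float("nan")
    grid = np.linspace(0.0, 1.0, 4001)
    mu = _mean_curve(cls, grid, t0, amplitude, baseline)
    sd = mu.std()
    if sd < 1e-12:
        return float("nan")
    z = (mu - mu.mean()) / sd
    idx = np.flatnonzero(z[:-1] * z[1:] < 0)
    if idx.size == 0:
        return float("nan")
    i = idx[0]
    frac = -z[i] / (z[i + 1] - z[i])
    return float(grid[i] + frac * (grid[i + 1] - grid[i]))


def simulate_cascade(
    n_genes: int,
    n_cells: int,
    n_samples: int = 1,
    frac_flat: float = 0.3,
    frac_transient: float = 0.0,
    noise_sd: float = 0.3,
    jitter_sd: float = 0.02,
    censor_floor: float = 0.1,
    amplitude: float = 2.0,
    baseline: float = 0.2,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, dict[str, PseudotimeOrdering], SyntheticTruth]:
    """Simulate a multi-gene cascade with known switch times.

    Cells receive pseudotimes uniform on [0, 1] per sample (sorted, so
    each sample's ordering is its cell order).  Non-flat, non-transient
    genes split evenly between increasing and decreasing.  Returns the
    expression matrix (cells of all samples concatenated, sample labels
    attached when ``n_samples > 1``), one ordering per sample, and the
    ground truth.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if n_cells < 50:
        raise ValueError("need >= 50 cells per sample")
    if not (0 <= frac_flat <= 1 and 0 <= frac_transient <= 1 and frac_flat + frac_transient <= 1):
        raise ValueError("invalid class fractions")
    rng = np.random.default_rng(seed)

    n_flat = round(frac_flat * n_genes)
    n_trans = round(frac_transient * n_genes)
    n_mono = n_genes - n_flat - n_trans
    classes = (
        ["increasing"] * ((n_mono + 1) // 2)
        + ["decreasing"] * (n_mono // 2)
        + ["transient-up"] * ((n_trans + 1) // 2)
        + ["transient-down"] * (n_trans // 2)
        + ["flat"] * n_flat
    )
    gene_ids = [f"g{i:04d}" for i in range(1, n_genes + 1)]
    t0 = rng.uniform(0.1, 0.9, n_genes)
    t0[np.array(classes) == "flat"] = np.nan
    truth_tab = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "class": classes,
            "t0": t0,
            "switch_t": [
                true_switch_time(cls, x0, amplitude, baseline)
                for cls, x0 in zip(classes, t0)
            ],
            "amplitude": amplitude,
            "baseline": baseline,
        }
    )

    samples = [f"s{k + 1}" for k in range(n_samples)]
    jitter = rng.normal(0.0, jitter_sd, (n_genes, n_samples)) if n_samples > 1 else np.zeros((n_genes, 1))
    sample_t0 = pd.DataFrame(t0[:, None] + jitter, index=gene_ids, columns=samples)

    blocks: list[np.ndarray] = []
    cell_ids: list[str] = []
    labels: list[str] = []
    orderings: dict[str, PseudotimeOrdering] = {}
    for k, sample in enumerate(samples):
        t = np.sort(rng.uniform(0.0, 1.0, n_cells))
        ids = [f"{sample}_c{i:05d}" for i in range(1, n_cells + 1)]
        block = np.empty((n_genes, n_cells))
        for gi, (cls, amp, base) in enumerate(zip(classes, truth_tab["amplitude"], truth_tab["baseline"])):
            g_t0 = float(sample_t0.iloc[gi, k]) if cls != "flat" else 0.5
            block[gi] = _mean_curve(cls, t, g_t0, amp, base)
        block += rng.normal(0.0, noise_sd, block.shape)
        block[block < censor_floor] = 0.0
        blocks.append(block)
        cell_ids.extend(ids)
        labels.extend([sample] * n_cells)
        orderings[sample] = PseudotimeOrdering(ids, t, sample)

    matrix = ExpressionMatrix(
        np.concatenate(blocks, axis=1),
        gene_ids,
        cell_ids,
        labels if n_samples > 1 else None,
    )
    truth = SyntheticTruth(truth_tab, noise_sd, jitter_sd, censor_floor, sample_t0)
    return matrix, orderings, truth


def make_toy_gmt(
    truth: SyntheticTruth,
    n_terms: int = 3,
    n_decoys: int = 0,
    seed: int | None = None,
) -> GeneSetCollection:
    """Build a gene-set collection from switch-time strata.

    Non-flat genes are split into ``n_terms`` contiguous strata of true
    switch time ("stratum_early", ..., given generic names stratum_1..k
    ordered early to late), so temporal enrichment has a known window
    of peak signal.  ``n_decoys`` additional terms draw members
    uniformly at random across all genes.
    """
    rng = np.random.default_rng(seed)
    tab = truth.table
    switching = tab.loc[tab["class"] != "flat"].sort_values("t0")
    genes = list(switching["gene_id"])
    if n_terms > len(genes):
        raise ValueError("more strata than switching genes")
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    strata = np.array_split(np.array(genes), n_terms)
    for i, members in enumerate(strata, 1):
        term = f"STRATUM_{i}"
        sets[term] = frozenset(members)
        names[term] = f"switch-time stratum {i} of {n_terms} (early to late)"
    all_genes = list(tab["gene_id"])
    size = max(2, len(genes) // max(n_terms, 1))
    for d in range(1, n_decoys + 1):
        term = f"DECOY_{d}"
        sets[term] = frozenset(rng.choice(all_genes, size=min(size, len(all_genes)), replace=False))
        names[term] = f"random decoy {d}"
    return GeneSetCollection(sets, names)


def write_simulation(
    outdir: str | Path,
    matrix: ExpressionMatrix,
    orderings: dict[str, PseudotimeOrdering],
    truth: SyntheticTruth,
    gmt: GeneSetCollection | None = None,
) -> None:
    """Write a simulated dataset as plain-text pipeline inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.to_frame().to_csv(outdir / "matrix.tsv", sep="\t")
    multi = len(orderings) > 1
    for sample, ordering in orderings.items():
        name = f"pseudotime_{sample}.tsv" if multi else "pseudotime.tsv"
        pd.DataFrame({"cell_id": ordering.cell_ids, "pseudotime": ordering.pseudotime}).to_csv(
            outdir / name, sep="\t", index=False, header=False
        )
    if matrix.sample_labels is not None:
        pd.DataFrame({"cell_id": matrix.cell_ids, "sample": matrix.sample_labels}).to_csv(
            outdir / "samples.tsv", sep="\t", index=False, header=False
        )
    truth.table.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if gmt is not None:
        with open(outdir / "genesets.gmt", "w") as fh:
            for term in gmt:
                fh.write("\t".join([term, gmt.names[term], *sorted(gmt[term])]) + "\n")
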