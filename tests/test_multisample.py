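import numpy as np
import pytest

from ptcascade.fit import ScaledTrajectory
from ptcascade.io import ExpressionMatrix, PseudotimeOrdering
from ptcascade.multisample import (
    SwitchPointCI,
    compare_switch_order,
    consensus_analysis,
    consensus_pattern,
    fit_per_sample,
    mean_trajectory,
    rescale_pseudotime,
    switchpoint_ci,
)
from ptcascade.simulate import simulate_cascade
from ptcascade.switchpoints import SwitchPointSet


def sw(gene, positions, pts, directions):
    return SwitchPointSet(gene, "zero", positions, pts, directions)


class TestConsensusPattern:
    def test_three_of_four_agree_retained(self):
        labels = {f"s{i}": p for i, p in enumerate(["I", "I", "I", "D"], 1)}
        padj = {s: 0.01 for s in labels}
        overall, conf, supporting, retained = consensus_pattern(labels, padj)
        assert overall == "I" and conf == 0.75 and retained
        assert sorted(supporting) == ["s1", "s2", "s3"]

    def test_tie_resolves_to_simpler_then_lexicographic(self):
        labels = {f"s{i}": p for i, p in enumerate(["I", "I", "D", "D"], 1)}
        padj = {s: 0.01 for s in labels}
        overall, conf, _, retained = consensus_pattern(labels, padj)
        assert overall == "I" and conf == 0.5 and not retained

    def test_all_agree_confidence_one(self):
        labels = {f"s{i}": "ID" for i in range(1, 5)}
        overall, conf, _, retained = consensus_pattern(labels, {s: 0.001 for s in labels})
        assert overall == "ID" and conf == 1.0 and retained

    def test_invalid_samples_excluded_from_denominator(self):
        labels = {"s1": "I", "s2": "I", "s3": "D"}
        padj = {"s1": 0.01, "s2": 0.01, "s3": 0.5}  # s3 not valid
        overall, conf, supporting, retained = consensus_pattern(labels, padj)
        assert overall == "I" and conf == 1.0 and retained and "s3" not in supporting

    def test_no_valid_sample_dropped(self):
        overall, conf, _, retained = consensus_pattern({"s1": "I"}, {"s1": 0.9})
        assert overall is None and not retained

    def test_invariant_to_sample_relabeling(self):
        labels = {"a": "I", "b": "D", "c": "I", "d": "I"}
        padj = {s: 0.01 for s in labels}
        ref = consensus_pattern(labels, padj)
        perm = {"x": "D", "y": "I", "z": "I", "w": "I"}
        out = consensus_pattern(perm, {s: 0.01 for s in perm})
        assert (ref[0], ref[1], ref[3]) == (out[0], out[1], out[3])


class TestMeanTrajectory:
    def test_identical_inputs_reproduced(self):
        grid = np.linspace(0, 1, 5)
        x = np.array([-1.2, -0.6, 0.0, 0.6, 1.2])
        trs = [ScaledTrajectory("g", grid, x.copy()) for _ in range(3)]
        np.testing.assert_allclose(mean_trajectory(trs).x, x / x.std(), atol=1e-12)

    def test_opposite_trajectories_degenerate(self):
        grid = np.linspace(0, 1, 4)
        x = np.array([-1.0, -0.5, 0.5, 1.0])
        with pytest.raises(ValueError, match="constant"):
            mean_trajectory(
                [ScaledTrajectory("g", grid, x), ScaledTrajectory("g", grid, -x)]
            )

    def test_output_standardized(self, rng):
        grid = np.linspace(0, 1, 50)
        trs = [ScaledTrajectory("g", grid, rng.normal(size=50)) for _ in range(4)]
        out = mean_trajectory(trs)
        assert abs(out.x.mean()) < 1e-10 and abs(out.x.std() - 1) < 1e-9


class TestSwitchpointCI:
    def test_direct_formula(self):
        cons = sw("g", [10], [12.0], ["I"])
        per = {
            "s1": sw("g", [10], [10.0], ["I"]),
            "s2": sw("g", [11], [12.0], ["I"]),
            "s3": sw("g", [12], [14.0], ["I"]),
        }
        (ci,) = switchpoint_ci(cons, per)
        assert ci.mean == 12.0
        assert abs(ci.se - 2 / np.sqrt(3)) < 1e-12
        assert abs(ci.ci_lower - 9.6906) < 1e-3 and abs(ci.ci_upper - 14.3094) < 1e-3

    def test_identical_samples_zero_width(self):
        cons = sw("g", [5], [5.0], ["D"])
        per = {s: sw("g", [5], [5.0], ["D"]) for s in ("a", "b", "c")}
        (ci,) = switchpoint_ci(cons, per)
        assert ci.se == 0.0 and ci.ci_lower == ci.ci_upper == 5.0

    def test_partial_matching_uses_available_samples(self):
        # second I-crossing exists in only 2 of 3 samples -> n = 2 there
        cons = sw("g", [3, 6, 9], [3.0, 6.0, 9.0], ["I", "D", "I"])
        per = {
            "s1": sw("g", [3, 6, 9], [3.0, 6.0, 9.0], ["I", "D", "I"]),
            "s2": sw("g", [2, 7, 8], [2.0, 7.0, 8.0], ["I", "D", "I"]),
            "s3": sw("g", [4], [4.0], ["I"]),
        }
        cis = switchpoint_ci(cons, per)
        assert [c.n_samples for c in cis] == [3, 2, 2]

    def test_single_sample_flagged(self):
        cons = sw("g", [4], [4.0], ["I"])
        (ci,) = switchpoint_ci(cons, {"only": sw("g", [4], [4.5], ["I"])})
        assert ci.degenerate and ci.ci_lower == ci.ci_upper == 4.5


class TestCompareSwitchOrder:
    def _ci(self, lo, hi):
        return SwitchPointCI("g", 1, "I", (lo + hi) / 2, 0.1, lo, hi, 4)

    def test_disjoint_intervals(self):
        assert compare_switch_order(self._ci(1, 2), self._ci(3, 4)) == "A-earlier"
        assert compare_switch_order(self._ci(3, 4), self._ci(1, 2)) == "B-earlier"

    def test_overlap_indeterminate(self):
        assert compare_switch_order(self._ci(1, 3), self._ci(2, 4)) == "indeterminate"

    def test_missing_ci_indeterminate(self):
        assert compare_switch_order(None, self._ci(1, 2)) == "indeterminate"


def replicate_samples(n_genes=30, n_cells=100, n_samples=3, seed=4):
    """Identical copies of one sample under different sample labels."""
    m1, ords1, truth = simulate_cascade(n_genes, n_cells, seed=seed)
    base_t = ords1["s1"].pseudotime
    vals = np.tile(m1.values, (1, n_samples))
    cells, labels = [], []
    orderings = {}
    for k in range(n_samples):
        s = f"r{k + 1}"
        ids = [f"{s}_{c}" for c in m1.cell_ids]
        cells.extend(ids)
        labels.extend([s] * n_cells)
        orderings[s] = PseudotimeOrdering(ids, base_t.copy(), s)
    return ExpressionMatrix(vals, m1.gene_ids, cells, labels), orderings, truth


class TestMultiSamplePipeline:
    def test_single_sample_input_rejected(self):
        m, ords, _ = simulate_cascade(10, 60, seed=0)
        labeled = ExpressionMatrix(m.values, m.gene_ids, m.cell_ids, ["s1"] * m.n_cells)
        with pytest.raises(ValueError, match="single-sample"):
            fit_per_sample(labeled, {"s1": ords["s1"]})

    def test_identical_samples_full_agreement(self):
        m, orderings, _ = replicate_samples()
        fits, scaled = fit_per_sample(m, orderings)
        # identical data -> identical per-sample fits
        samples = sorted(fits)
        for g in fits[samples[0]]:
            ps = [fits[s][g].pvalue for s in samples]
            assert max(ps) - min(ps) < 1e-6
        consensus = consensus_analysis(fits, scaled)
        retained = [c for c in consensus.values() if c.retained]
        assert retained
        for c in retained:
            assert c.confidence == 1.0
            for ci in c.cis:
                assert ci.ci_upper - ci.ci_lower <= 1e-9

    def test_rescale_pseudotime_to_unit_interval(self):
        t = rescale_pseudotime(np.array([3.0, 5.0, 9.0]))
        np.testing.assert_allclose(t, [0.0, 1 / 3, 1.0])
        with pytest.raises(ValueError):
            rescale_pseudotime(np.array([2.0, 2.0]))

    def test_ci_width_shrinks_with_sample_count(self):
        # cross-sample SE scales as 1/sqrt(n): widths at n=16 should be
        # about half those at n=4
        widths = {}
        for n in (4, 16):
            m, ords, truth = simulate_cascade(
                16, 100, n_samples=n, frac_flat=0.0, seed=99
            )
            fits, scaled = fit_per_sample(m, ords)
            consensus = consensus_analysis(fits, scaled)
            ws = [
                c.cis[0].ci_upper - c.cis[0].ci_lower
                for c in consensus.values()
                if c.retained and c.cis and c.cis[0].n_samples >= n - 1
            ]
            widths[n] = np.mean(ws)
        ratio = widths[4] / widths[16]
        assert 1.4 < ratio < 2.9
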