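"""Unit tests for normalisation, stage assembly and DE filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynppi.preprocess import (ExpressionMatrix, StageDesign, anova_de_filter,
                               assemble_stage_profile, collapse_probes,
                               default_stage_designs, normalize_to_baseline,
                               quantile_normalize)
from dynppi.simulate import SimulatedDesign, generate_dataset, make_ground_truth


def _matrix(values, conditions=None, days=None, reps=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    names = [f"s{i}" for i in range(n_samples)]
    ann = pd.DataFrame({
        "condition": conditions or ["A"] * n_samples,
        "day": days or list(range(n_samples)),
        "replicate": reps or [1] * n_samples,
    }, index=names)
    frame = pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)],
                         columns=names)
    return ExpressionMatrix(frame, ann)


class TestQuantileNormalize:
    def test_two_sample_worked_example(self):
        matrix = _matrix(np.column_stack([[1, 3, 5], [2, 4, 6]]))
        out = quantile_normalize(matrix).values.to_numpy()
        np.testing.assert_allclose(out[:, 0], [1.5, 3.5, 5.5])
        np.testing.assert_allclose(out[:, 1], [1.5, 3.5, 5.5])

    def test_identical_samples_are_a_fixed_point(self):
        col = [4.0, 1.0, 7.0]
        out = quantile_normalize(_matrix(np.column_stack([col, col, col])))
        np.testing.assert_allclose(out.values.to_numpy(),
                                   np.column_stack([col, col, col]))

    def test_ties_get_mean_of_tied_reference_values(self):
        # sample 1 has a tie spanning ranks 1-2; reference = mean of sorted cols
        matrix = _matrix(np.column_stack([[1.0, 1.0, 5.0], [2.0, 4.0, 6.0]]))
        out = quantile_normalize(matrix).values.to_numpy()
        reference = np.array([1.5, 2.5, 5.5])
        np.testing.assert_allclose(out[:, 1], reference)
        np.testing.assert_allclose(out[:2, 0], np.full(2, reference[:2].mean()))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_column_order_statistics_identical_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        matrix = _matrix(rng.normal(size=(8, 4)))
        once = quantile_normalize(matrix)
        vals = once.values.to_numpy()
        sorted_cols = np.sort(vals, axis=0)
        for j in range(1, vals.shape[1]):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values.to_numpy(), vals, atol=1e-12)


class TestStageAssembly:
    def test_stage_two_takes_late_days_from_second_condition(self):
        truth = make_ground_truth(n_genes=4, n_true_edges=3, seed=0)
        matrix = generate_dataset(truth, SimulatedDesign(), obs_noise_sd=0.0)
        design = default_stage_designs()[1]
        assert design.segments[:2] == (("LSB", 0), ("LSB", 1))
        assert all(c == "LSB/S/F8" for c, d in design.segments[2:])
        profile = assemble_stage_profile(matrix, design)
        assert list(profile.days) == [0, 1, 3, 5, 7, 11, 13]
        ann = matrix.annotations
        for cond, day in design.segments:
            cols = ann.index[(ann["condition"] == cond) & (ann["day"] == day)]
            np.testing.assert_allclose(
                profile.values[day].to_numpy(),
                matrix.values[cols].mean(axis=1).to_numpy())

    def test_replicates_are_averaged(self):
        matrix = _matrix(np.array([[1.0, 2.0, 3.0]]), conditions=["A"] * 3,
                         days=[0, 0, 0], reps=[1, 2, 3])
        design = StageDesign("s", (("A", 0),))
        with pytest.raises(ValueError):
            StageDesign("bad", (("A", 1), ("A", 0)))
        profile = assemble_stage_profile(matrix, design)
        assert profile.values.iloc[0, 0] == pytest.approx(2.0)

    def test_missing_cell_is_named_in_error(self):
        matrix = _matrix(np.ones((2, 2)), conditions=["A", "A"], days=[0, 1])
        design = StageDesign("s", (("A", 0), ("B", 5)))
        with pytest.raises(KeyError, match="day=5"):
            assemble_stage_profile(matrix, design)

    def test_commutes_with_gene_subsetting(self):
        truth = make_ground_truth(n_genes=6, n_true_edges=5, seed=3)
        matrix = generate_dataset(truth, SimulatedDesign())
        design = default_stage_designs()[0]
        subset = truth.genes[:3]
        a = assemble_stage_profile(matrix.subset_genes(subset), design)
        b = assemble_stage_profile(matrix, design).subset_genes(subset)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestBaselineAndProbes:
    def test_day0_mean_is_subtracted_per_condition(self, small_matrix):
        out = normalize_to_baseline(small_matrix)
        ann = out.annotations
        for cond in ("A", "B"):
            day0 = ann.index[(ann["condition"] == cond) & (ann["day"] == 0)]
            np.testing.assert_allclose(out.values[day0].mean(axis=1), 0.0)

    def test_max_variance_probe_is_kept(self):
        values = pd.DataFrame(
            [[1.0, 1.0, 1.0], [0.0, 5.0, 10.0], [2.0, 2.0, 3.0]],
            index=["p1", "p2", "p3"], columns=["a", "b", "c"])
        collapsed = collapse_probes(values, {"p1": "g1", "p2": "g1", "p3": "g2"})
        np.testing.assert_allclose(collapsed.loc["g1"], [0.0, 5.0, 10.0])
        assert list(collapsed.index) == ["g1", "g2"]


class TestAnovaFilter:
    @staticmethod
    def _design(n_days=4):
        return StageDesign("s", tuple(("A", d) for d in range(n_days)))

    @staticmethod
    def _null_matrix(rng, n_genes=50, n_days=4, reps=3, signal_genes=()):
        cols, names, ann = [], [], []
        data = rng.normal(size=(n_genes, n_days * reps))
        k = 0
        for day in range(n_days):
            for rep in range(1, reps + 1):
                names.append(f"s{k}")
                ann.append(("A", day, rep))
                k += 1
        for g in signal_genes:
            for day in range(n_days):
                data[g, day * reps:(day + 1) * reps] += 5.0 * day
        frame = pd.DataFrame(data, index=[f"g{i}" for i in range(n_genes)],
                             columns=names)
        annotations = pd.DataFrame(ann, index=names,
                                   columns=["condition", "day", "replicate"])
        return ExpressionMatrix(frame, annotations)

    def test_constant_gene_gets_p_one_and_is_excluded(self, rng):
        matrix = self._null_matrix(rng, n_genes=10)
        matrix.values.iloc[0] = 3.0
        table = anova_de_filter(matrix, self._design(), 0.5)
        assert table.loc["g0", "p"] == 1.0
        assert not table.loc["g0", "selected"]

    def test_bh_adjustment_hand_example(self, rng):
        # independently computed: p * m / rank with step-up monotonicity
        matrix = self._null_matrix(rng, n_genes=3, signal_genes=(0,))
        table = anova_de_filter(matrix, self._design(), 1e-3)
        p = table["p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        expected = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.minimum(expected, 1.0)
        np.testing.assert_allclose(table["p_adj"].to_numpy()[order], expected)
        assert table.loc["g0", "selected"]

    def test_threshold_one_keeps_all_nonconstant_and_tiny_threshold_none(self, rng):
        matrix = self._null_matrix(rng, n_genes=30)
        all_in = anova_de_filter(matrix, self._design(), 1.0)
        assert all_in["selected"].all()
        none_in = anova_de_filter(matrix, self._design(), 1e-12)
        assert not none_in["selected"].any()

    def test_single_replicate_rejected(self):
        matrix = _matrix(np.random.default_rng(0).normal(size=(5, 4)),
                         conditions=["A"] * 4, days=[0, 1, 2, 3])
        with pytest.raises(ValueError, match="replicate"):
            anova_de_filter(matrix, self._design(), 0.05)
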