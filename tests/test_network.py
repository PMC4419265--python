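"""Unit tests for interpolation, the bilinear regression and AIC pruning."""

import math

import numpy as np
import pandas as pd
import pytest

from dynppi.network import (FitConfig, RankDeficientDesign, StageNetwork,
                            aic_score, build_regression_problem, choose_L,
                            construct_stage_network, edge_recovery, fit_target,
                            interpolate_profile, prune_by_aic)
from dynppi.preprocess import StageProfile
from dynppi.simulate import make_ground_truth, simulate_unit_grid_dataset

from conftest import manual_truth


def _profile(values, days, stage="I"):
    genes = [f"g{i}" for i in range(len(values))]
    return StageProfile(stage, pd.DataFrame(np.asarray(values, float),
                                            index=genes, columns=days))


class TestChooseL:
    @pytest.mark.parametrize("q,mult,expected",
                             [(5, 4.0, 28), (0, 3.0, 6), (10, 5.0, 60)])
    def test_parameter_count_scaling(self, q, mult, expected):
        assert choose_L(q, mult) == expected

    def test_multiplier_outside_3_to_5_rejected(self):
        with pytest.raises(ValueError):
            choose_L(4, 2.0)


class TestInterpolation:
    def test_matching_grid_returns_input(self):
        profile = _profile([[1.0, 4.0, 2.0, 5.0, 3.0]], [0, 1, 2, 3, 4])
        out = interpolate_profile(profile, 5)
        np.testing.assert_allclose(out.values.to_numpy(),
                                   profile.values.to_numpy())

    def test_linear_series_reproduced_exactly(self):
        days = [0.0, 1.0, 3.0, 5.0, 7.0]
        profile = _profile([[2 * d + 1 for d in days]], days)
        out = interpolate_profile(profile, 17)
        np.testing.assert_allclose(out.values.to_numpy()[0],
                                   2 * out.days + 1, atol=1e-12)

    def test_constant_series_stays_constant(self):
        profile = _profile([[3.0] * 5], [0, 1, 2, 3, 4])
        out = interpolate_profile(profile, 12)
        np.testing.assert_allclose(out.values.to_numpy(), 3.0)

    def test_knot_values_preserved_on_refined_grid(self):
        days = [0.0, 1.0, 2.0, 3.0]
        profile = _profile([[1.0, -1.0, 2.0, 0.5]], days)
        out = interpolate_profile(profile, 7)  # grid step 0.5 hits every knot
        np.testing.assert_allclose(out.values.to_numpy()[0, ::2],
                                   profile.values.to_numpy()[0], atol=1e-12)

    def test_too_few_points_or_shrinking_rejected(self):
        with pytest.raises(ValueError):
            interpolate_profile(_profile([[1.0, 2.0, 3.0]], [0, 1, 2]), 10)
        with pytest.raises(ValueError):
            interpolate_profile(_profile([[1.0, 2.0, 3.0, 4.0]], [0, 1, 2, 3]), 3)


class TestFitTarget:
    def test_noiseless_recovery_is_exact(self):
        truth = make_ground_truth(n_genes=6, n_true_edges=6, noise_sd=0.0, seed=11)
        profile, x_profile = simulate_unit_grid_dataset(truth, "I", 40)
        index = truth.gene_index
        target = truth.genes[0]
        neighbors = sorted({b for a, b in truth.candidate_edges if a == target}
                           | {a for a, b in truth.candidate_edges if b == target})
        if not neighbors:
            pytest.skip("drawn truth left the first gene isolated")
        problem = build_regression_problem(profile.values, target, neighbors,
                                           x=x_profile.values)
        fit = fit_target(problem)
        for q in neighbors:
            true_b = truth.stage_networks["I"][index[target], index[q]]
            assert fit.b[q] == pytest.approx(true_b, abs=1e-9)
        assert fit.alpha == pytest.approx(truth.translation_effects[index[target]],
                                          abs=1e-9)
        assert fit.beta == pytest.approx(truth.degradation_rates[index[target]],
                                         abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_orthogonal_response_gives_zero_coefficients(self):
        # design columns live on even indices, response on odd ones
        L = 8
        design = np.zeros((L, 2))
        design[::2, 0] = 1.0
        design[::2, 1] = [1.0, -1.0, 2.0, -2.0]
        response = np.zeros(L)
        response[1::2] = [3.0, 1.0, -2.0, 4.0]
        from dynppi.network import RegressionProblem
        problem = RegressionProblem("t", ["q1"], response, design, False, L)
        fit = fit_target(problem)
        assert fit.b["q1"] == pytest.approx(0.0, abs=1e-12)
        assert fit.rss == pytest.approx(float(response @ response))

    def test_duplicated_neighbor_column_raises(self):
        truth = make_ground_truth(n_genes=5, n_true_edges=4, noise_sd=0.0, seed=2)
        profile, x_profile = simulate_unit_grid_dataset(truth, "I", 30)
        target = truth.genes[0]
        other = truth.genes[1]
        problem = build_regression_problem(profile.values, target,
                                           [other, other], x=x_profile.values)
        with pytest.raises(RankDeficientDesign):
            fit_target(problem)


class TestAicScore:
    def test_arithmetic_example(self):
        assert aic_score(rss=28.0, L=28, k=3) == pytest.approx(6.0)

    def test_each_parameter_costs_two(self):
        assert aic_score(5.0, 20, 4) - aic_score(5.0, 20, 3) == pytest.approx(2.0)

    def test_halving_rss_drops_L_ln2(self):
        drop = aic_score(10.0, 28, 3) - aic_score(5.0, 28, 3)
        assert drop == pytest.approx(28 * math.log(2))

    def test_zero_rss_is_finite(self):
        assert np.isfinite(aic_score(0.0, 10, 2))

    def test_aicc_adds_small_sample_penalty(self):
        plain = aic_score(5.0, 20, 4)
        corrected = aic_score(5.0, 20, 4, variant="aicc")
        assert corrected - plain == pytest.approx(2 * 4 * 5 / 15)


class TestPruning:
    def test_noiseless_decoy_is_excluded(self):
        # 3 candidate neighbours, one of them inert in the generating model
        truth = manual_truth(
            ["A", "B", "C", "D"],
            {"I": {("A", "B"): 0.04, ("A", "C"): -0.03,
                   ("B", "A"): 0.02, ("C", "A"): 0.01}},
            alpha=0.3, beta=0.3, noise_sd=0.0)
        truth.candidate_edges = sorted(set(truth.candidate_edges) | {("A", "D")})
        profile, x_profile = simulate_unit_grid_dataset(truth, "I", 30)
        problem = build_regression_problem(profile.values, "A", ["B", "C", "D"],
                                           x=x_profile.values)
        fit = prune_by_aic(problem, FitConfig(strategy="exhaustive"))
        assert set(fit.neighbors) == {"B", "C"}

    def test_no_neighbors_returns_base_model(self):
        truth = make_ground_truth(n_genes=4, n_true_edges=3, noise_sd=0.0, seed=5)
        profile, x_profile = simulate_unit_grid_dataset(truth, "I", 20)
        problem = build_regression_problem(profile.values, truth.genes[0], [],
                                           x=x_profile.values)
        fit = prune_by_aic(problem)
        assert fit.neighbors == [] and fit.b == {}
        assert fit.k == 2

    def test_greedy_equals_exhaustive_on_a_noiseless_instance(self):
        truth = manual_truth(
            ["A", "B", "C"], {"I": {("A", "B"): 0.05, ("A", "C"): -0.02}},
            alpha=0.2, beta=0.4, noise_sd=0.0)
        profile, x_profile = simulate_unit_grid_dataset(truth, "I", 30)
        problem = build_regression_problem(profile.values, "A", ["B", "C"],
                                           x=x_profile.values)
        exhaustive = prune_by_aic(problem, FitConfig(strategy="exhaustive"))
        greedy = prune_by_aic(problem, FitConfig(strategy="greedy-backward"))
        assert greedy.neighbors == exhaustive.neighbors
        assert greedy.aic == pytest.approx(exhaustive.aic)


class TestConstructStageNetwork:
    def test_candidates_disjoint_from_profile_are_ignored(self):
        truth = make_ground_truth(n_genes=5, n_true_edges=4, noise_sd=0.0, seed=3)
        profile, _ = simulate_unit_grid_dataset(truth, "I", 20)
        net = construct_stage_network(profile, [("X1", "X2")], FitConfig())
        assert net.b.nnz == 0

    def test_noiseless_network_recovers_true_edges_through_decoys(self):
        from dynppi.simulate import generate_candidate_network
        truth = make_ground_truth(n_genes=12, n_true_edges=14, noise_sd=0.0,
                                  edge_presence=1.0, seed=21)
        candidates = generate_candidate_network(truth, 1.0, seed=22)
        profile, x_profile = simulate_unit_grid_dataset(truth, "I", 70)
        net = construct_stage_network(profile, candidates, FitConfig(),
                                      x_profile=x_profile)
        metrics = edge_recovery(truth.true_directed("I"), net)
        assert metrics["precision"] == 1.0
        assert metrics["recall"] == 1.0

    def test_nonzeros_are_subset_of_candidates(self):
        truth = make_ground_truth(n_genes=10, n_true_edges=12, noise_sd=0.05, seed=9)
        profile, x_profile = simulate_unit_grid_dataset(
            truth, "I", 60, rng=np.random.default_rng(1))
        candidates = list(truth.candidate_edges)
        net = construct_stage_network(profile, candidates, FitConfig(),
                                      x_profile=x_profile)
        allowed = {tuple(sorted(e)) for e in candidates}
        for p, q in net.directed_pairs():
            assert tuple(sorted((p, q))) in allowed

    def test_symmetrization_averages_the_two_roles(self):
        truth = make_ground_truth(n_genes=8, n_true_edges=8, noise_sd=0.0,
                                  edge_presence=1.0, seed=13)
        profile, x_profile = simulate_unit_grid_dataset(truth, "I", 50)
        net = construct_stage_network(profile, truth.candidate_edges,
                                      FitConfig(symmetrize=True),
                                      x_profile=x_profile)
        dense = net.b.toarray()
        np.testing.assert_allclose(dense, dense.T, atol=1e-12)
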