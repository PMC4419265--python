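"""Simulation studies that benchmark the identification pipeline.

Each study draws ground truths from the synthetic generator, runs the same
fitting code the pipeline uses, and measures recovery.  The shared protocol:
unit-step records of 96 steps (about four periods of the slowest mRNA driver,
enough excitation to identify every parameter), three replicate trajectories
averaged exactly as the pipeline averages replicate arrays, and ground truths
with every true edge active in the fitted stage so "true edges" is
unambiguous.
"""

from __future__ import annotations

import numpy as np

from .network import (FitConfig, build_regression_problem,
                      construct_stage_network, edge_recovery, prune_by_aic)
from .simulate import (generate_candidate_network, make_ground_truth,
                       mrna_profiles, simulate_unit_grid_dataset)

RECOVERY_STAGE = "I"
RECOVERY_STEPS = 96
RECOVERY_REPLICATES = 3


def _recovery_instance(n_genes, n_true_edges, noise_sd, decoy_ratio, seed,
                       n_steps=RECOVERY_STEPS):
    truth = make_ground_truth(n_genes=n_genes, n_true_edges=n_true_edges,
                              noise_sd=noise_sd, edge_presence=1.0, seed=seed)
    candidates = (generate_candidate_network(truth, decoy_ratio, seed=seed + 10_000)
                  if decoy_ratio > 0 else list(truth.candidate_edges))
    rng = np.random.default_rng(seed + 20_000)
    n_reps = RECOVERY_REPLICATES if noise_sd > 0 else 1
    profile, x_profile = simulate_unit_grid_dataset(
        truth, RECOVERY_STAGE, n_steps, n_replicates=n_reps, rng=rng)
    network = construct_stage_network(profile, candidates, FitConfig(),
                                      x_profile=x_profile)
    return truth, network


def _b_errors(truth, network):
    """Per-entry absolute errors of b over the stage's true directed pairs."""
    index = truth.gene_index
    net_index = network.gene_index
    b_true = truth.stage_networks[RECOVERY_STAGE]
    errors = []
    for p, q in sorted(truth.true_directed(RECOVERY_STAGE)):
        est = network.b[net_index[p], net_index[q]]
        errors.append(abs(est - b_true[index[p], index[q]]))
    return np.asarray(errors)


def exact_recovery_study(n_genes: int = 30, n_true_edges: int = 40,
                         seed: int = 0) -> dict:
    """Noise-free identification: all parameters should be exact.

    Returns the maximum absolute error of the b, alpha and beta estimates
    against ground truth over every fitted target.
    """
    truth, network = _recovery_instance(n_genes, n_true_edges,
                                        noise_sd=0.0, decoy_ratio=0.0, seed=seed)
    index = truth.gene_index
    max_b = float(_b_errors(truth, network).max())
    alpha_err, beta_err = [], []
    for target, fit in network.fits.items():
        p = index[target]
        alpha_err.append(abs(fit.alpha - truth.translation_effects[p]))
        beta_err.append(abs(fit.beta - truth.degradation_rates[p]))
    return {"max_abs_error_b": max_b,
            "max_abs_error_alpha": float(max(alpha_err)),
            "max_abs_error_beta": float(max(beta_err)),
            "n_targets": len(network.fits),
            "n_failed": len(network.failed_targets)}


def noisy_recovery_study(noise_levels=(0.01, 0.05, 0.1), n_seeds: int = 10,
                         n_genes: int = 20, n_true_edges: int = 25,
                         seed: int = 0) -> dict:
    """Mean RMSE of the b estimates as a function of process-noise level."""
    out = {}
    for noise_sd in noise_levels:
        rmses = []
        for k in range(n_seeds):
            truth, network = _recovery_instance(
                n_genes, n_true_edges, noise_sd=noise_sd, decoy_ratio=0.0,
                seed=seed + 100 * k + int(noise_sd * 10_000))
            errors = _b_errors(truth, network)
            rmses.append(float(np.sqrt(np.mean(errors ** 2))))
        out[noise_sd] = float(np.mean(rmses))
    return out


def decoy_rejection_study(n_seeds: int = 10, n_genes: int = 20,
                          n_true_edges: int = 25, decoy_ratio: float = 1.0,
                          noise_sd: float = 0.05, seed: int = 0) -> dict:
    """AIC pruning against an equal number of decoy candidate edges."""
    precisions, recalls = [], []
    for k in range(n_seeds):
        truth, network = _recovery_instance(
            n_genes, n_true_edges, noise_sd=noise_sd, decoy_ratio=decoy_ratio,
            seed=seed + k)
        metrics = edge_recovery(truth.true_directed(RECOVERY_STAGE), network)
        precisions.append(metrics["precision"])
        recalls.append(metrics["recall"])
    return {"mean_precision": float(np.mean(precisions)),
            "mean_recall": float(np.mean(recalls)),
            "n_seeds": n_seeds}


def null_de_study(n_genes: int = 2000, n_days: int = 7, n_replicates: int = 3,
                  fdr_threshold: float = 1e-3, seed: int = 0) -> dict:
    """False-selection rate of the ANOVA/BH filter on pure-noise genes.

    Every gene is i.i.d. Gaussian with no time effect, so any selection is a
    false discovery; BH should keep the selected fraction at or below the
    threshold.
    """
    import pandas as pd

    from .preprocess import ExpressionMatrix, StageDesign, anova_de_filter

    rng = np.random.default_rng(seed)
    names, records = [], []
    for day in range(n_days):
        for rep in range(1, n_replicates + 1):
            names.append(f"s_d{day}_r{rep}")
            records.append(("A", day, rep))
    values = pd.DataFrame(rng.normal(size=(n_genes, len(names))),
                          index=[f"g{i}" for i in range(n_genes)], columns=names)
    annotations = pd.DataFrame(records, index=names,
                               columns=["condition", "day", "replicate"])
    matrix = ExpressionMatrix(values, annotations)
    design = StageDesign("null", tuple(("A", d) for d in range(n_days)))
    table = anova_de_filter(matrix, design, fdr_threshold)
    return {"n_genes": n_genes,
            "n_selected": int(table["selected"].sum()),
            "selected_fraction": float(table["selected"].mean())}


def aic_oracle_study(n_instances: int = 100, max_neighbors: int = 6,
                     seed: int = 0) -> dict:
    """Greedy backward elimination vs exhaustive minimum-AIC search.

    Each instance is one target with 3-6 candidate neighbours (a mix of true
    and decoy edges) fitted from a noisy record; the study counts how often
    greedy attains the exhaustive optimum and how often it is within 2 AIC
    units of it.
    """
    rng = np.random.default_rng(seed)
    exact = within2 = 0
    for k in range(n_instances):
        inst_seed = seed + 1000 + k
        truth = make_ground_truth(n_genes=8, n_true_edges=8, noise_sd=0.05,
                                  edge_presence=0.8, seed=inst_seed)
        candidates = generate_candidate_network(truth, 1.0, seed=inst_seed + 1)
        profile, x_profile = simulate_unit_grid_dataset(
            truth, RECOVERY_STAGE, RECOVERY_STEPS,
            n_replicates=RECOVERY_REPLICATES,
            rng=np.random.default_rng(inst_seed + 2))
        # the largest neighbourhood that is fully contained within Q_max,
        # so the candidate model class always nests the truth
        nbrs: dict[str, list[str]] = {g: [] for g in truth.genes}
        for a, b in candidates:
            nbrs[a].append(b)
            nbrs[b].append(a)
        eligible = [g for g in truth.genes if 3 <= len(nbrs[g]) <= max_neighbors]
        if not eligible:
            continue
        target = max(eligible, key=lambda g: (len(nbrs[g]), g))
        neighbors = sorted(nbrs[target])
        problem = build_regression_problem(profile.values, target, neighbors,
                                           x=x_profile.values)
        best = prune_by_aic(problem, FitConfig(strategy="exhaustive"))
        greedy = prune_by_aic(problem, FitConfig(strategy="greedy-backward"))
        if abs(greedy.aic - best.aic) < 1e-9:
            exact += 1
            within2 += 1
        elif greedy.aic - best.aic <= 2.0:
            within2 += 1
    return {"n_instances": n_instances, "exact_matches": exact,
            "within_2_aic": within2}
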