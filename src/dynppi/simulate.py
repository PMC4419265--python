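"""Synthetic staged differentiation data with known interaction networks.

The generator draws ground-truth stage networks and simulates the discrete
bilinear protein dynamics

    z_p[t+1] = z_p[t] + sum_q b_pq z_p[t] z_q[t] + a_p x_p[t] - B_p z_p[t] + w_p[t+1]

where b_pq is the interaction activity of neighbour q on target p, x_p is the
mRNA level driving translation with effect a_p, B_p is the degradation rate
and w is process noise.  Every quantity downstream inference estimates is
known here, so recovery can be measured exactly.

Design choices that make the instances behave like differentiation time
courses: mRNA driver curves swing by multi-fold amounts (as DE genes do
during differentiation), the translation effect is coupled to degradation so
protein levels track the mRNA scale, and per-target interaction budgets are
capped below the degradation capacity so the bilinear recurrence stays
dissipative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import (DEFAULT_CONDITIONS, DEFAULT_DAYS, ExpressionMatrix,
                         StageProfile)

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("I", "II", "III")

# magnitude range of nonzero interaction activities
B_RANGE = (0.001, 0.05)
BETA_RANGE = (0.2, 0.5)
ALPHA_BETA_RATIO = (0.7, 1.3)
MRNA_BASELINE = (1.2, 1.8)
MRNA_AMPLITUDE = (0.6, 1.2)
MRNA_PERIOD = (8.0, 24.0)
#: per-target stability budget: sum_q |b_pq| <= STABILITY_FRACTION * beta_p
STABILITY_FRACTION = 0.5

DIVERGENCE_LIMIT = 1e6


class SimulationDiverged(RuntimeError):
    """The bilinear recurrence left the bounded regime."""


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """True stage networks and kinetic parameters for a simulated cohort."""

    genes: list[str]
    stage_networks: dict[str, np.ndarray]  # stage -> dense (n, n), b[p, q]
    translation_effects: np.ndarray        # alpha, per gene
    degradation_rates: np.ndarray          # beta, per gene
    noise_sd: float
    candidate_edges: list[tuple[str, str]]  # undirected, lexicographic pairs
    seed: int | None
    mrna_baseline: np.ndarray = field(default=None)
    mrna_amplitude: np.ndarray = field(default=None)
    mrna_period: np.ndarray = field(default=None)
    mrna_phase: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.genes)
        beta = np.asarray(self.degradation_rates, dtype=float)
        if beta.shape != (n,) or np.any(beta < 0) or np.any(beta > 1):
            raise ValueError("degradation rates must be per-gene values in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        cand = {tuple(sorted(e)) for e in self.candidate_edges}
        idx = self.gene_index
        for stage, b in self.stage_networks.items():
            if b.shape != (n, n):
                raise ValueError(f"stage {stage}: network must be {n}x{n}")
            for p, q in zip(*np.nonzero(b)):
                pair = tuple(sorted((self.genes[p], self.genes[q])))
                if pair not in cand:
                    raise ValueError(
                        f"stage {stage}: true edge {pair} missing from candidates")
        del idx

    @property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def true_directed(self, stage: str) -> set[tuple[str, str]]:
        """Directed (target, neighbour) pairs with nonzero activity in a stage."""
        b = self.stage_networks[stage]
        return {(self.genes[p], self.genes[q]) for p, q in zip(*np.nonzero(b))}

    def true_edges(self) -> set[tuple[str, str]]:
        """Undirected pairs active in at least one stage."""
        out: set[tuple[str, str]] = set()
        for stage in self.stage_networks:
            for p, q in self.true_directed(stage):
                out.add(tuple(sorted((p, q))))
        return out


def make_ground_truth(n_genes: int = 20, n_true_edges: int = 25,
                      stage_labels=DEFAULT_STAGES, noise_sd: float = 0.05,
                      edge_presence: float = 0.8,
                      seed: int | None = 0) -> GroundTruth:
    """Draw a random ground truth with stage-rewired interaction activities.

    Each undirected true edge is active per stage with probability
    ``edge_presence`` (forced active in at least one stage) and, when active,
    carries independently drawn activities for its two directed roles.
    Draws are screened for dissipativity: the bilinear recurrence is only a
    meaningful data-generating process in its bounded regime, so parameter
    sets whose probe trajectories leave it are redrawn.
    """
    rng = np.random.default_rng(seed)
    for _ in range(50):
        truth = _draw_ground_truth(n_genes, n_true_edges, stage_labels,
                                   noise_sd, edge_presence, seed, rng)
        if _is_dissipative(truth, rng):
            return truth
    raise RuntimeError("could not draw a bounded ground truth in 50 attempts")


def _is_dissipative(truth: GroundTruth, rng: np.random.Generator,
                    n_steps: int = 160, bound: float = 8.0) -> bool:
    """Probe every stage's dynamics for boundedness, with noise headroom."""
    times = np.arange(n_steps + 1, dtype=float)
    x = mrna_profiles(truth, times)
    z0 = equilibrium_z0(truth)
    probe_sd = max(2.0 * truth.noise_sd, 0.05)
    for stage in truth.stage_networks:
        try:
            traj = simulate_dynamics(truth, stage, n_steps, z0, x=x,
                                     noise_sd=probe_sd, rng=rng)
        except SimulationDiverged:
            return False
        if np.abs(traj).max() > bound:
            return False
    return True


def _draw_ground_truth(n_genes, n_true_edges, stage_labels, noise_sd,
                       edge_presence, seed, rng) -> GroundTruth:
    max_edges = n_genes * (n_genes - 1) // 2
    if n_true_edges > max_edges:
        raise ValueError("more true edges requested than gene pairs available")
    genes = [f"G{i:03d}" for i in range(n_genes)]

    all_pairs = [(i, j) for i in range(n_genes) for j in range(i + 1, n_genes)]
    chosen = rng.choice(len(all_pairs), size=n_true_edges, replace=False)
    edges = [all_pairs[k] for k in sorted(chosen)]

    beta = rng.uniform(*BETA_RANGE, size=n_genes)
    alpha = beta * rng.uniform(*ALPHA_BETA_RATIO, size=n_genes)

    networks: dict[str, np.ndarray] = {s: np.zeros((n_genes, n_genes)) for s in stage_labels}
    for (i, j) in edges:
        active = rng.random(len(stage_labels)) < edge_presence
        if not active.any():
            active[rng.integers(len(stage_labels))] = True
        for stage, is_active in zip(stage_labels, active):
            if not is_active:
                continue
            for p, q in ((i, j), (j, i)):
                sign = rng.choice([-1.0, 1.0])
                networks[stage][p, q] = sign * rng.uniform(*B_RANGE)

    # dissipativity: cap each target's total interaction budget
    for b in networks.values():
        row_sums = np.abs(b).sum(axis=1)
        cap = STABILITY_FRACTION * beta
        scale = np.where(row_sums > cap, cap / np.maximum(row_sums, 1e-300), 1.0)
        b *= scale[:, None]

    return GroundTruth(
        genes=genes,
        stage_networks=networks,
        translation_effects=alpha,
        degradation_rates=beta,
        noise_sd=noise_sd,
        candidate_edges=[(genes[i], genes[j]) for i, j in edges],
        seed=None if seed is None else int(seed),
        mrna_baseline=rng.uniform(*MRNA_BASELINE, size=n_genes),
        mrna_amplitude=rng.uniform(*MRNA_AMPLITUDE, size=n_genes),
        mrna_period=rng.uniform(*MRNA_PERIOD, size=n_genes),
        mrna_phase=rng.uniform(0.0, 2 * np.pi, size=n_genes),
    )


def mrna_profiles(truth: GroundTruth, times: np.ndarray) -> np.ndarray:
    """Deterministic per-gene mRNA driver curves, shape (n_genes, len(times))."""
    t = np.asarray(times, dtype=float)[None, :]
    x = (truth.mrna_baseline[:, None]
         + truth.mrna_amplitude[:, None]
         * np.sin(2 * np.pi * t / truth.mrna_period[:, None]
                  + truth.mrna_phase[:, None]))
    return np.maximum(x, 0.05)


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def _step(z, b, alpha, beta, x_t, w):
    return z + z * (b @ z) + alpha * x_t - beta * z + w


def simulate_dynamics(truth: GroundTruth, stage: str, n_steps: int,
                      z0: np.ndarray, x: np.ndarray | None = None,
                      noise_sd: float | None = None,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Iterate the bilinear recurrence for ``n_steps`` steps.

    ``x`` supplies the mRNA input series, shape (n_genes, >= n_steps).  When
    omitted, the model's default substitution is used: x equals the noiseless
    latent trajectory of z itself.  Returns shape (n_genes, n_steps + 1).
    """
    if stage not in truth.stage_networks:
        raise KeyError(f"unknown stage {stage!r}")
    z0 = np.asarray(z0, dtype=float)
    if not np.all(np.isfinite(z0)):
        raise ValueError("z0 must be finite")
    sd = truth.noise_sd if noise_sd is None else noise_sd
    if sd > 0 and rng is None:
        if truth.seed is None:
            raise ValueError("noise_sd > 0 requires a seed or an explicit rng")
        rng = np.random.default_rng(truth.seed)

    b = truth.stage_networks[stage]
    alpha = truth.translation_effects
    beta = truth.degradation_rates
    n = len(truth.genes)

    if x is None:
        # noiseless latent path, self-consistent x := z
        latent = np.empty((n, n_steps + 1))
        latent[:, 0] = z0
        for t in range(n_steps):
            latent[:, t + 1] = _step(latent[:, t], b, alpha, beta, latent[:, t], 0.0)
            _check_finite(latent[:, t + 1], truth.genes, t + 1)
        x = latent[:, :n_steps]
    else:
        x = np.asarray(x, dtype=float)
        if x.shape[0] != n or x.shape[1] < n_steps:
            raise ValueError(f"x must have shape (n_genes, >= {n_steps})")

    traj = np.empty((n, n_steps + 1))
    traj[:, 0] = z0
    for t in range(n_steps):
        w = rng.normal(0.0, sd, size=n) if sd > 0 else 0.0
        traj[:, t + 1] = _step(traj[:, t], b, alpha, beta, x[:, t], w)
        _check_finite(traj[:, t + 1], truth.genes, t + 1)
    return traj


def _check_finite(z: np.ndarray, genes: list[str], step: int) -> None:
    bad = ~np.isfinite(z) | (np.abs(z) > DIVERGENCE_LIMIT)
    if bad.any():
        gene = genes[int(np.flatnonzero(bad)[0])]
        raise SimulationDiverged(
            f"trajectory diverged at step {step} for gene {gene}")


def equilibrium_z0(truth: GroundTruth) -> np.ndarray:
    """Protein level balancing translation and degradation at the initial mRNA."""
    x0 = mrna_profiles(truth, np.array([0.0]))[:, 0]
    return truth.translation_effects * x0 / truth.degradation_rates


def simulate_unit_grid_dataset(truth: GroundTruth, stage: str, n_steps: int,
                               x_mode: str = "exogenous",
                               n_replicates: int = 1,
                               rng: np.random.Generator | None = None,
                               ) -> tuple[StageProfile, StageProfile | None]:
    """Trajectories sampled at every step; days are the step indices.

    With ``x_mode='exogenous'`` the mRNA driver curves are used as input and
    returned as a second profile (the fully identifiable regime); with
    ``'latent'`` the model's mRNA-as-protein substitution is simulated and no
    x profile is returned.  ``n_replicates`` independent trajectories
    (replicate dishes, independent process-noise realisations) are averaged,
    mirroring the pipeline's replicate averaging on real data.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    times = np.arange(n_steps + 1, dtype=float)
    z0 = equilibrium_z0(truth)
    if x_mode == "exogenous":
        x = mrna_profiles(truth, times)
        x_profile = StageProfile(stage, pd.DataFrame(x, index=truth.genes, columns=times))
    elif x_mode == "latent":
        x = None
        x_profile = None
    else:
        raise ValueError("x_mode must be 'exogenous' or 'latent'")
    if truth.noise_sd > 0 and rng is None:
        if truth.seed is None:
            raise ValueError("noisy simulation requires a seed or an explicit rng")
        rng = np.random.default_rng(truth.seed)
    reps = [simulate_dynamics(truth, stage, n_steps, z0, x=x, rng=rng)
            for _ in range(n_replicates)]
    traj = np.mean(reps, axis=0)
    profile = StageProfile(stage, pd.DataFrame(traj, index=truth.genes, columns=times))
    return profile, x_profile


# ---------------------------------------------------------------------------
# Full factorial dataset in the reference design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedDesign:
    """Sampling layout emulating the reference experiment."""

    conditions: tuple[str, str, str] = DEFAULT_CONDITIONS
    days: tuple[int, ...] = DEFAULT_DAYS
    replicates_per_timepoint: int = 3

    def __post_init__(self) -> None:
        if self.days[0] != 0 or any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must strictly increase starting at 0")
        if self.replicates_per_timepoint < 1:
            raise ValueError("replicates_per_timepoint must be >= 1")


def _condition_schedule(conditions, stages) -> dict[str, list[tuple[int, str]]]:
    """Day at which each condition's dynamics switch stage networks.

    The first condition runs stage-1 dynamics throughout; the second switches
    to stage-2 dynamics at day 1; the third additionally switches to stage-3
    dynamics at day 3 (the days the media are changed).
    """
    c1, c2, c3 = conditions
    s1, s2, s3 = stages
    return {
        c1: [(0, s1)],
        c2: [(0, s1), (1, s2)],
        c3: [(0, s1), (1, s2), (3, s3)],
    }


def generate_dataset(truth: GroundTruth, design: SimulatedDesign,
                     obs_noise_sd: float = 0.05,
                     x_mode: str = "latent") -> ExpressionMatrix:
    """Simulate the full conditions x days x replicates expression matrix.

    Each condition follows one latent unit-step trajectory whose dynamics
    switch stage networks at the media-change days; replicates are the
    sampled latent values plus independent Gaussian observation noise.
    """
    if truth.seed is None and (truth.noise_sd > 0 or obs_noise_sd > 0):
        raise ValueError("noisy simulation requires GroundTruth.seed to be set")
    rng = np.random.default_rng(truth.seed)
    stages = list(truth.stage_networks)
    if len(stages) != len(DEFAULT_STAGES):
        raise ValueError("reference design needs exactly three stage networks")
    schedule = _condition_schedule(design.conditions, stages)

    n = len(truth.genes)
    total_steps = max(design.days)
    times = np.arange(total_steps + 1, dtype=float)
    x_all = mrna_profiles(truth, times) if x_mode == "exogenous" else None

    columns, names, records = [], [], []
    for condition in design.conditions:
        switches = schedule[condition]
        traj = np.empty((n, total_steps + 1))
        traj[:, 0] = equilibrium_z0(truth)
        # piecewise simulation, one segment per active stage network
        for k, (start, stage) in enumerate(switches):
            end = switches[k + 1][0] if k + 1 < len(switches) else total_steps
            if end <= start:
                continue
            seg = simulate_dynamics(
                truth, stage, end - start, traj[:, start],
                x=None if x_all is None else x_all[:, start:end],
                rng=rng)
            traj[:, start:end + 1] = seg
        for day in design.days:
            latent = traj[:, day]
            for rep in range(1, design.replicates_per_timepoint + 1):
                noise = rng.normal(0.0, obs_noise_sd, size=n) if obs_noise_sd > 0 else 0.0
                columns.append(latent + noise)
                names.append(f"{condition.replace('/', '.')}_d{day}_r{rep}")
                records.append((condition, day, rep))

    values = pd.DataFrame(np.column_stack(columns), index=truth.genes, columns=names)
    annotations = pd.DataFrame(records, index=names,
                               columns=["condition", "day", "replicate"])
    return ExpressionMatrix(values, annotations)


# ---------------------------------------------------------------------------
# Candidate network with decoys
# ---------------------------------------------------------------------------

def generate_candidate_network(truth: GroundTruth, decoy_ratio: float,
                               seed: int | None = None) -> list[tuple[str, str]]:
    """True edges plus ``round(decoy_ratio * n_true)`` decoy pairs (b = 0)."""
    if decoy_ratio < 0:
        raise ValueError("decoy_ratio must be >= 0")
    true = sorted(truth.true_edges())
    n_decoys = round(decoy_ratio * len(true))
    if n_decoys == 0:
        return true
    genes = truth.genes
    true_set = set(true)
    non_true = [(genes[i], genes[j])
                for i in range(len(genes)) for j in range(i + 1, len(genes))
                if (genes[i], genes[j]) not in true_set]
    if n_decoys > len(non_true):
        raise ValueError(
            f"requested {n_decoys} decoys but only {len(non_true)} non-true pairs exist")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    picked = rng.choice(len(non_true), size=n_decoys, replace=False)
    decoys = [non_true[k] for k in sorted(picked)]
    return sorted(true + decoys)
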