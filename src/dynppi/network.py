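"""Stage network identification: spline interpolation, least squares, AIC pruning.

For each target gene p with candidate neighbours q = 1..Q the one-step model

    z_p[t+1] = z_p[t] z_1[t] b_p1 + ... + z_p[t] z_Q[t] b_pQ + x_p[t] a_p + z_p[t] (1 - B_p)

is solved by ordinary least squares over L interpolated pseudo-time steps,
after cubic-spline interpolation of the stage profile onto a common grid.
Candidate interactions are then pruned by minimising AIC over interaction
subsets (exhaustively for small neighbourhoods, by greedy backward
elimination otherwise); the mRNA and self terms are never pruned.

Identifiability note: when no separate mRNA series is available the field
practice is to use the observed expression series as both x_p and z_p.  The
two design columns are then identical, so the translation effect a_p and the
retention factor 1 - B_p cannot be separated; this module merges them into a
single self-column whose coefficient is the net self-effect 1 + a_p - B_p
(reported through ``beta`` with ``alpha`` fixed at 0).  Interaction
activities b_pq, the only quantities used downstream, are unaffected.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.sparse import csr_matrix, lil_matrix

from .preprocess import StageProfile

logger = logging.getLogger(__name__)


class RankDeficientDesign(ValueError):
    """The regression design matrix does not have full column rank."""


@dataclass
class FitConfig:
    """Tunables of the network identification step."""

    l_multiplier: float = 4.0        # L = ceil(multiplier * (Q + 2)), in [3, 5]
    aic_variant: str = "aic"         # "aic" or "aicc"
    strategy: str = "auto"           # "auto", "exhaustive", "greedy-backward"
    exhaustive_limit: int = 8        # exhaustive search up to this many neighbours
    symmetrize: bool = False         # average b_pq and b_qp after fitting
    edge_floor: float = 1e-12        # |b| below this is numerical zero
    rss_floor_rel: float = 1e-16     # RSS floor relative to ||Z||^2 in AIC


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------

def choose_L(n_neighbors: int, multiplier: float = 4.0) -> int:
    """Number of regression rows: 3-5 times the parameter count Q + 2."""
    if not (3.0 <= multiplier <= 5.0):
        raise ValueError("multiplier must be within [3, 5]")
    return math.ceil(multiplier * (n_neighbors + 2))


def interpolate_profile(profile: StageProfile, n_points: int) -> StageProfile:
    """Natural cubic spline onto ``n_points`` evenly spaced pseudo-times.

    Knot values are reproduced whenever a pseudo-time coincides with an
    original day; if the requested grid equals the original day grid the
    profile is returned unchanged.
    """
    days = profile.days
    if len(days) < 4:
        raise ValueError("cubic spline interpolation needs >= 4 time points")
    if n_points < len(days):
        raise ValueError(
            f"n_points ({n_points}) must be >= number of original points ({len(days)})")
    grid = np.linspace(days[0], days[-1], n_points)
    if n_points == len(days) and np.allclose(grid, days):
        return StageProfile(profile.stage_label, profile.values.copy())
    spline = CubicSpline(days, profile.values.to_numpy(dtype=float),
                         axis=1, bc_type="natural")
    values = pd.DataFrame(spline(grid), index=profile.values.index, columns=grid)
    return StageProfile(profile.stage_label, values)


# ---------------------------------------------------------------------------
# Per-target regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionProblem:
    """One target's least-squares system over L pseudo-time transitions."""

    target: str
    neighbors: list[str]
    response: np.ndarray      # (L,)  = z_p at steps 1..L
    design: np.ndarray        # (L, Q + 2) exogenous x, or (L, Q + 1) proxy
    has_x: bool               # True when a distinct mRNA column is present
    L: int

    @property
    def n_neighbors(self) -> int:
        return len(self.neighbors)


def build_regression_problem(z: pd.DataFrame, target: str, neighbors: list[str],
                             x: pd.DataFrame | None = None) -> RegressionProblem:
    """Assemble response and design rows from interpolated series.

    ``z`` (and optionally ``x``) are gene x pseudo-time frames with T columns;
    the system uses the T - 1 transitions between consecutive grid points.
    """
    zp = z.loc[target].to_numpy(dtype=float)
    L = len(zp) - 1
    cols = [zp[:-1] * z.loc[q].to_numpy(dtype=float)[:-1] for q in neighbors]
    if x is not None:
        xp = x.loc[target].to_numpy(dtype=float)
        cols.append(xp[:L])
    cols.append(zp[:-1])
    design = np.column_stack(cols)
    return RegressionProblem(target=target, neighbors=list(neighbors),
                             response=zp[1:], design=design,
                             has_x=x is not None, L=L)


@dataclass
class TargetModelFit:
    """OLS estimates for one target after (optional) AIC pruning."""

    target: str
    neighbors: list[str]           # retained neighbours
    b: dict[str, float]
    alpha: float
    beta: float
    rss: float
    aic: float
    L: int
    k: int

    def __post_init__(self) -> None:
        if not (self.rss >= 0 and np.isfinite(self.aic)):
            raise ValueError("invalid fit: rss must be >= 0 and aic finite")


def _solve(problem: RegressionProblem, subset: tuple[int, ...],
           rss_floor: float, aic_variant: str) -> TargetModelFit:
    """OLS on the interaction columns in ``subset`` plus the fixed tail columns."""
    n_fixed = 2 if problem.has_x else 1
    q_total = problem.n_neighbors
    cols = list(subset) + list(range(q_total, q_total + n_fixed))
    design = problem.design[:, cols]
    theta, residuals, rank, _ = np.linalg.lstsq(design, problem.response, rcond=None)
    if rank < design.shape[1]:
        raise RankDeficientDesign(
            f"target {problem.target}: design rank {rank} < {design.shape[1]} "
            f"(collinear columns)")
    resid = problem.response - design @ theta
    rss = float(resid @ resid)
    k = design.shape[1]
    aic = aic_score(rss, problem.L, k, variant=aic_variant, rss_floor=rss_floor)
    names = [problem.neighbors[i] for i in subset]
    if problem.has_x:
        alpha = float(theta[-2])
        beta = 1.0 - float(theta[-1])
    else:
        alpha = 0.0
        beta = 1.0 - float(theta[-1])  # net self-effect; see module docstring
    return TargetModelFit(target=problem.target, neighbors=names,
                          b={n: float(v) for n, v in zip(names, theta)},
                          alpha=alpha, beta=beta, rss=rss, aic=aic,
                          L=problem.L, k=k)


def fit_target(problem: RegressionProblem,
               aic_variant: str = "aic", rss_floor: float = 0.0) -> TargetModelFit:
    """Full-model OLS fit (no pruning); raises on rank-deficient designs."""
    return _solve(problem, tuple(range(problem.n_neighbors)), rss_floor, aic_variant)


def aic_score(rss: float, L: int, k: int, variant: str = "aic",
              rss_floor: float = 0.0) -> float:
    """AIC = L ln(rss / L) + 2k, with rss floored to avoid -inf.

    ``variant='aicc'`` adds the small-sample correction 2k(k+1)/(L-k-1).
    """
    if rss < 0 or L <= 0 or k < 0:
        raise ValueError("need rss >= 0, L > 0, k >= 0")
    floored = max(rss, rss_floor, np.finfo(float).tiny)
    value = L * math.log(floored / L) + 2 * k
    if variant == "aicc":
        if L - k - 1 <= 0:
            raise ValueError("AICc undefined for L <= k + 1")
        value += 2.0 * k * (k + 1) / (L - k - 1)
    elif variant != "aic":
        raise ValueError(f"unknown AIC variant {variant!r}")
    return value


# ---------------------------------------------------------------------------
# AIC pruning
# ---------------------------------------------------------------------------

def _rss_floor_for(problem: RegressionProblem, config: FitConfig) -> float:
    scale = float(problem.response @ problem.response)
    return config.rss_floor_rel * max(1.0, scale)


def prune_by_aic(problem: RegressionProblem,
                 config: FitConfig | None = None) -> TargetModelFit:
    """Minimum-AIC interaction subset for one target.

    Exhaustive enumeration of all 2^Q subsets when Q <= ``exhaustive_limit``,
    greedy backward elimination otherwise (``strategy`` can force either).
    The mRNA and self terms are always retained.  Ties favour the smaller
    model, then the lexicographically first neighbour subset.
    """
    config = config or FitConfig()
    floor = _rss_floor_for(problem, config)
    strategy = config.strategy
    if strategy == "auto":
        strategy = ("exhaustive" if problem.n_neighbors <= config.exhaustive_limit
                    else "greedy-backward")
    if strategy == "exhaustive":
        return _prune_exhaustive(problem, config, floor)
    if strategy == "greedy-backward":
        return _prune_greedy(problem, config, floor)
    raise ValueError(f"unknown pruning strategy {strategy!r}")


def _prune_exhaustive(problem, config, floor) -> TargetModelFit:
    best = None
    best_key = None
    skipped = 0
    indices = range(problem.n_neighbors)
    for size in range(problem.n_neighbors + 1):
        for subset in itertools.combinations(indices, size):
            try:
                fit = _solve(problem, subset, floor, config.aic_variant)
            except RankDeficientDesign:
                skipped += 1
                continue
            key = (fit.aic, len(subset), tuple(fit.neighbors))
            if best_key is None or key < best_key:
                best, best_key = fit, key
    if skipped:
        logger.info("target %s: skipped %d rank-deficient subset(s)",
                    problem.target, skipped)
    if best is None:
        raise RankDeficientDesign(
            f"target {problem.target}: every interaction subset was rank-deficient")
    return best


def _prune_greedy(problem, config, floor) -> TargetModelFit:
    current_subset = tuple(range(problem.n_neighbors))
    current = _solve(problem, current_subset, floor, config.aic_variant)
    while current_subset:
        best_candidate = None
        best_key = None
        for drop in current_subset:
            subset = tuple(i for i in current_subset if i != drop)
            try:
                fit = _solve(problem, subset, floor, config.aic_variant)
            except RankDeficientDesign:
                continue
            key = (fit.aic, tuple(fit.neighbors))
            if best_key is None or key < best_key:
                best_candidate, best_key = (subset, fit), key
        if best_candidate is None or best_candidate[1].aic >= current.aic:
            break
        current_subset, current = best_candidate
    return current


# ---------------------------------------------------------------------------
# Whole-stage construction
# ---------------------------------------------------------------------------

@dataclass
class StageNetwork:
    """Identified interaction activities b_pq for one stage, sparse over genes."""

    stage_label: str
    genes: list[str]
    b: csr_matrix                       # (n, n), row = target p, col = neighbour q
    fits: dict[str, TargetModelFit] = field(default_factory=dict)
    failed_targets: list[str] = field(default_factory=list)

    @property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def edge_frame(self) -> pd.DataFrame:
        coo = self.b.tocoo()
        frame = pd.DataFrame({
            "source": [self.genes[i] for i in coo.row],
            "target": [self.genes[j] for j in coo.col],
            "b": coo.data,
            "stage": self.stage_label,
        })
        return frame.sort_values(["source", "target"], ignore_index=True)

    def directed_pairs(self) -> set[tuple[str, str]]:
        coo = self.b.tocoo()
        return {(self.genes[i], self.genes[j]) for i, j in zip(coo.row, coo.col)}

    def n_edges(self) -> int:
        """Undirected edge count (either directed role present)."""
        coo = self.b.tocoo()
        return len({tuple(sorted((self.genes[i], self.genes[j])))
                    for i, j in zip(coo.row, coo.col)})

    def n_nodes(self) -> int:
        coo = self.b.tocoo()
        return len({g for i, j in zip(coo.row, coo.col)
                    for g in (self.genes[i], self.genes[j])})


def neighbor_map(candidates, genes) -> dict[str, list[str]]:
    """Undirected candidate edges -> per-gene sorted neighbour lists."""
    gene_set = set(genes)
    nbrs: dict[str, set[str]] = {g: set() for g in genes}
    for a, b in candidates:
        if a == b or a not in gene_set or b not in gene_set:
            continue
        nbrs[a].add(b)
        nbrs[b].add(a)
    return {g: sorted(v) for g, v in nbrs.items()}


def construct_stage_network(profile: StageProfile, candidates,
                            config: FitConfig | None = None,
                            x_profile: StageProfile | None = None) -> StageNetwork:
    """Identify one stage's network over the profile's gene set.

    Every gene with at least one candidate neighbour inside the profile is
    fitted and pruned; genes whose designs are rank deficient are recorded in
    ``failed_targets`` and left isolated.  A shared pseudo-time grid is used
    for all targets (the model multiplies series pointwise).
    """
    config = config or FitConfig()
    genes = profile.genes
    if len(genes) == 0:
        raise ValueError("stage profile has no genes")
    nbrs = neighbor_map(candidates, genes)
    q_max = max((len(v) for v in nbrs.values()), default=0)
    n = len(genes)
    if q_max == 0:
        logger.warning("stage %s: no candidate edges within the gene set; "
                       "returning an empty network", profile.stage_label)
        return StageNetwork(profile.stage_label, genes, csr_matrix((n, n)))

    L = choose_L(q_max, config.l_multiplier)
    n_points = max(L + 1, len(profile.days))
    z = interpolate_profile(profile, n_points).values
    x = None
    if x_profile is not None:
        x = interpolate_profile(x_profile, n_points).values

    mat = lil_matrix((n, n))
    index = {g: i for i, g in enumerate(genes)}
    fits: dict[str, TargetModelFit] = {}
    failed: list[str] = []
    for target in genes:
        if not nbrs[target]:
            continue
        problem = build_regression_problem(z, target, nbrs[target], x=x)
        try:
            fit = prune_by_aic(problem, config)
        except RankDeficientDesign as exc:
            logger.warning("dropping target %s: %s", target, exc)
            failed.append(target)
            continue
        fits[target] = fit
        for q_name, value in fit.b.items():
            if abs(value) > config.edge_floor:
                mat[index[target], index[q_name]] = value

    b = mat.tocsr()
    if config.symmetrize:
        b = (b + b.T) / 2.0
    return StageNetwork(profile.stage_label, genes, b, fits, failed)


def edge_recovery(truth_directed: set[tuple[str, str]],
                  network: StageNetwork) -> dict[str, float]:
    """Precision/recall of the identified directed interactions."""
    estimated = network.directed_pairs()
    tp = len(estimated & truth_directed)
    precision = tp / len(estimated) if estimated else 0.0
    recall = tp / len(truth_directed) if truth_directed else 1.0
    return {"precision": precision, "recall": recall,
            "n_estimated": len(estimated), "n_true": len(truth_directed)}
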