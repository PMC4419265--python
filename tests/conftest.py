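import numpy as np
import pandas as pd
import pytest

from dynppi.network import StageNetwork
from dynppi.preprocess import ExpressionMatrix
from dynppi.simulate import DEFAULT_STAGES, GroundTruth
from scipy.sparse import csr_matrix


def manual_truth(genes, edges_b, alpha=0.0, beta=0.0, noise_sd=0.0, seed=0,
                 stages=DEFAULT_STAGES):
    """GroundTruth with explicit per-stage activities.

    ``edges_b`` maps stage -> {(p, q): b_pq} (directed); candidate edges are
    the undirected closure of all directed pairs.
    """
    n = len(genes)
    index = {g: i for i, g in enumerate(genes)}
    networks = {}
    candidates = set()
    for stage in stages:
        b = np.zeros((n, n))
        for (p, q), value in edges_b.get(stage, {}).items():
            b[index[p], index[q]] = value
            candidates.add(tuple(sorted((p, q))))
        networks[stage] = b
    rng = np.random.default_rng(seed)
    return GroundTruth(
        genes=list(genes),
        stage_networks=networks,
        translation_effects=np.full(n, float(alpha)),
        degradation_rates=np.full(n, float(beta)),
        noise_sd=noise_sd,
        candidate_edges=sorted(candidates),
        seed=seed,
        mrna_baseline=rng.uniform(1.2, 1.8, n),
        mrna_amplitude=rng.uniform(0.6, 1.2, n),
        mrna_period=rng.uniform(8.0, 24.0, n),
        mrna_phase=rng.uniform(0.0, 2 * np.pi, n),
    )


def network_from_dict(stage, genes, entries) -> StageNetwork:
    """StageNetwork from {(p, q): b} directed entries."""
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    mat = np.zeros((n, n))
    for (p, q), value in entries.items():
        mat[index[p], index[q]] = value
    return StageNetwork(stage, list(genes), csr_matrix(mat))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """2 genes x (2 conditions x 2 days x 2 replicates) annotated matrix."""
    names, records, cols = [], [], []
    value = 1.0
    for cond in ("A", "B"):
        for day in (0, 1):
            for rep in (1, 2):
                names.append(f"{cond}_d{day}_r{rep}")
                records.append((cond, day, rep))
                cols.append([value, value * 10])
                value += 1.0
    values = pd.DataFrame(np.array(cols).T, index=["g1", "g2"], columns=names)
    ann = pd.DataFrame(records, index=names,
                       columns=["condition", "day", "replicate"])
    return ExpressionMatrix(values, ann)
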