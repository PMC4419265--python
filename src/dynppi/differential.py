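"""Interaction difference networks (IDNs) and relevance scores.

The IDN between two stages is the entrywise difference of their interaction
matrices, D = B(s2) - B(s1), taken over the union gene set (an interaction or
gene absent from a stage contributes 0).  Each changed edge is classified by
direction (enhancing if the activity increased, attenuating if it decreased)
and existence (emerged / diminished / coexisting), and likewise each node.

The relevance score of a protein is the mean absolute activity change over
its changed interactions,

    RS_p = sum_q |d_pq| / degree(p),

where degree(p) counts the nonzero entries of row p of D; RS_p = 0 when the
row is all zeros.  Absolute values are used so that opposite-sign changes
cannot cancel: the score measures the magnitude of rewiring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix, lil_matrix

from .network import StageNetwork

logger = logging.getLogger(__name__)

ENHANCING = "enhancing"
ATTENUATING = "attenuating"
NO_DIRECTION = "none"
EMERGED = "emerged"
DIMINISHED = "diminished"
COEXISTING = "coexisting"


@dataclass
class IDN:
    """Interaction difference network between two stages."""

    from_stage: str
    to_stage: str
    genes: list[str]
    D: csr_matrix                 # (n, n), d_pq = b_pq(to) - b_pq(from)
    edge_labels: pd.DataFrame     # source, target, b_from, b_to, d, direction, existence
    node_labels: pd.Series        # gene -> emerged | diminished | coexisting

    @property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def changed_genes(self) -> list[str]:
        """Genes with at least one nonzero entry in their row or column of D."""
        coo = self.D.tocoo()
        out = {self.genes[i] for i in coo.row} | {self.genes[j] for j in coo.col}
        return sorted(out)


def classify_edge_change(b1: float | None, b2: float | None) -> tuple[str, str]:
    """Direction and existence of one interaction's change between stages.

    ``None`` (or 0) means the interaction is absent in that stage.  The
    direction compares activities with absence read as 0: an interaction
    whose activity increases (e.g. + to ++, 0 to +, - to 0) is enhancing;
    one whose activity decreases (++ to +, + to 0, 0 to -) is attenuating.
    """
    present1 = b1 is not None and b1 != 0
    present2 = b2 is not None and b2 != 0
    if not present1 and not present2:
        raise ValueError("interaction absent in both stages has no change to classify")
    v1 = b1 if present1 else 0.0
    v2 = b2 if present2 else 0.0
    if v2 > v1:
        direction = ENHANCING
    elif v2 < v1:
        direction = ATTENUATING
    else:
        direction = NO_DIRECTION
    if present1 and present2:
        existence = COEXISTING
    elif present2:
        existence = EMERGED
    else:
        existence = DIMINISHED
    return direction, existence


def _embed(net: StageNetwork, genes: list[str]) -> csr_matrix:
    """Re-index a stage matrix onto the union gene list (absent rows are 0)."""
    index = {g: i for i, g in enumerate(genes)}
    coo = net.b.tocoo()
    n = len(genes)
    out = lil_matrix((n, n))
    for i, j, v in zip(coo.row, coo.col, coo.data):
        out[index[net.genes[i]], index[net.genes[j]]] = v
    return out.tocsr()


def compute_idn(net1: StageNetwork, net2: StageNetwork,
                floor: float = 1e-12) -> IDN:
    """D = B(net2) - B(net1) over the union gene set, with change labels."""
    if net1.stage_label == net2.stage_label:
        raise ValueError("IDN requires two distinct stage labels")
    genes = sorted(set(net1.genes) | set(net2.genes))
    b1 = _embed(net1, genes)
    b2 = _embed(net2, genes)
    d = (b2 - b1).tocoo()
    keep = np.abs(d.data) > floor
    D = csr_matrix((d.data[keep], (d.row[keep], d.col[keep])),
                   shape=(len(genes), len(genes)))

    rows = []
    pairs = set(zip(*b1.nonzero())) | set(zip(*b2.nonzero()))
    for i, j in sorted(pairs):
        v1, v2 = b1[i, j], b2[i, j]
        if v1 == v2:
            continue  # unchanged interaction: not part of the difference network
        direction, existence = classify_edge_change(v1 or None, v2 or None)
        rows.append((genes[i], genes[j], float(v1), float(v2),
                     float(v2 - v1), direction, existence))
    edge_labels = pd.DataFrame(
        rows, columns=["source", "target", "b_from", "b_to", "d",
                       "direction", "existence"])

    present1 = _present_nodes(b1, genes)
    present2 = _present_nodes(b2, genes)
    labels = {}
    for g in sorted(present1 | present2):
        if g in present1 and g in present2:
            labels[g] = COEXISTING
        elif g in present2:
            labels[g] = EMERGED
        else:
            labels[g] = DIMINISHED
    node_labels = pd.Series(labels, dtype=object, name="existence")

    return IDN(net1.stage_label, net2.stage_label, genes, D, edge_labels, node_labels)


def _present_nodes(b: csr_matrix, genes: list[str]) -> set[str]:
    coo = b.tocoo()
    return {genes[i] for i in coo.row} | {genes[j] for j in coo.col}


# ---------------------------------------------------------------------------
# Relevance scores
# ---------------------------------------------------------------------------

def relevance_scores(idn: IDN) -> pd.DataFrame:
    """Per-gene relevance score and row degree over the difference matrix."""
    abs_d = abs(idn.D)
    row_sums = np.asarray(abs_d.sum(axis=1)).ravel()
    degrees = np.diff(idn.D.indptr)  # nonzeros per row (csr)
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = np.where(degrees > 0, row_sums / np.maximum(degrees, 1), 0.0)
    return pd.DataFrame({"rs": rs, "degree": degrees}, index=idn.genes)


def relevance_score_protein(idn: IDN, gene: str) -> float:
    """RS_p = sum_q |d_pq| / degree(p) for one protein (0 if the row is empty)."""
    try:
        row = idn.gene_index[gene]
    except KeyError:
        raise KeyError(f"gene {gene!r} not in the IDN") from None
    data = idn.D.getrow(row).data
    if len(data) == 0:
        return 0.0
    return float(np.abs(data).sum() / len(data))


@dataclass
class RelevanceTable:
    """Ranked per-protein relevance scores for one stage transition."""

    from_stage: str
    to_stage: str
    table: pd.DataFrame   # all genes: rank, gene, rs, degree
    top: pd.DataFrame     # first top_n rows


def rank_proteins(idn: IDN, top_n: int = 10) -> RelevanceTable:
    """All genes ranked by RS descending; ties broken by gene name."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    scores = relevance_scores(idn)
    # deterministic tie handling: equal scores in lexicographic gene order
    ordered = (scores.reset_index(names="gene")
               .sort_values(["rs", "gene"], ascending=[False, True],
                            kind="stable", ignore_index=True))
    ordered.insert(0, "rank", np.arange(1, len(ordered) + 1))
    return RelevanceTable(idn.from_stage, idn.to_stage,
                          ordered, ordered.head(top_n).copy())


# ---------------------------------------------------------------------------
# Neighbourhood extraction
# ---------------------------------------------------------------------------

def extract_neighborhood(idn: IDN, seeds, radius: int = 1) -> IDN:
    """Induced sub-IDN of all nodes within ``radius`` hops of any seed.

    Hops follow the undirected graph of nonzero difference entries.  Seeds
    missing from the IDN are skipped with a warning.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    gene_set = set(idn.genes)
    kept_seeds = []
    for s in seeds:
        if s in gene_set:
            kept_seeds.append(s)
        else:
            logger.warning("seed %s not in the IDN; skipped", s)
    graph = nx.Graph()
    graph.add_nodes_from(idn.genes)
    coo = idn.D.tocoo()
    graph.add_edges_from((idn.genes[i], idn.genes[j])
                         for i, j in zip(coo.row, coo.col))
    nodes: set[str] = set()
    for s in kept_seeds:
        nodes |= set(nx.ego_graph(graph, s, radius=radius).nodes)
    return subset_idn(idn, sorted(nodes))


def subset_idn(idn: IDN, genes: list[str]) -> IDN:
    """Restrict an IDN to a gene subset, preserving labels."""
    keep = [g for g in idn.genes if g in set(genes)]
    index = idn.gene_index
    rows = [index[g] for g in keep]
    D = idn.D[rows][:, rows]
    in_keep = set(keep)
    edges = idn.edge_labels[
        idn.edge_labels["source"].isin(in_keep)
        & idn.edge_labels["target"].isin(in_keep)].reset_index(drop=True)
    nodes = idn.node_labels[idn.node_labels.index.isin(in_keep)]
    return IDN(idn.from_stage, idn.to_stage, keep, D.tocsr(), edges, nodes)
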