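"""Readers and writers for the pipeline's plain-text formats.

Expression matrices and annotations travel as tab-separated text; candidate
networks as SIF (``geneA<TAB>pp<TAB>geneB``) or two-column TSV; identified
networks as weighted edge TSV, SIF or GraphML; gene sets as GMT.  Reads and
writes round-trip for the TSV/SIF dialects.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix, lil_matrix

from .differential import IDN, compute_idn
from .modules import GeneSetCollection
from .network import StageNetwork
from .preprocess import ExpressionMatrix, StageProfile

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Expression matrices and profiles
# ---------------------------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, expr_path, annot_path) -> None:
    frame = matrix.values.copy()
    frame.index.name = "gene"
    frame.to_csv(expr_path, sep="\t")
    ann = matrix.annotations.copy()
    ann.index.name = "sampleID"
    ann.to_csv(annot_path, sep="\t")


def read_expression(expr_path, annot_path) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col="gene").rename_axis(None)
    annotations = pd.read_csv(annot_path, sep="\t",
                              index_col="sampleID").rename_axis(None)
    return ExpressionMatrix(values, annotations)


def write_profile(profile: StageProfile, path) -> None:
    frame = profile.values.copy()
    frame.columns = [f"{d:g}" for d in profile.days]
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t")


def read_profile(path, stage_label: str) -> StageProfile:
    frame = pd.read_csv(path, sep="\t", index_col="gene").rename_axis(None)
    frame.columns = [float(c) for c in frame.columns]
    return StageProfile(stage_label, frame)


# ---------------------------------------------------------------------------
# Candidate networks
# ---------------------------------------------------------------------------

def read_candidate_network(path) -> list[tuple[str, str]]:
    """Undirected candidate edges from SIF or 2-column TSV.

    Duplicates (either orientation) and self-loops are dropped with logged
    counts; malformed lines raise with their line number.
    """
    path = Path(path)
    is_sif = path.suffix.lower() == ".sif"
    edges: set[tuple[str, str]] = set()
    duplicates = self_loops = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if is_sif:
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: SIF line needs 3 fields")
                a, b = fields[0], fields[2]
            else:
                if lineno == 1 and {f.lower() for f in fields[:2]} >= {"source", "target"}:
                    continue  # header row
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: edge line needs 2 fields")
                a, b = fields[0], fields[1]
            if a == b:
                self_loops += 1
                continue
            pair = tuple(sorted((a, b)))
            if pair in edges:
                duplicates += 1
            edges.add(pair)
    if duplicates or self_loops:
        logger.info("%s: dropped %d duplicate and %d self-loop edge(s)",
                    path, duplicates, self_loops)
    return sorted(edges)


def write_candidate_sif(edges, path, interaction: str = "pp") -> None:
    with open(path, "w") as handle:
        for a, b in sorted(tuple(sorted(e)) for e in edges):
            handle.write(f"{a}\t{interaction}\t{b}\n")


def write_truth_activities(truth, path) -> None:
    """Ground-truth directed activities per stage, for test oracles."""
    rows = []
    for stage, b in truth.stage_networks.items():
        for p, q in zip(*np.nonzero(b)):
            rows.append((truth.genes[p], truth.genes[q], stage, b[p, q]))
    frame = pd.DataFrame(rows, columns=["source", "target", "stage", "b"])
    frame.sort_values(["stage", "source", "target"], ignore_index=True
                      ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Identified stage networks
# ---------------------------------------------------------------------------

def write_network(net: StageNetwork, path, fmt: str = "tsv") -> None:
    """Weighted edge list as TSV (default), SIF or GraphML."""
    if fmt == "tsv":
        net.edge_frame().to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        write_candidate_sif(net.directed_pairs(), path)
    elif fmt == "graphml":
        nx.write_graphml(_to_graph(net), path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def _to_graph(net: StageNetwork) -> nx.DiGraph:
    graph = nx.DiGraph(stage=net.stage_label)
    graph.add_nodes_from(net.genes)
    frame = net.edge_frame()
    for row in frame.itertuples(index=False):
        graph.add_edge(row.source, row.target, b=float(row.b))
    return graph


def read_network(path, stage_label: str | None = None,
                 genes=None) -> StageNetwork:
    """Rebuild a StageNetwork from a weighted edge TSV."""
    frame = pd.read_csv(path, sep="\t")
    if stage_label is None:
        stage_label = str(frame["stage"].iloc[0]) if len(frame) else "?"
    if genes is None:
        genes = sorted(set(frame["source"]) | set(frame["target"]))
    genes = list(genes)
    index = {g: i for i, g in enumerate(genes)}
    mat = lil_matrix((len(genes), len(genes)))
    for row in frame.itertuples(index=False):
        mat[index[row.source], index[row.target]] = row.b
    return StageNetwork(stage_label, genes, mat.tocsr())


# ---------------------------------------------------------------------------
# IDNs and score tables
# ---------------------------------------------------------------------------

def write_idn(idn: IDN, path) -> None:
    frame = idn.edge_labels.copy()
    frame.insert(0, "from_stage", idn.from_stage)
    frame.insert(1, "to_stage", idn.to_stage)
    frame.to_csv(path, sep="\t", index=False)


def read_idn(path) -> IDN:
    """Rebuild an IDN from its edge-label TSV (via the two stage matrices)."""
    frame = pd.read_csv(path, sep="\t")
    if frame.empty:
        raise ValueError(f"{path}: empty IDN table cannot be reconstructed")
    from_stage = str(frame["from_stage"].iloc[0])
    to_stage = str(frame["to_stage"].iloc[0])
    genes = sorted(set(frame["source"]) | set(frame["target"]))
    index = {g: i for i, g in enumerate(genes)}
    b1 = lil_matrix((len(genes), len(genes)))
    b2 = lil_matrix((len(genes), len(genes)))
    for row in frame.itertuples(index=False):
        i, j = index[row.source], index[row.target]
        b1[i, j] = row.b_from
        b2[i, j] = row.b_to
    net1 = StageNetwork(from_stage, genes, b1.tocsr())
    net2 = StageNetwork(to_stage, genes, b2.tocsr())
    return compute_idn(net1, net2)


def write_relevance_table(table, path) -> None:
    frame = table.table.copy()
    frame.insert(1, "from_stage", table.from_stage)
    frame.insert(2, "to_stage", table.to_stage)
    frame.to_csv(path, sep="\t", index=False)


def write_module_table(table, path) -> None:
    frame = table.table.copy()
    frame.insert(1, "from_stage", table.from_stage)
    frame.insert(2, "to_stage", table.to_stage)
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """GMT: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set {name!r}")
            members = {f for f in fields[2:] if f}
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = members
    return GeneSetCollection(sets, source=str(path))
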