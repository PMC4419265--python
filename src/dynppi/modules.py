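"""Functional-module relevance scores with hypergeometric enrichment.

A module's relevance score is the sum of its member proteins' scores,
RS_f = sum_{p in f} RS_p, over members present in the IDN.  Enrichment of a
module among the IDN's changed genes is assessed with a one-sided
hypergeometric test (population = scoring universe, successes = module
members, draws = changed genes); p-values are reported raw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .differential import IDN, relevance_scores

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) read from a GMT file."""

    sets: dict[str, set[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")


def relevance_score_module(idn: IDN, members) -> float:
    """RS_f: sum of member relevance scores; absent members contribute 0."""
    members = set(members)
    if not members:
        raise ValueError("module has no members")
    scores = relevance_scores(idn)
    present = scores.index.intersection(sorted(members))
    return float(scores.loc[present, "rs"].sum())


def enrich_module(idn_genes, members, universe) -> float:
    """One-sided hypergeometric tail P(X >= overlap).

    Population = ``universe``, successes = ``members``, draws = ``idn_genes``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("enrichment universe is empty")
    members = set(members)
    idn_genes = set(idn_genes)
    if not members <= universe:
        raise ValueError("members must be a subset of the universe")
    if not idn_genes <= universe:
        raise ValueError("idn_genes must be a subset of the universe")
    overlap = len(members & idn_genes)
    return float(hypergeom.sf(overlap - 1, len(universe), len(members),
                              len(idn_genes)))


@dataclass
class ModuleScoreTable:
    """Ranked module relevance scores with enrichment p-values."""

    from_stage: str
    to_stage: str
    table: pd.DataFrame   # rank, module, rs, n_members_in_idn, p
    top: pd.DataFrame


def rank_modules(idn: IDN, collection: GeneSetCollection,
                 universe=None, top_n: int = 10) -> ModuleScoreTable:
    """Score and enrich every module, ranked by RS_f descending.

    The default universe is the IDN's union gene set; module members outside
    the universe are ignored for both scoring and enrichment.  Ties are
    broken by module name.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    universe = set(idn.genes) if universe is None else set(universe)
    changed = set(idn.changed_genes()) & universe
    scores = relevance_scores(idn)

    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        present = scores.index.intersection(sorted(members))
        rs = float(scores.loc[present, "rs"].sum()) if len(present) else 0.0
        p = enrich_module(changed, members, universe) if members else 1.0
        rows.append((name, rs, len(members & changed), p))
    if not rows:
        logger.warning("empty gene-set collection: empty module table")
    table = pd.DataFrame(rows, columns=["module", "rs", "n_members_in_idn", "p"])
    table = table.sort_values(["rs", "module"], ascending=[False, True],
                              kind="stable", ignore_index=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return ModuleScoreTable(idn.from_stage, idn.to_stage,
                            table, table.head(top_n).copy())
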