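"""End-to-end pipeline: preprocess -> stage networks -> IDNs -> rankings.

A run reads an expression matrix, its sample annotations and a candidate
edge list; performs quantile normalisation and per-stage DE filtering;
identifies the three stage networks; computes the two stage-transition IDNs
(I -> II and II -> III by default); and writes ranked protein and module
relevance tables.  Every output file is recorded with a content hash in a
JSON run manifest so identical configurations produce identical artefacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as dio
from .differential import compute_idn, rank_proteins
from .modules import rank_modules
from .network import FitConfig, construct_stage_network
from .preprocess import (anova_de_filter, assemble_stage_profile,
                         default_stage_designs, normalize_to_baseline,
                         quantile_normalize)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    expression: str = ""
    annotations: str = ""
    candidates: str = ""
    gmt: str | None = None
    out_dir: str = "results"
    fdr_threshold: float = 1e-3
    baseline_normalize: bool = False
    l_multiplier: float = 4.0
    aic_variant: str = "aic"
    strategy: str = "auto"
    exhaustive_limit: int = 8
    symmetrize: bool = False
    top_n: int = 10
    seed: int = 0
    stage_pairs: tuple[tuple[str, str], ...] = (("I", "II"), ("II", "III"))

    def __post_init__(self) -> None:
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must be in (0, 1]")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        self.stage_pairs = tuple(tuple(p) for p in self.stage_pairs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def fit_config(self) -> FitConfig:
        return FitConfig(l_multiplier=self.l_multiplier,
                         aic_variant=self.aic_variant,
                         strategy=self.strategy,
                         exhaustive_limit=self.exhaustive_limit,
                         symmetrize=self.symmetrize)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run manifest (also written)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, path in (("expression", config.expression),
                        ("annotations", config.annotations),
                        ("candidates", config.candidates)):
        if not Path(path).exists():
            raise FileNotFoundError(f"{label} file not found: {path}")
    if config.gmt and not Path(config.gmt).exists():
        raise FileNotFoundError(f"gmt file not found: {config.gmt}")

    matrix = dio.read_expression(config.expression, config.annotations)
    candidates = dio.read_candidate_network(config.candidates)
    collection = dio.read_gmt(config.gmt) if config.gmt else None

    matrix = quantile_normalize(matrix)
    if config.baseline_normalize:
        matrix = normalize_to_baseline(matrix)

    outputs: dict[str, Path] = {}
    networks = {}
    counts = {}
    for design in default_stage_designs():
        stage = design.stage_label
        de = anova_de_filter(matrix, design, config.fdr_threshold)
        de_path = out / f"de_stage_{stage}.tsv"
        de.rename_axis("gene").to_csv(de_path, sep="\t")
        outputs[f"de_stage_{stage}"] = de_path

        selected = de.index[de["selected"]]
        if len(selected) == 0:
            raise RuntimeError(
                f"stage {stage}: no genes pass the DE filter "
                f"(fdr_threshold={config.fdr_threshold})")
        profile = assemble_stage_profile(matrix.subset_genes(selected), design)
        net = construct_stage_network(profile, candidates, config.fit_config())
        networks[stage] = net
        counts[stage] = {"de_genes": int(len(selected)),
                         "nodes": net.n_nodes(), "edges": net.n_edges()}
        for fmt, suffix in (("tsv", "tsv"), ("sif", "sif")):
            path = out / f"network_stage_{stage}.{suffix}"
            dio.write_network(net, path, fmt=fmt)
            outputs[f"network_stage_{stage}_{suffix}"] = path
        logger.info("stage %s: %d DE genes, %d nodes, %d edges",
                    stage, len(selected), net.n_nodes(), net.n_edges())

    for s1, s2 in config.stage_pairs:
        if s1 not in networks or s2 not in networks:
            raise RuntimeError(f"stage pair ({s1}, {s2}) not among built stages")
        tag = f"{s1}_to_{s2}"
        idn = compute_idn(networks[s1], networks[s2])
        idn_path = out / f"idn_{tag}.tsv"
        dio.write_idn(idn, idn_path)
        outputs[f"idn_{tag}"] = idn_path

        proteins = rank_proteins(idn, top_n=config.top_n)
        rs_path = out / f"protein_relevance_{tag}.tsv"
        dio.write_relevance_table(proteins, rs_path)
        outputs[f"protein_relevance_{tag}"] = rs_path

        if collection is not None:
            mods = rank_modules(idn, collection, top_n=config.top_n)
            mod_path = out / f"module_relevance_{tag}.tsv"
            dio.write_module_table(mods, mod_path)
            outputs[f"module_relevance_{tag}"] = mod_path

    manifest = {
        "config": {k: (list(map(list, v)) if k == "stage_pairs" else v)
                   for k, v in dataclasses.asdict(config).items()},
        "stage_counts": counts,
        "outputs": {name: {"path": str(path), "sha256": _sha256(path)}
                    for name, path in sorted(outputs.items())},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
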