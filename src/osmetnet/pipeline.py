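"""End-to-end orchestration: DE -> ORA -> GSVA -> PPI/features -> survival
-> diffusion/disease-network, driven by one YAML configuration.

Each stage writes its outputs before the next starts and contributes an
entry (input hashes, parameters, row counts, warnings) to the run manifest,
so every number in every output table is traceable to exactly one stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, diffexpr, diffusion, gsva, io, network, ora, survival

logger = logging.getLogger("osmetnet")

STAGES = ["dge", "ora", "gsva", "network", "survival", "diffusion"]


@dataclass
class PipelineConfig:
    """Input paths and thresholds for a full run.

    Threshold defaults are the study cut-offs: |log2FC| > 2 with BH q < 0.05
    for DEGs, raw p < 0.05 for ORA, q < 0.05 for GSVA, PPI confidence >=
    0.7, log-rank p < 0.05, diffusion p < 0.05.
    """

    expression: Path
    groups: Path
    gene_sets: Path
    ppi: Path
    disease_a: Path
    disease_b: Path
    clinical: Path
    graph_nodes: Path
    graph_edges: Path
    affected: Path
    compound_gene: Path
    outdir: Path
    seed: int
    mapping: Path | None = None
    lfc: float = 2.0
    de_alpha: float = 0.05
    ora_alpha: float = 0.05
    gsva_alpha: float = 0.05
    ppi_min_score: float = 0.7
    survival_alpha: float = 0.05
    diffusion_alpha: float = 0.05
    n_perm: int = 10000

    def __post_init__(self) -> None:
        for name in ("lfc",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "de_alpha", "ora_alpha", "gsva_alpha", "survival_alpha", "diffusion_alpha",
        ):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0 <= self.ppi_min_score <= 1:
            raise ValueError("ppi_min_score must lie in [0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw.update(overrides)
        path_fields = {
            "expression", "groups", "gene_sets", "ppi", "disease_a", "disease_b",
            "clinical", "graph_nodes", "graph_edges", "affected", "compound_gene",
            "mapping", "outdir",
        }
        kwargs = {
            k: (Path(v) if k in path_fields and v is not None else v)
            for k, v in raw.items()
        }
        return cls(**kwargs)


@dataclass
class RunManifest:
    seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, inputs: dict[str, Path], params: dict, counts: dict,
               stage_warnings: list[str]) -> None:
        self.stages.append(
            {
                "stage": stage,
                "inputs": {k: io.file_sha256(v) for k, v in inputs.items()},
                "params": params,
                "row_counts": counts,
                "warnings": stage_warnings,
            }
        )

    def to_json(self) -> dict:
        return {"seed": self.seed, "version": self.version, "stages": self.stages}


class StageError(RuntimeError):
    """An error labeled with the pipeline stage where it occurred."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: start", name)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                try:
                    result = fn(*args, **kwargs)
                except Exception as exc:
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return result, [str(w.message) for w in caught]
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order, writing outputs under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed)

    # --- differential expression -----------------------------------------
    @_stage("dge")
    def run_dge():
        expr = io.read_expression(config.expression)
        groups = io.read_groups(config.groups)
        stats = diffexpr.moderate_statistics(diffexpr.fit_gene_models(expr, groups))
        degs = diffexpr.call_degs(stats, lfc_threshold=config.lfc, alpha=config.de_alpha)
        io.write_table(stats.as_frame(), out / "dge_stats.tsv")
        io.write_table(degs, out / "degs.tsv")
        return expr, groups, degs

    (expr, groups, degs), w = run_dge()
    manifest.record(
        "dge",
        {"expression": config.expression, "groups": config.groups},
        {"lfc": config.lfc, "alpha": config.de_alpha},
        {"genes": len(expr), "degs": len(degs)},
        w,
    )

    # --- over-representation ----------------------------------------------
    @_stage("ora")
    def run_ora():
        collection = io.read_gmt(config.gene_sets)
        universe = list(expr.index)
        frames = []
        for direction in ("up", "down"):
            query = degs.loc[degs["direction"] == direction, "gene"]
            result = ora.enrich(query, collection, universe, alpha=config.ora_alpha)
            result.insert(0, "direction", direction)
            frames.append(result)
        enrichment = pd.concat(frames, ignore_index=True)
        io.write_table(enrichment, out / "ora.tsv")
        return enrichment

    enrichment, w = run_ora()
    manifest.record(
        "ora",
        {"gene_sets": config.gene_sets},
        {"alpha": config.ora_alpha},
        {"enriched_sets": len(enrichment)},
        w,
    )

    # --- GSVA ---------------------------------------------------------------
    @_stage("gsva")
    def run_gsva():
        collection = io.read_gmt(config.gene_sets)
        es = gsva.es_scores(gsva.kernel_cdf_scores(expr), collection)
        diff = gsva.differential_pathways(es, groups, alpha=config.gsva_alpha)
        io.write_table(es.reset_index(names="set"), out / "gsva_es.tsv")
        io.write_table(diff, out / "gsva_diff.tsv")
        return diff

    gsva_diff, w = run_gsva()
    manifest.record(
        "gsva",
        {"expression": config.expression, "gene_sets": config.gene_sets},
        {"alpha": config.gsva_alpha},
        {"differential_sets": len(gsva_diff)},
        w,
    )

    # --- PPI network + feature genes ----------------------------------------
    @_stage("network")
    def run_network():
        edge_table = io.read_table(config.ppi, columns=["gene_a", "gene_b", "score"])
        ppi = network.build_ppi(edge_table, degs, min_score=config.ppi_min_score)
        degree_table = network.degrees(ppi)
        features = network.feature_genes(
            ppi, io.read_gene_list(config.disease_a), io.read_gene_list(config.disease_b)
        )
        io.write_table(degree_table, out / "ppi_degrees.tsv")
        io.write_table(features, out / "feature_genes.tsv")
        network.write_graphml(ppi, out / "ppi.graphml")
        return ppi, features

    (ppi, features), w = run_network()
    feature_list = features.loc[features["feature"], "gene"].tolist()
    manifest.record(
        "network",
        {"ppi": config.ppi, "disease_a": config.disease_a, "disease_b": config.disease_b},
        {"min_score": config.ppi_min_score},
        {"nodes": ppi.number_of_nodes(), "edges": ppi.number_of_edges(),
         "feature_genes": len(feature_list)},
        w,
    )

    # --- survival screening ---------------------------------------------------
    @_stage("survival")
    def run_survival():
        clinical = io.read_table(config.clinical, columns=["sample", "time_months", "event"])
        prognosis = survival.screen_prognostic(
            clinical, feature_list, alpha=config.survival_alpha
        )
        io.write_table(prognosis, out / "prognosis.tsv")
        return prognosis

    prognosis, w = run_survival()
    manifest.record(
        "survival",
        {"clinical": config.clinical},
        {"alpha": config.survival_alpha},
        {"screened": len(feature_list), "prognostic": len(prognosis)},
        w,
    )

    # --- diffusion + disease-metabolic network --------------------------------
    @_stage("diffusion")
    def run_diffusion():
        graph = diffusion.build_graph(
            io.read_table(config.graph_nodes, columns=["id", "type"]),
            io.read_table(config.graph_edges, columns=["source", "target"]),
        )
        affected = set(io.read_table(config.affected, columns=["compound"])["compound"])
        scores = diffusion.permutation_pvalues(
            graph, affected, n_perm=config.n_perm, seed=config.seed
        )
        subnet = diffusion.significant_subnetwork(graph, scores, alpha=config.diffusion_alpha)
        disease_net = diffusion.assemble_disease_network(
            subnet, io.read_table(config.compound_gene, columns=["compound", "gene"]), degs
        )
        key = diffusion.rank_key_metabolites(disease_net)
        io.write_table(scores, out / "diffusion_scores.tsv")
        io.write_table(key, out / "key_metabolites.tsv")
        network.write_graphml(disease_net, out / "disease_network.graphml")
        return scores, disease_net, key

    (scores, disease_net, key), w = run_diffusion()
    manifest.record(
        "diffusion",
        {"graph_nodes": config.graph_nodes, "graph_edges": config.graph_edges,
         "affected": config.affected, "compound_gene": config.compound_gene},
        {"n_perm": config.n_perm, "alpha": config.diffusion_alpha, "seed": config.seed},
        {"scored_nodes": len(scores), "network_nodes": disease_net.number_of_nodes(),
         "network_edges": disease_net.number_of_edges(), "compounds_ranked": len(key)},
        w,
    )

    io.write_json(manifest.to_json(), out / "manifest.json")
    return manifest
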