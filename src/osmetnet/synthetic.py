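"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the shapes of the real study inputs at desk scale:
a two-group log2 expression matrix (19 tumor cell lines vs 4 normal bone
samples by default) with planted differentially expressed genes, a
right-censored survival cohort with planted prognostic genes, a scored
PPI edge list, disease-gene association tables, a compound-gene interaction
table with an id-mapping table, and a connected typed metabolic graph
(compound / reaction / enzyme / pathway / module) with a planted "hot"
neighborhood of affected compounds. Every generator is a pure function of
the configuration, seed included: identical configuration gives identical
outputs, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_clinical",
    "simulate_metabolic_graph",
    "simulate_association_tables",
    "simulate_gene_sets",
    "write_bundle",
]


def _default_graph_sizes() -> dict[str, int]:
    # a small affected set against a much larger compound pool, echoing the
    # scale imbalance of real metabolic networks
    return {"compound": 80, "reaction": 50, "enzyme": 15, "pathway": 5, "module": 3}


def _default_prognostic() -> list[tuple[str, float]]:
    # hazard ratio of the high-expression group; >1 means high expression is
    # adverse ("negative" prognostic direction), <1 protective ("positive")
    return [("GENE0001", 3.0), ("GENE0002", 1.0 / 3.0)]


@dataclass(frozen=True)
class SimConfig:
    """Study-scale simulation parameters.

    Expression shapes follow the emulated tumor-versus-normal design
    (19 case, 4 control); planted effects of +-3 log2 units against unit
    Gaussian noise give a clearly separable but non-trivial calling problem.
    """

    seed: int = 0
    n_genes: int = 1000
    n_case: int = 19
    n_control: int = 4
    n_de: int = 40
    lfc_effect: float = 3.0
    noise_sd: float = 1.0
    base_mean_range: tuple[float, float] = (4.0, 12.0)
    n_samples_survival: int = 80
    prognostic_genes: list[tuple[str, float]] = field(default_factory=_default_prognostic)
    baseline_hazard: float = 1.0 / 60.0  # events per month; median OS ~ 3.5 years
    censor_rate: float = 0.3
    graph_sizes: dict[str, int] = field(default_factory=_default_graph_sizes)
    n_affected_compounds: int = 4
    disease_overlap: float = 0.8  # fraction of DE genes in each disease table
    n_gene_sets: int = 12
    gene_set_size: int = 15

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_case": self.n_case,
            "n_control": self.n_control,
            "n_samples_survival": self.n_samples_survival,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not 0 <= self.n_de <= self.n_genes:
            raise ValueError("n_de must lie in [0, n_genes]")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must lie in [0, 1]")
        if not 0.0 <= self.disease_overlap <= 1.0:
            raise ValueError("disease_overlap must lie in [0, 1]")
        if self.graph_sizes.get("pathway", 0) < 1:
            raise ValueError("the metabolic graph needs at least one pathway node")
        if self.n_affected_compounds > self.graph_sizes.get("compound", 0):
            raise ValueError("n_affected_compounds exceeds the compound pool")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        stage_key = int.from_bytes(stage.encode(), "big") % (2**31)
        return np.random.default_rng([stage_key, self.seed])


@dataclass
class GroundTruth:
    """Planted structure, exactly describing the generated objects."""

    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> signed lfc
    prognostic_genes: dict[str, float] = field(default_factory=dict)  # gene -> HR
    affected_compounds: set[str] = field(default_factory=set)
    hot_pathway: str | None = None

    def to_json(self) -> dict:
        return {
            "de_genes": self.de_genes,
            "prognostic_genes": self.prognostic_genes,
            "affected_compounds": sorted(self.affected_compounds),
            "hot_pathway": self.hot_pathway,
        }


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i + 1:04d}" for i in range(n)]


def simulate_expression(config: SimConfig) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Two-group log2 expression with planted DE genes.

    The first ``n_de`` genes carry a case-minus-control mean shift of
    exactly +-``lfc_effect`` (alternating sign); Gaussian noise with
    ``noise_sd`` is added on top. Returns (matrix, group labels, truth).
    """
    rng = config.rng("expression")
    genes = _gene_ids(config.n_genes)
    samples = [f"CASE{i + 1:03d}" for i in range(config.n_case)] + [
        f"CTRL{i + 1:03d}" for i in range(config.n_control)
    ]
    groups = pd.Series(
        ["case"] * config.n_case + ["control"] * config.n_control,
        index=pd.Index(samples, name="sample"),
        name="group",
    )
    base = rng.uniform(*config.base_mean_range, size=config.n_genes)
    signs = np.where(np.arange(config.n_de) % 2 == 0, 1.0, -1.0)
    mean = np.tile(base[:, None], (1, len(samples)))
    is_case = (groups == "case").to_numpy()
    mean[: config.n_de, is_case] += (signs * config.lfc_effect)[:, None]
    values = mean + rng.normal(0.0, config.noise_sd, size=mean.shape)
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    truth = GroundTruth(
        de_genes={
            genes[i]: float(signs[i] * config.lfc_effect) for i in range(config.n_de)
        }
    )
    return expr, groups, truth


def simulate_clinical(config: SimConfig, expr: pd.DataFrame) -> pd.DataFrame:
    """Right-censored survival cohort with planted prognostic genes.

    A separate cohort of ``n_samples_survival`` samples gets per-gene
    expression (Gaussian around each gene's cohort mean) and exponential
    survival times whose log hazard is log(baseline) plus log(HR_g) for
    every planted gene whose expression exceeds its cohort median.
    Censoring is administrative: a ``censor_rate`` Bernoulli mask replaces
    the event time by a uniform fraction of it.
    """
    if config.n_samples_survival < 10:
        raise ValueError("survival simulation needs n_samples_survival >= 10")
    rng = config.rng("clinical")
    n = config.n_samples_survival
    samples = [f"SURV{i + 1:03d}" for i in range(n)]
    genes = list(expr.index)
    missing = [g for g, _ in config.prognostic_genes if g not in set(genes)]
    if missing:
        raise ValueError(f"prognostic genes absent from expression universe: {missing}")

    values = rng.normal(8.0, 2.0, size=(n, len(genes)))
    table = pd.DataFrame(values, columns=genes)
    table.insert(0, "sample", samples)

    log_hazard = np.full(n, np.log(config.baseline_hazard))
    for gene, hazard_ratio in config.prognostic_genes:
        high = table[gene].to_numpy() > np.median(table[gene])
        log_hazard += np.log(hazard_ratio) * high
    event_time = rng.exponential(scale=1.0 / np.exp(log_hazard))
    censored = rng.random(n) < config.censor_rate
    observed = np.where(censored, event_time * rng.uniform(0.05, 0.95, size=n), event_time)
    table.insert(1, "time_months", np.maximum(observed, 1e-3))
    table.insert(2, "event", (~censored).astype(int))
    return table


def simulate_metabolic_graph(config: SimConfig) -> tuple[nx.Graph, GroundTruth]:
    """Connected typed metabolic graph with a planted hot neighborhood.

    Template edges follow compound-reaction, reaction-enzyme,
    reaction-pathway and pathway-module links. All pathways hang off the
    first module (or each other via shared reactions when no module exists),
    so the scored subgraph is one component containing every pathway node.
    The affected compounds cluster around the first ("hot") pathway.
    """
    sizes = config.graph_sizes
    n_c, n_r = sizes.get("compound", 0), sizes.get("reaction", 0)
    n_e, n_p, n_m = sizes.get("enzyme", 0), sizes.get("pathway", 0), sizes.get("module", 0)
    if n_p < 1:
        raise ValueError("at least one pathway node is required")
    if n_c > 0 and n_r < 1:
        raise ValueError("compounds cannot connect without at least one reaction")
    if n_p > 1 and n_m < 1:
        raise ValueError("multiple pathways need at least one module to stay connected")

    rng = config.rng("graph")
    compounds = [f"C{i + 1:04d}" for i in range(n_c)]
    reactions = [f"R{i + 1:04d}" for i in range(n_r)]
    enzymes = [f"E{i + 1:04d}" for i in range(n_e)]
    pathways = [f"P{i + 1:03d}" for i in range(n_p)]
    modules = [f"M{i + 1:03d}" for i in range(n_m)]

    graph = nx.Graph()
    for nodes, node_type in [
        (compounds, "compound"),
        (reactions, "reaction"),
        (enzymes, "enzyme"),
        (pathways, "pathway"),
        (modules, "module"),
    ]:
        for node in nodes:
            graph.add_node(node, type=node_type)

    # pathways hang off module 1; extra modules attach to random pathways
    for module in modules[:1]:
        for pathway in pathways:
            graph.add_edge(pathway, module)
    for module in modules[1:]:
        graph.add_edge(rng.choice(pathways), module)
    # reactions distributed round-robin over pathways
    for i, reaction in enumerate(reactions):
        graph.add_edge(reaction, pathways[i % n_p])
    # enzymes catalyze 1-2 random reactions
    for enzyme in enzymes:
        for reaction in rng.choice(reactions, size=min(n_r, int(rng.integers(1, 3))), replace=False):
            graph.add_edge(enzyme, reaction)

    hot_pathway = pathways[0]
    hot_reactions = [r for i, r in enumerate(reactions) if i % n_p == 0]
    n_affected = config.n_affected_compounds
    affected = compounds[:n_affected]
    # affected compounds attach to hot reactions only (the hot neighborhood)
    for compound in affected:
        picks = rng.choice(
            hot_reactions, size=min(len(hot_reactions), 2), replace=False
        )
        for reaction in picks:
            graph.add_edge(compound, reaction)
    for compound in compounds[n_affected:]:
        picks = rng.choice(reactions, size=min(n_r, int(rng.integers(1, 3))), replace=False)
        for reaction in picks:
            graph.add_edge(compound, reaction)

    if n_c + n_r + n_e + n_m > 0 and not nx.is_connected(graph):
        raise ValueError("generated graph is not connected; adjust graph_sizes")
    graph.graph["excluded_components"] = []
    truth = GroundTruth(affected_compounds=set(affected), hot_pathway=hot_pathway)
    return graph, truth


def simulate_association_tables(
    config: SimConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """PPI edges, two disease-gene tables, compound-gene links, id mapping.

    PPI: planted DE genes form a connected scored backbone (chain plus
    random extra edges, scores in [0.7, 1]) with low-score decoy edges below
    threshold. Disease tables each cover ``disease_overlap`` of the DE set
    plus non-DE decoys. The compound-gene table links the first affected
    compound to six DEGs (the planted key metabolite) and the remaining
    affected compounds to one DEG each.
    """
    rng = config.rng("associations")
    de_genes = sorted(truth.de_genes)
    all_genes = _gene_ids(config.n_genes)
    non_de = [g for g in all_genes if g not in truth.de_genes]

    ppi_rows = []
    for a, b in zip(de_genes, de_genes[1:]):  # connected backbone
        ppi_rows.append((a, b, float(rng.uniform(0.7, 1.0))))
    for _ in range(len(de_genes)):
        a, b = rng.choice(de_genes, size=2, replace=False)
        ppi_rows.append((a, b, float(rng.uniform(0.7, 1.0))))
    for _ in range(len(de_genes) // 2):  # decoys below threshold
        a, b = rng.choice(all_genes, size=2, replace=False)
        ppi_rows.append((a, b, float(rng.uniform(0.1, 0.65))))
    ppi = pd.DataFrame(ppi_rows, columns=["gene_a", "gene_b", "score"])

    n_overlap = int(round(config.disease_overlap * len(de_genes)))
    tables = []
    for _ in range(2):
        members = list(rng.choice(de_genes, size=n_overlap, replace=False)) if n_overlap else []
        decoys = list(rng.choice(non_de, size=min(20, len(non_de)), replace=False))
        tables.append(pd.DataFrame({"gene": sorted(set(members + decoys))}))
    disease_a, disease_b = tables

    affected = sorted(truth.affected_compounds)
    cg_rows = []
    if affected:
        key_partners = de_genes[: min(6, len(de_genes))]
        for gene in key_partners:
            cg_rows.append((affected[0], gene))
        for i, compound in enumerate(affected[1:]):
            cg_rows.append((compound, de_genes[(i + 6) % len(de_genes)]))
    compound_gene = pd.DataFrame(cg_rows, columns=["compound", "gene"])

    mapping = pd.DataFrame(
        {
            "name": [f"chemical {c.lower()}" for c in affected],
            "kegg_id": affected,
        }
    )
    return ppi, disease_a, disease_b, compound_gene, mapping


def simulate_gene_sets(config: SimConfig, truth: GroundTruth) -> dict[str, set[str]]:
    """GMT-style collection: one up-DE set, one down-DE set, random decoys."""
    rng = config.rng("genesets")
    all_genes = _gene_ids(config.n_genes)
    up = sorted(g for g, s in truth.de_genes.items() if s > 0)
    down = sorted(g for g, s in truth.de_genes.items() if s < 0)
    collection: dict[str, set[str]] = {}
    if len(up) >= 2:
        collection["PLANTED_UP"] = set(up)
    if len(down) >= 2:
        collection["PLANTED_DOWN"] = set(down)
    non_de = [g for g in all_genes if g not in truth.de_genes]
    for i in range(config.n_gene_sets - len(collection)):
        members = rng.choice(non_de, size=min(config.gene_set_size, len(non_de)), replace=False)
        collection[f"RANDOM_{i + 1:02d}"] = set(members)
    return collection


def write_bundle(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every pipeline input into ``outdir``; returns written paths.

    Emits expression, groups, clinical, PPI, disease tables, compound-gene
    and mapping TSVs, the metabolic-graph node/edge TSVs, a GMT collection
    and the ground-truth JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, groups, truth_expr = simulate_expression(config)
    clinical = simulate_clinical(config, expr)
    graph, truth_graph = simulate_metabolic_graph(config)
    truth = GroundTruth(
        de_genes=truth_expr.de_genes,
        prognostic_genes=dict(config.prognostic_genes),
        affected_compounds=truth_graph.affected_compounds,
        hot_pathway=truth_graph.hot_pathway,
    )
    ppi, disease_a, disease_b, compound_gene, mapping = simulate_association_tables(
        config, truth
    )
    gene_sets = simulate_gene_sets(config, truth)

    nodes = pd.DataFrame(
        sorted((n, graph.nodes[n]["type"]) for n in graph.nodes), columns=["id", "type"]
    )
    edges = pd.DataFrame(sorted(tuple(sorted(e)) for e in graph.edges), columns=["source", "target"])
    affected = pd.DataFrame({"compound": sorted(truth.affected_compounds)})

    paths = {
        "expression": io.write_expression(expr, outdir / "expression.tsv"),
        "groups": io.write_table(groups.reset_index(), outdir / "groups.tsv"),
        "clinical": io.write_table(clinical, outdir / "clinical.tsv"),
        "ppi": io.write_table(ppi, outdir / "ppi.tsv"),
        "disease_a": io.write_table(disease_a, outdir / "disease_a.tsv"),
        "disease_b": io.write_table(disease_b, outdir / "disease_b.tsv"),
        "compound_gene": io.write_table(compound_gene, outdir / "compound_gene.tsv"),
        "mapping": io.write_table(mapping, outdir / "mapping.tsv"),
        "graph_nodes": io.write_table(nodes, outdir / "graph_nodes.tsv"),
        "graph_edges": io.write_table(edges, outdir / "graph_edges.tsv"),
        "affected": io.write_table(affected, outdir / "affected_compounds.tsv"),
        "gene_sets": io.write_gmt(gene_sets, outdir / "gene_sets.gmt"),
        "truth": io.write_json(truth.to_json(), outdir / "truth.json"),
    }
    return paths
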