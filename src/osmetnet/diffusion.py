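"""Heat diffusion on a typed KEGG-style metabolic graph.

Disease-affected metabolites act as heat sources on an undirected graph of
compounds, reactions, enzymes, pathways and modules. With L the
unnormalized Laplacian of the scored subgraph and B a diagonal 0/1 matrix
marking pathway nodes (heat sinks, which make the system non-singular), the
conductance matrix is KI = L + B and the per-node temperature scores T
solve the linear system KI . T = G, where G indicates the affected
compounds. Node significance is Monte-Carlo: the affected set is redrawn
uniformly among compound nodes and each node's observed temperature is
ranked against its permutation distribution (add-one estimator). Nodes with
p < 0.05 form the significant subnetwork, onto which DEG-compound
interaction edges are overlaid; the compound with most DEG interactions is
the key metabolite.

The ranking step depends only on the ordering of observed versus permuted
temperatures, so any global rescaling or sign convention of the solve
leaves every p-value unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "NODE_TYPES",
    "ConductanceSystem",
    "build_graph",
    "conductance",
    "diffusion_scores",
    "permutation_pvalues",
    "significant_subnetwork",
    "assemble_disease_network",
    "rank_key_metabolites",
    "map_compound_ids",
]

NODE_TYPES = frozenset({"compound", "reaction", "enzyme", "pathway", "module", "gene"})


@dataclass(frozen=True)
class ConductanceSystem:
    """Laplacian system of the scored (non-gene) subgraph."""

    nodes: list[str]  # scored node order
    laplacian: np.ndarray
    sink_diagonal: np.ndarray  # B(i,i) = 1 iff node i is a pathway
    conductance_matrix: np.ndarray  # KI = L + B

    @property
    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}


def build_graph(node_table: pd.DataFrame, edge_table: pd.DataFrame) -> nx.Graph:
    """Validated typed undirected graph from node (id, type) and edge tables.

    Components of the scored (non-gene) subgraph that contain no pathway
    node cannot anchor the diffusion solve; they are excluded from scoring
    with a warning and recorded in the graph attribute
    ``excluded_components``.
    """
    if not {"id", "type"} <= set(node_table.columns):
        raise ValueError("node table needs columns id, type")
    if not {"source", "target"} <= set(edge_table.columns):
        raise ValueError("edge table needs columns source, target")
    types = {}
    for row in node_table.itertuples(index=False):
        if row.type not in NODE_TYPES:
            raise ValueError(f"unknown node type {row.type!r} for node {row.id!r}")
        types[str(row.id)] = row.type
    graph = nx.Graph()
    for node, node_type in types.items():
        graph.add_node(node, type=node_type)
    for row_number, row in enumerate(edge_table.itertuples(index=False), start=2):
        source, target = str(row.source), str(row.target)
        for endpoint in (source, target):
            if endpoint not in types:
                raise ValueError(
                    f"edge table row {row_number}: endpoint {endpoint!r} not declared "
                    "in the node table"
                )
        if source != target:
            graph.add_edge(source, target)

    scored = graph.subgraph(n for n in graph if graph.nodes[n]["type"] != "gene")
    excluded = []
    for component in nx.connected_components(scored):
        if not any(graph.nodes[n]["type"] == "pathway" for n in component):
            excluded.append(sorted(component))
    if excluded:
        warnings.warn(
            f"{len(excluded)} scored component(s) lack a pathway node and are "
            "excluded from diffusion scoring"
        )
    graph.graph["excluded_components"] = excluded
    return graph


def _scored_nodes(graph: nx.Graph) -> list[str]:
    excluded = {n for comp in graph.graph.get("excluded_components", []) for n in comp}
    return sorted(
        n for n in graph if graph.nodes[n]["type"] != "gene" and n not in excluded
    )


def conductance(graph: nx.Graph) -> ConductanceSystem:
    """Build L, B and KI = L + B on the scored subgraph.

    Every scored component holds a pathway node (guaranteed by
    :func:`build_graph`), so KI is symmetric positive definite.
    """
    nodes = _scored_nodes(graph)
    if not nodes:
        raise ValueError("no scored nodes: the graph has no valid non-gene component")
    sub = graph.subgraph(nodes)
    laplacian = nx.laplacian_matrix(sub, nodelist=nodes).toarray().astype(float)
    sink = np.array(
        [1.0 if graph.nodes[n]["type"] == "pathway" else 0.0 for n in nodes]
    )
    return ConductanceSystem(
        nodes=nodes,
        laplacian=laplacian,
        sink_diagonal=sink,
        conductance_matrix=laplacian + np.diag(sink),
    )


def diffusion_scores(system: ConductanceSystem, g: np.ndarray) -> np.ndarray:
    """Temperature scores: solve KI . T = G.

    The solve uses a symmetric positive-definite (Cholesky) factorization;
    the relative residual is checked against 1e-10.
    """
    g = np.asarray(g, float)
    ki = system.conductance_matrix
    if g.shape != (ki.shape[0],):
        raise ValueError(f"indicator has shape {g.shape}, expected ({ki.shape[0]},)")
    if not g.any():
        return np.zeros_like(g)
    try:
        temperature = cho_solve(cho_factor(ki), g)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "conductance matrix is singular: every scored component must "
            "contain at least one pathway node"
        ) from exc
    residual = np.linalg.norm(ki @ temperature - g) / np.linalg.norm(g)
    if residual > 1e-10:
        raise ArithmeticError(f"diffusion solve residual {residual:.2e} exceeds 1e-10")
    return temperature


def _indicator(system: ConductanceSystem, affected: set[str]) -> np.ndarray:
    g = np.zeros(len(system.nodes))
    idx = system.index
    for compound in affected:
        g[idx[compound]] = 1.0
    return g


def permutation_pvalues(
    graph: nx.Graph,
    affected_compounds: set[str],
    n_perm: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Temperature scores with Monte-Carlo permutation p-values.

    Each permutation redraws the affected set uniformly among compound-type
    scored nodes at the observed cardinality; per node,
    p = (1 + #{T_perm >= T_obs}) / (n_perm + 1). Because T is linear in G,
    permuted scores are sums of precomputed per-source solution columns,
    so the permutation loop costs one matrix slice per draw.
    """
    if seed is None:
        raise ValueError("a seed is required for the permutation null")
    system = conductance(graph)
    compounds = [n for n in system.nodes if graph.nodes[n]["type"] == "compound"]
    affected = set(affected_compounds)
    if not affected:
        raise ValueError("affected compound set is empty")
    unknown = affected - set(compounds)
    if unknown:
        raise ValueError(f"affected ids not among scored compounds: {sorted(unknown)}")
    if len(affected) > len(compounds):
        raise ValueError("affected set larger than the compound pool")

    t_obs = diffusion_scores(system, _indicator(system, affected))

    # unit responses: column c of KI^-1 restricted to compound sources
    inv_columns = np.linalg.solve(
        system.conductance_matrix, np.eye(len(system.nodes))
    )[:, [system.index[c] for c in compounds]]
    rng = np.random.default_rng(seed)
    k = len(affected)
    exceed = np.zeros(len(system.nodes))
    for _ in range(n_perm):
        draw = rng.choice(len(compounds), size=k, replace=False)
        t_perm = inv_columns[:, draw].sum(axis=1)
        exceed += t_perm >= t_obs
    p = (1.0 + exceed) / (n_perm + 1.0)

    return pd.DataFrame(
        {
            "node": system.nodes,
            "type": [graph.nodes[n]["type"] for n in system.nodes],
            "T": t_obs,
            "p": p,
        }
    )


def significant_subnetwork(
    graph: nx.Graph, scores: pd.DataFrame, alpha: float = 0.05
) -> nx.Graph:
    """Induced subgraph of nodes with p < alpha (strict)."""
    kept = scores.loc[scores["p"] < alpha, "node"].tolist()
    subnet = graph.subgraph(kept).copy()
    p_by_node = dict(zip(scores["node"], scores["p"]))
    t_by_node = dict(zip(scores["node"], scores["T"]))
    for node in subnet.nodes:
        subnet.nodes[node]["p"] = float(p_by_node[node])
        subnet.nodes[node]["T"] = float(t_by_node[node])
    return subnet


def assemble_disease_network(
    subnet: nx.Graph, compound_gene_table: pd.DataFrame, deg_table: pd.DataFrame
) -> nx.Graph:
    """Overlay DEG-compound interaction edges onto the significant subnetwork.

    Gene nodes (annotated up/down from the DEG table) are added only for
    interactions whose compound survived retention; each retained compound
    gets a ``deg_interactions`` count.
    """
    network = subnet.copy()
    directions = {
        str(g).upper(): d for g, d in zip(deg_table["gene"], deg_table["direction"])
    }
    retained_compounds = {
        n for n in subnet.nodes if subnet.nodes[n]["type"] == "compound"
    }
    counts = {c: 0 for c in retained_compounds}
    if not compound_gene_table.empty:
        for row in compound_gene_table.itertuples(index=False):
            compound, gene = str(row.compound), str(row.gene).upper()
            if compound not in retained_compounds or gene not in directions:
                continue
            if not network.has_node(gene):
                network.add_node(gene, type="gene", direction=directions[gene])
            if not network.has_edge(gene, compound):
                network.add_edge(gene, compound, kind="deg_compound")
                counts[compound] += 1
    for compound, count in counts.items():
        network.nodes[compound]["deg_interactions"] = count
    return network


def rank_key_metabolites(network: nx.Graph) -> pd.DataFrame:
    """Compounds ranked by descending DEG-interaction count.

    Ties break by smaller diffusion p, then lexical compound id. The
    top-ranked compound is the key disease-associated metabolite.
    """
    rows = [
        {
            "compound": n,
            "deg_interactions": network.nodes[n].get("deg_interactions", 0),
            "p": network.nodes[n].get("p", 1.0),
        }
        for n in network.nodes
        if network.nodes[n]["type"] == "compound"
    ]
    table = pd.DataFrame(rows, columns=["compound", "deg_interactions", "p"])
    return table.sort_values(
        ["deg_interactions", "p", "compound"], ascending=[False, True, True]
    ).reset_index(drop=True)


def map_compound_ids(
    chemical_names: list[str], mapping_table: pd.DataFrame
) -> tuple[list[str], list[str]]:
    """Case-insensitive exact-name lookup of compound ids.

    Returns (sorted unique mapped ids, unmapped names in input order);
    unmapped names are reported, never silently dropped.
    """
    if not {"name", "kegg_id"} <= set(mapping_table.columns):
        raise ValueError("mapping table needs columns name, kegg_id")
    lookup = {
        str(name).strip().lower(): str(cid)
        for name, cid in zip(mapping_table["name"], mapping_table["kegg_id"])
    }
    mapped: set[str] = set()
    unmapped: list[str] = []
    for name in chemical_names:
        key = str(name).strip().lower()
        if key in lookup:
            mapped.add(lookup[key])
        elif name not in unmapped:
            unmapped.append(name)
    return sorted(mapped), unmapped
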