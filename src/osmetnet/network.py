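"""Score-filtered PPI network construction and feature-gene intersection.

Edges between differentially expressed genes are retained at a confidence
score >= 0.7 (the "medium confidence" convention of STRING-style edge
lists, inclusive of the boundary). Feature genes are the three-way
intersection of the PPI node set with two disease-association gene tables.
Gene symbols are upper-cased before any comparison because the source
tables differ in case conventions.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

__all__ = ["build_ppi", "degrees", "feature_genes", "write_graphml"]


def _norm(symbol: str) -> str:
    return str(symbol).strip().upper()


def build_ppi(
    edge_table: pd.DataFrame, deg_table: pd.DataFrame, min_score: float = 0.7
) -> nx.Graph:
    """Build the PPI graph of DEGs from a scored edge list.

    Keeps edges with score >= ``min_score`` whose endpoints are both DEGs,
    deduplicating unordered pairs by maximum score and dropping self-loops.
    Nodes carry the DEG ``direction`` attribute; isolated DEGs are not
    included (downstream intersection is over connected network genes).
    """
    required = {"gene_a", "gene_b", "score"}
    if not required <= set(edge_table.columns):
        raise ValueError(f"edge table needs columns {sorted(required)}")
    direction = {
        _norm(g): d for g, d in zip(deg_table["gene"], deg_table["direction"])
    }
    graph = nx.Graph()
    for row_number, row in enumerate(edge_table.itertuples(index=False), start=2):
        a, b = _norm(row.gene_a), _norm(row.gene_b)
        try:
            score = float(row.score)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"edge table row {row_number}: bad score {row.score!r}") from exc
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"edge table row {row_number}: score {score} outside [0, 1]")
        if a == b:
            continue
        if score < min_score or a not in direction or b not in direction:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["score"] = max(graph[a][b]["score"], score)
        else:
            graph.add_edge(a, b, score=score)
    for node in graph.nodes:
        graph.nodes[node]["direction"] = direction[node]
    return graph


def degrees(network: nx.Graph) -> pd.DataFrame:
    """Node degrees (count of incident retained edges), sorted descending."""
    table = pd.DataFrame(
        [(node, deg) for node, deg in network.degree()], columns=["gene", "degree"]
    )
    return table.sort_values(["degree", "gene"], ascending=[False, True]).reset_index(
        drop=True
    )


def feature_genes(
    network: nx.Graph, table_a: set[str], table_b: set[str]
) -> pd.DataFrame:
    """Three-way intersection of PPI nodes with two disease gene tables.

    Returns every gene found in at least one source with per-source
    membership flags; the ``feature`` column marks the triple intersection.
    """
    ppi = {_norm(g) for g in network.nodes}
    a = {_norm(g) for g in table_a}
    b = {_norm(g) for g in table_b}
    rows = [
        {
            "gene": gene,
            "in_ppi": gene in ppi,
            "in_table_a": gene in a,
            "in_table_b": gene in b,
            "feature": gene in ppi and gene in a and gene in b,
        }
        for gene in sorted(ppi | a | b)
    ]
    return pd.DataFrame(rows, columns=["gene", "in_ppi", "in_table_a", "in_table_b", "feature"])


def write_graphml(network: nx.Graph, path) -> None:
    # GraphML carries only scalar attributes; drop structural metadata lists
    export = network.copy()
    export.graph = {
        k: v for k, v in network.graph.items() if isinstance(v, (str, int, float, bool))
    }
    nx.write_graphml(export, path)
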