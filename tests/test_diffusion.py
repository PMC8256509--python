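"""Heat diffusion: conductance system, solver, permutation null, overlay."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from osmetnet import diffusion
from osmetnet.synthetic import SimConfig, simulate_metabolic_graph


def tables_from(nodes, edges):
    node_table = pd.DataFrame(nodes, columns=["id", "type"])
    edge_table = pd.DataFrame(edges, columns=["source", "target"])
    return node_table, edge_table


@pytest.fixture()
def path_graph():
    """compound - reaction - pathway chain."""
    return diffusion.build_graph(
        *tables_from(
            [("c1", "compound"), ("r1", "reaction"), ("p1", "pathway")],
            [("c1", "r1"), ("r1", "p1")],
        )
    )


# ------------------------------------------------------------ build_graph


def test_build_graph_rejects_unknown_type_and_dangling_edge():
    with pytest.raises(ValueError, match="unknown node type"):
        diffusion.build_graph(*tables_from([("x", "protein")], []))
    with pytest.raises(ValueError, match="row 2.*ghost"):
        diffusion.build_graph(
            *tables_from([("c1", "compound"), ("p1", "pathway")], [("c1", "ghost")])
        )


def test_build_graph_excludes_pathwayless_components():
    nodes = [("c1", "compound"), ("r1", "reaction"), ("p1", "pathway"),
             ("c2", "compound"), ("r2", "reaction")]
    edges = [("c1", "r1"), ("r1", "p1"), ("c2", "r2")]
    with pytest.warns(UserWarning, match="lack a pathway node"):
        graph = diffusion.build_graph(*tables_from(nodes, edges))
    assert graph.graph["excluded_components"] == [["c2", "r2"]]
    system = diffusion.conductance(graph)
    assert set(system.nodes) == {"c1", "r1", "p1"}


def test_template_graph_from_generator_accepted():
    config = SimConfig(
        graph_sizes={"compound": 5, "reaction": 3, "enzyme": 2, "pathway": 1, "module": 1},
        n_affected_compounds=2,
    )
    graph, truth = simulate_metabolic_graph(config)
    assert graph.number_of_nodes() == 12
    assert nx.is_connected(graph)
    system = diffusion.conductance(graph)
    assert len(system.nodes) == 12


# ------------------------------------------------------------ conductance


def test_conductance_single_pathway_node():
    graph = diffusion.build_graph(*tables_from([("p1", "pathway")], []))
    system = diffusion.conductance(graph)
    assert system.laplacian.tolist() == [[0.0]]
    assert system.conductance_matrix.tolist() == [[1.0]]


def test_conductance_hand_matrix_on_path(path_graph):
    system = diffusion.conductance(path_graph)
    order = system.index
    expected_l = np.zeros((3, 3))
    for a, b in [("c1", "r1"), ("r1", "p1")]:
        i, j = order[a], order[b]
        expected_l[i, j] = expected_l[j, i] = -1.0
        expected_l[i, i] += 1.0
        expected_l[j, j] += 1.0
    np.testing.assert_allclose(system.laplacian, expected_l)
    np.testing.assert_allclose(system.laplacian.sum(axis=1), 0.0, atol=1e-12)
    expected_b = np.zeros(3)
    expected_b[order["p1"]] = 1.0
    np.testing.assert_allclose(system.sink_diagonal, expected_b)
    np.testing.assert_allclose(
        system.conductance_matrix, expected_l + np.diag(expected_b)
    )


def test_conductance_positive_definite_on_random_graphs():
    for seed in range(5):
        graph, _ = simulate_metabolic_graph(SimConfig(seed=seed))
        system = diffusion.conductance(graph)
        smallest = np.linalg.eigvalsh(system.conductance_matrix)[0]
        assert smallest > 0


# --------------------------------------------------------------- solver


def test_diffusion_scores_trivial_cases(path_graph):
    system = diffusion.conductance(path_graph)
    np.testing.assert_allclose(
        diffusion.diffusion_scores(system, np.zeros(3)), np.zeros(3)
    )
    single = diffusion.conductance(
        diffusion.build_graph(*tables_from([("p1", "pathway")], []))
    )
    np.testing.assert_allclose(
        diffusion.diffusion_scores(single, np.ones(1)), np.ones(1)
    )


def test_diffusion_scores_match_dense_inverse_oracle():
    for seed in range(3):
        graph, truth = simulate_metabolic_graph(SimConfig(seed=seed))
        system = diffusion.conductance(graph)
        g = np.zeros(len(system.nodes))
        for compound in truth.affected_compounds:
            g[system.index[compound]] = 1.0
        t = diffusion.diffusion_scores(system, g)
        expected = np.linalg.inv(system.conductance_matrix) @ g
        np.testing.assert_allclose(t, expected, atol=1e-8)
        residual = np.linalg.norm(system.conductance_matrix @ t - g)
        assert residual / np.linalg.norm(g) <= 1e-10


# ----------------------------------------------------------- permutation


def test_permutation_min_p_is_add_one_bound(path_graph):
    scores = diffusion.permutation_pvalues(path_graph, {"c1"}, n_perm=10, seed=0)
    assert (scores["p"] >= 1 / 11 - 1e-12).all()


def test_permutation_deterministic_under_seed():
    graph, truth = simulate_metabolic_graph(SimConfig(seed=2))
    a = diffusion.permutation_pvalues(graph, truth.affected_compounds, n_perm=200, seed=5)
    b = diffusion.permutation_pvalues(graph, truth.affected_compounds, n_perm=200, seed=5)
    pd.testing.assert_frame_equal(a, b)


def test_permutation_requires_seed_and_valid_affected(path_graph):
    with pytest.raises(ValueError, match="seed"):
        diffusion.permutation_pvalues(path_graph, {"c1"}, n_perm=10)
    with pytest.raises(ValueError, match="not among"):
        diffusion.permutation_pvalues(path_graph, {"p1"}, n_perm=10, seed=0)
    with pytest.raises(ValueError, match="empty"):
        diffusion.permutation_pvalues(path_graph, set(), n_perm=10, seed=0)


def test_pvalues_invariant_to_solve_convention():
    """Ranking by -T with the lower tail equals ranking by T with the upper
    tail, and any positive rescaling leaves the comparison unchanged."""
    graph, truth = simulate_metabolic_graph(SimConfig(seed=4))
    system = diffusion.conductance(graph)
    compounds = [n for n in system.nodes if graph.nodes[n]["type"] == "compound"]
    g_obs = np.zeros(len(system.nodes))
    for compound in truth.affected_compounds:
        g_obs[system.index[compound]] = 1.0
    t_obs = diffusion.diffusion_scores(system, g_obs)

    rng = np.random.default_rng(0)
    draws = [
        rng.choice(compounds, size=len(truth.affected_compounds), replace=False)
        for _ in range(300)
    ]
    perms = []
    for draw in draws:
        g = np.zeros(len(system.nodes))
        for compound in draw:
            g[system.index[compound]] = 1.0
        perms.append(diffusion.diffusion_scores(system, g))
    perms = np.array(perms)

    def pvals(obs, mat, upper):
        exceed = (mat >= obs).sum(axis=0) if upper else (mat <= obs).sum(axis=0)
        return (1.0 + exceed) / (len(mat) + 1.0)

    base = pvals(t_obs, perms, upper=True)
    flipped = pvals(-t_obs, -perms, upper=False)
    scaled = pvals(7.3 * t_obs, 7.3 * perms, upper=True)
    np.testing.assert_allclose(base, flipped)
    np.testing.assert_allclose(base, scaled)


def test_locality_in_barbell_graph():
    """Affected compounds in one cluster heat that cluster more than the
    far cluster across the single bridge."""
    nodes, edges = [], []
    for side in ("a", "b"):
        nodes += [(f"p_{side}", "pathway")]
        for i in range(4):
            nodes += [(f"c{i}_{side}", "compound"), (f"r{i}_{side}", "reaction")]
            edges += [
                (f"c{i}_{side}", f"r{i}_{side}"),
                (f"r{i}_{side}", f"p_{side}"),
            ]
    edges += [("p_a", "p_b")]  # the bridge
    graph = diffusion.build_graph(*tables_from(nodes, edges))
    system = diffusion.conductance(graph)
    g = np.zeros(len(system.nodes))
    for i in range(4):
        g[system.index[f"c{i}_a"]] = 1.0
    t = diffusion.diffusion_scores(system, g)
    side_a = [i for n, i in system.index.items() if n.endswith("_a")]
    side_b = [i for n, i in system.index.items() if n.endswith("_b")]
    assert t[side_a].mean() > t[side_b].mean()
    assert min(t[side_a]) > max(t[side_b])


# ------------------------------------------------ retention and overlay


def test_significant_subnetwork_strict_boundary(path_graph):
    scores = pd.DataFrame(
        {"node": ["c1", "r1", "p1"], "type": ["compound", "reaction", "pathway"],
         "T": [1.0, 0.5, 0.2], "p": [0.01, 0.05, 1.0]}
    )
    subnet = diffusion.significant_subnetwork(path_graph, scores)
    assert set(subnet.nodes) == {"c1"}  # p = 0.05 excluded, p = 1 excluded
    empty = diffusion.significant_subnetwork(
        path_graph, scores.assign(p=[1.0, 1.0, 1.0])
    )
    assert empty.number_of_nodes() == 0


def degs_fixture(genes, direction="down"):
    return pd.DataFrame({"gene": genes, "direction": [direction] * len(genes)})


def test_overlay_counts_and_skips_unretained_compounds(path_graph):
    scores = pd.DataFrame(
        {"node": ["c1", "r1", "p1"], "type": ["compound", "reaction", "pathway"],
         "T": [1.0, 0.5, 0.2], "p": [0.01, 0.02, 0.5]}
    )
    subnet = diffusion.significant_subnetwork(path_graph, scores)
    links = pd.DataFrame(
        {"compound": ["c1"] * 6 + ["c_gone"], "gene": [f"g{i}" for i in range(6)] + ["g0"]}
    )
    degs = degs_fixture([f"g{i}" for i in range(6)])
    net = diffusion.assemble_disease_network(subnet, links, degs)
    assert net.nodes["c1"]["deg_interactions"] == 6
    assert "c_gone" not in net
    gene_nodes = [n for n in net if net.nodes[n]["type"] == "gene"]
    assert len(gene_nodes) == 6
    # overlay edges only connect genes to compounds
    for a, b in net.edges:
        kinds = {net.nodes[a]["type"], net.nodes[b]["type"]}
        if "gene" in kinds:
            assert kinds == {"gene", "compound"}


def test_overlay_empty_interaction_table(path_graph):
    scores = pd.DataFrame(
        {"node": ["c1", "r1", "p1"], "type": ["compound", "reaction", "pathway"],
         "T": [1.0, 0.5, 0.2], "p": [0.01, 0.5, 0.5]}
    )
    subnet = diffusion.significant_subnetwork(path_graph, scores)
    net = diffusion.assemble_disease_network(
        subnet, pd.DataFrame(columns=["compound", "gene"]), degs_fixture([])
    )
    assert net.nodes["c1"]["deg_interactions"] == 0
    assert set(net.nodes) == set(subnet.nodes)


def test_rank_key_metabolites_order_and_ties():
    net = nx.Graph()
    net.add_node("cA", type="compound", deg_interactions=6, p=0.01)
    net.add_node("cB", type="compound", deg_interactions=1, p=0.001)
    net.add_node("cC", type="compound", deg_interactions=1, p=0.001)
    net.add_node("r1", type="reaction", p=0.01)
    table = diffusion.rank_key_metabolites(net)
    assert table["compound"].tolist() == ["cA", "cB", "cC"]  # count, then p, then id
    assert diffusion.rank_key_metabolites(nx.Graph()).empty


# ------------------------------------------------------------- id mapping


def test_map_compound_ids_reports_unmapped():
    mapping = pd.DataFrame(
        {"name": ["Bisphenol A", "Cyclophosphamide"], "kegg_id": ["C13624", "C07888"]}
    )
    ids, unmapped = diffusion.map_compound_ids(
        ["bisphenol a", "CYCLOPHOSPHAMIDE", "unobtainium", "bisphenol a"], mapping
    )
    assert ids == ["C07888", "C13624"]
    assert unmapped == ["unobtainium"]
    assert diffusion.map_compound_ids([], mapping) == ([], [])
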