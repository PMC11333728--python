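"""Centrality measures against brute-force shortest-path enumeration."""

import networkx as nx
import numpy as np
import pytest

from crossdx.netrank import (
    MEASURES,
    BipartiteRegulatorNetwork,
    bottleneck_scores,
    build_graph,
    centrality_table,
    compute_centrality,
    neighborhood_similarity,
    rank_regulators,
    select_hubs,
)
from crossdx.synthdata import SyntheticNetworkSpec, generate_ppi_graph

# ---------------------------------------------------------------------------
# independent oracles: explicit enumeration of all shortest paths
# ---------------------------------------------------------------------------


def oracle_path_scores(g):
    """Betweenness and stress by enumerating every shortest path."""
    nodes = sorted(g.nodes, key=str)
    betw = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if not nx.has_path(g, s, t):
                continue
            paths = list(nx.all_shortest_paths(g, s, t))
            for v in nodes:
                if v in (s, t):
                    continue
                hits = sum(1 for p in paths if v in p)
                stress[v] += hits
                betw[v] += hits / len(paths)
    return betw, stress


def oracle_closeness(g):
    out = {}
    for v in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, v)
        out[v] = sum(1.0 / d for w, d in lengths.items() if w != v)
    return out


def oracle_radiality(g):
    out = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        nc = len(comp)
        if nc == 1:
            out.update({v: 0.0 for v in comp})
            continue
        ecc = nx.eccentricity(sub)
        diam = max(ecc.values())
        for v in comp:
            lengths = nx.single_source_shortest_path_length(sub, v)
            out[v] = sum(diam + 1 - d for w, d in lengths.items() if w != v) / (nc - 1)
    return out


def oracle_mnc(g):
    """Largest neighbor component via union-find, independent of networkx CCs."""
    out = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        parent = {u: u for u in nbrs}

        def find(u):
            while parent[u] != u:
                parent[u] = parent[parent[u]]
                u = parent[u]
            return u

        for a in nbrs:
            for b in g.neighbors(a):
                if b in parent:
                    parent[find(a)] = find(b)
        sizes = {}
        for u in nbrs:
            r = find(u)
            sizes[r] = sizes.get(r, 0) + 1
        out[v] = max(sizes.values()) if sizes else 0
    return out


def oracle_bottleneck(g):
    """Ancestor-walk recount of the per-root shortest-path-tree votes."""
    scores = {v: 0 for v in g.nodes}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        nc = len(comp)
        for root in comp:
            dist = nx.single_source_shortest_path_length(sub, root)
            parent = {}
            for v in comp:
                if v == root:
                    continue
                parent[v] = min((u for u in sub.neighbors(v)
                                 if dist[u] == dist[v] - 1), key=str)
            # count subtree sizes by walking every node up to the root
            counts = {v: 0 for v in comp}
            for w in comp:
                u = w
                counts[w] += 1
                while u != root:
                    u = parent[u]
                    counts[u] += 1
            for v in comp:
                if v != root and counts[v] > nc / 4.0:
                    scores[v] += 1
    return scores


def random_graph(seed, max_nodes=8):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.15, 0.9))
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(f"n{i}", f"n{j}")
    return g


# ---------------------------------------------------------------------------


class TestNeighborhoodSimilarity:
    def test_hand_example(self):
        g = build_graph([("i", "a"), ("i", "b"), ("i", "c"),
                         ("j", "b"), ("j", "c"), ("j", "d")])
        assert neighborhood_similarity(g, "i", "j") == pytest.approx(2 / 3)

    def test_identical_neighborhoods(self):
        g = build_graph([("i", "a"), ("i", "b"), ("j", "a"), ("j", "b")])
        assert neighborhood_similarity(g, "i", "j") == 1.0

    def test_disjoint_neighborhoods(self):
        g = build_graph([("i", "a"), ("j", "b")])
        assert neighborhood_similarity(g, "i", "j") == 0.0

    def test_symmetry_on_random_graphs(self):
        g = random_graph(100)
        for i in g.nodes:
            for j in g.nodes:
                if g.degree(i) + g.degree(j) > 0:
                    assert neighborhood_similarity(g, i, j) == pytest.approx(
                        neighborhood_similarity(g, j, i))

    def test_isolated_pair_raises(self):
        g = nx.Graph()
        g.add_nodes_from(["x", "y"])
        with pytest.raises(ValueError, match="x"):
            neighborhood_similarity(g, "x", "y")


class TestHandGraphs:
    def test_path_graph(self):
        g = build_graph([("a", "b"), ("b", "c")])
        assert compute_centrality(g, "betweenness")["b"] == pytest.approx(1.0)
        assert compute_centrality(g, "stress")["b"] == 1
        cl = compute_centrality(g, "closeness")
        assert cl["b"] == pytest.approx(2.0) and cl["a"] == pytest.approx(1.5)
        rad = compute_centrality(g, "radiality")
        assert rad["b"] == pytest.approx(2.0) and rad["a"] == pytest.approx(1.5)
        assert compute_centrality(g, "mnc")["b"] == 1

    def test_star_graph(self):
        g = build_graph([("c", x) for x in "xyz"])
        assert compute_centrality(g, "degree")["c"] == 3
        assert compute_centrality(g, "betweenness")["c"] == pytest.approx(3.0)
        assert compute_centrality(g, "stress")["c"] == 3
        assert compute_centrality(g, "mnc")["c"] == 1
        bn = bottleneck_scores(g)
        assert bn["c"] == 3 and all(bn[x] == 0 for x in "xyz")

    def test_single_edge_bottleneck(self):
        bn = bottleneck_scores(build_graph([("a", "b")]))
        assert bn == {"a": 1, "b": 1}

    def test_edgeless_graph_bottleneck(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        assert set(bottleneck_scores(g).values()) == {0}

    def test_triangle_symmetry(self):
        g = build_graph([("a", "b"), ("b", "c"), ("a", "c")])
        assert set(compute_centrality(g, "betweenness").values()) == {0.0}
        assert set(compute_centrality(g, "mnc").values()) == {2}
        assert set(compute_centrality(g, "degree").values()) == {2}

    def test_complete_graph_zero_betweenness(self):
        g = nx.complete_graph(6)
        assert set(compute_centrality(g, "betweenness").values()) == {0.0}
        assert set(compute_centrality(g, "stress").values()) == {0.0}
        assert set(compute_centrality(g, "degree").values()) == {5}


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_all_measures_match_enumeration(self, seed):
        g = random_graph(seed)
        betw_o, stress_o = oracle_path_scores(g)
        oracles = {
            "betweenness": betw_o,
            "stress": stress_o,
            "closeness": oracle_closeness(g),
            "radiality": oracle_radiality(g),
            "mnc": oracle_mnc(g),
            "bottleneck": oracle_bottleneck(g),
            "degree": dict(g.degree()),
        }
        for measure in MEASURES:
            got = compute_centrality(g, measure)
            for v in g.nodes:
                assert got[v] == pytest.approx(oracles[measure][v]), \
                    f"{measure} mismatch at {v} (seed {seed})"

    def test_component_additivity(self):
        """Scores on a disconnected graph equal per-component scores."""
        g1 = random_graph(7, max_nodes=6)
        g2 = nx.relabel_nodes(random_graph(8, max_nodes=6), lambda v: f"m{v}")
        union = nx.union(g1, g2)
        for measure in MEASURES:
            whole = compute_centrality(union, measure)
            for part in (g1, g2):
                alone = compute_centrality(part, measure)
                for v in part.nodes:
                    assert whole[v] == pytest.approx(alone[v]), measure


class TestHubSelection:
    def test_planted_hub_ranked_first_both_methods(self):
        spec = SyntheticNetworkSpec(n_background_nodes=40, n_planted_hubs=1,
                                    hub_degree=15, background_density=0.03, seed=3)
        g = generate_ppi_graph(spec)
        for method in ("mean_rank", "topk_count"):
            sel = select_hubs(g, k=10, method=method)
            assert sel.genes[0] == "HUB00", method

    def test_k_equals_node_count_returns_all(self):
        g = build_graph([("a", "b"), ("b", "c")])
        sel = select_hubs(g, k=3)
        assert sorted(sel.genes) == ["a", "b", "c"]

    def test_tie_break_deterministic(self):
        # two leaves in isomorphic positions: lexicographic order decides
        g = build_graph([("c", "a"), ("c", "b")])
        runs = {tuple(select_hubs(g, k=3).genes) for _ in range(3)}
        assert runs == {("c", "a", "b")}

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            select_hubs(build_graph([("a", "b")]), k=0)

    def test_centrality_table_has_all_measures(self, small_sim):
        g = generate_ppi_graph(SyntheticNetworkSpec(seed=1))
        tab = centrality_table(g).table
        assert list(tab.columns) == list(MEASURES)
        assert (tab >= 0).all().all()
        assert (tab["degree"] % 1 == 0).all()


class TestRegulators:
    def network(self):
        return BipartiteRegulatorNetwork(edges=[
            ("TF1", "TF", "A"), ("TF1", "TF", "B"), ("TF2", "TF", "A"),
            ("MIR1", "miRNA", "A"), ("MIR1", "miRNA", "B"), ("MIR1", "miRNA", "C"),
            ("TF3", "TF", "Z"),
        ])

    def test_ordering_by_target_count(self):
        ranked = rank_regulators(self.network(), ["A", "B"])
        assert ranked["TF"] == [("TF1", 2), ("TF2", 1)]
        assert ranked["miRNA"] == [("MIR1", 2)]

    def test_regulator_without_targets_excluded(self):
        ranked = rank_regulators(self.network(), ["A", "B", "C"])
        assert all(reg != "TF3" for reg, _ in ranked["TF"])

    def test_kinds_ranked_independently_with_top_n(self):
        ranked = rank_regulators(self.network(), ["A", "B", "C"], top_n=1)
        assert len(ranked["TF"]) == 1 and len(ranked["miRNA"]) == 1

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            rank_regulators(self.network(), [])
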