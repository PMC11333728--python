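"""PPI-network hub selection via topological centrality, CytoHubba-style.

Hub genes are selected from an undirected, unweighted protein–protein
interaction graph by ranking every node under seven measures — Degree,
Betweenness, Closeness (harmonic), Stress, Radiality, MNC (maximal
neighborhood component) and BottleNeck — and aggregating the per-measure
ranks.  A Dice similarity on neighbor sets, ``2|Ni ∩ Nj| / (|Ni| + |Nj|)``,
is provided for neighborhood-overlap analyses.  A bipartite
regulator→gene network can additionally be ranked by how many of a target
set each regulator (transcription factor or miRNA) hits.

Conventions (all well defined on disconnected graphs):

* betweenness and stress sum over unordered pairs ``s < t`` with both
  endpoints distinct from the scored node, unnormalized;
* closeness is harmonic, ``sum_w 1/d(v, w)``; unreachable nodes contribute 0;
* radiality is computed within the node's connected component as
  ``sum_w (diam + 1 - d(v, w)) / (n_comp - 1)``;
* MNC is the size of the largest connected component of the subgraph induced
  by the node's neighbors;
* BottleNeck builds one deterministic BFS shortest-path tree per root
  (lexicographically smallest parent) and scores a point for every tree in
  which the node's subtree holds more than a quarter of the component.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Hashable, Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

MEASURES = ("degree", "betweenness", "closeness", "stress", "radiality",
            "mnc", "bottleneck")

Measure = Literal["degree", "betweenness", "closeness", "stress", "radiality",
                  "mnc", "bottleneck"]


def build_graph(edges: Iterable[tuple[Hashable, Hashable]],
                nodes: Iterable[Hashable] = ()) -> nx.Graph:
    """Simple undirected graph from an edge list; self-loops rejected."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in edges:
        if u == v:
            raise ValueError(f"self-loop on node {u!r} not allowed")
        g.add_edge(u, v)
    return g


def neighborhood_similarity(graph: nx.Graph, i: Hashable, j: Hashable) -> float:
    """Dice coefficient of the two nodes' neighbor sets, in [0, 1]."""
    ni = set(graph.neighbors(i))
    nj = set(graph.neighbors(j))
    denom = len(ni) + len(nj)
    if denom == 0:
        raise ValueError(f"both nodes isolated: {i!r}, {j!r}; similarity undefined")
    return 2.0 * len(ni & nj) / denom


def neighborhood_distance(graph: nx.Graph, i: Hashable, j: Hashable) -> float:
    """1 − neighborhood_similarity."""
    return 1.0 - neighborhood_similarity(graph, i, j)


# ---------------------------------------------------------------------------
# shortest-path machinery
# ---------------------------------------------------------------------------


def _bfs_counts(graph: nx.Graph, nodes: Sequence[Hashable], source_idx: int,
                index: dict[Hashable, int]) -> tuple[np.ndarray, np.ndarray]:
    """Distances and shortest-path counts from one source (unweighted BFS)."""
    n = len(nodes)
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    dist[source_idx] = 0
    sigma[source_idx] = 1
    q = deque([source_idx])
    while q:
        u = q.popleft()
        du = dist[u]
        for w in graph.neighbors(nodes[u]):
            wi = index[w]
            if np.isinf(dist[wi]):
                dist[wi] = du + 1
                q.append(wi)
            if dist[wi] == du + 1:
                sigma[wi] += sigma[u]
    return dist, sigma


def _all_pairs(graph: nx.Graph) -> tuple[list, np.ndarray, np.ndarray]:
    """All-pairs distance and shortest-path-count matrices."""
    nodes = sorted(graph.nodes, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.empty((n, n))
    sigma = np.empty((n, n))
    for i in range(n):
        dist[i], sigma[i] = _bfs_counts(graph, nodes, i, index)
    return nodes, dist, sigma


def _stress(graph: nx.Graph) -> dict:
    """stress(v) = number of shortest s–t paths through v (s < t, both != v)."""
    nodes, dist, sigma = _all_pairs(graph)
    n = len(nodes)
    out = {}
    iu, ju = np.triu_indices(n, k=1)
    for vi, v in enumerate(nodes):
        # paths s -> v -> t that are shortest: sigma_sv * sigma_vt when
        # d(s,v) + d(v,t) == d(s,t)
        with np.errstate(invalid="ignore"):
            on_path = dist[:, vi][:, None] + dist[vi, :][None, :] == dist
        counts = np.outer(sigma[:, vi], sigma[vi, :]) * on_path
        counts[vi, :] = 0
        counts[:, vi] = 0
        out[v] = float(counts[iu, ju].sum())
    return out


def _radiality(graph: nx.Graph) -> dict:
    out = {}
    for comp in nx.connected_components(graph):
        comp = list(comp)
        nc = len(comp)
        if nc == 1:
            out[comp[0]] = 0.0
            continue
        sub = graph.subgraph(comp)
        dists = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in dists.values())
        for v in comp:
            out[v] = sum(diam + 1 - d for w, d in dists[v].items() if w != v) / (nc - 1)
    return out


def _mnc(graph: nx.Graph) -> dict:
    out = {}
    for v in graph.nodes:
        nbrs = list(graph.neighbors(v))
        if not nbrs:
            out[v] = 0
            continue
        sub = graph.subgraph(nbrs)
        out[v] = max(len(c) for c in nx.connected_components(sub))
    return out


def bottleneck_scores(graph: nx.Graph) -> dict:
    """BottleNeck centrality: subtree-size votes over per-root BFS trees.

    For each root the shortest-path tree is made deterministic by assigning
    each node the lexicographically smallest eligible parent.  A node v != root
    scores a point when its subtree (v included) exceeds a quarter of its
    component's node count; the strict threshold and per-component roots
    follow the measure's usual convention.
    """
    scores = {v: 0 for v in graph.nodes}
    for comp in nx.connected_components(graph):
        comp_nodes = sorted(comp, key=str)
        nc = len(comp_nodes)
        sub = graph.subgraph(comp_nodes)
        for root in comp_nodes:
            dist = nx.single_source_shortest_path_length(sub, root)
            # deterministic parent: lexicographically smallest neighbor one
            # level up
            children: dict[Hashable, list] = {v: [] for v in comp_nodes}
            for v in comp_nodes:
                if v == root:
                    continue
                parent = min(
                    (u for u in sub.neighbors(v) if dist[u] == dist[v] - 1),
                    key=str,
                )
                children[parent].append(v)
            # subtree sizes bottom-up (by decreasing depth)
            size = {v: 1 for v in comp_nodes}
            for v in sorted(comp_nodes, key=lambda x: -dist[x]):
                for c in children[v]:
                    size[v] += size[c]
            for v in comp_nodes:
                if v != root and size[v] > nc / 4.0:
                    scores[v] += 1
    return scores


def compute_centrality(graph: nx.Graph, measure: Measure) -> dict:
    """Per-node scores for one of the seven supported measures."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if measure == "degree":
        return dict(graph.degree())
    if measure == "betweenness":
        return nx.betweenness_centrality(graph, normalized=False)
    if measure == "closeness":
        return nx.harmonic_centrality(graph)
    if measure == "stress":
        return _stress(graph)
    if measure == "radiality":
        return _radiality(graph)
    if measure == "mnc":
        return _mnc(graph)
    if measure == "bottleneck":
        return bottleneck_scores(graph)
    raise ValueError(f"unknown centrality measure {measure!r}")


@dataclass
class CentralityTable:
    """Per-node scores under all seven measures."""

    table: pd.DataFrame  # index: node, columns: MEASURES

    def ranks(self) -> pd.DataFrame:
        """Descending ranks per measure; ties share the average rank."""
        return self.table.apply(lambda col: rankdata(-col.values, method="average"))


def centrality_table(graph: nx.Graph) -> CentralityTable:
    nodes = sorted(graph.nodes, key=str)
    data = {m: compute_centrality(graph, m) for m in MEASURES}
    tab = pd.DataFrame({m: [data[m][v] for v in nodes] for m in MEASURES},
                       index=pd.Index(nodes, name="node"))
    return CentralityTable(table=tab)


@dataclass
class HubSelection:
    """Aggregated hub ranking: ordered genes, per-measure ranks, k selected."""

    genes: list
    aggregate: pd.Series  # full ranking score per node (lower/higher per method)
    ranks: pd.DataFrame
    k: int
    method: str


def select_hubs(graph: nx.Graph, k: int = 10,
                method: Literal["mean_rank", "topk_count"] = "mean_rank",
                table: CentralityTable | None = None) -> HubSelection:
    """Top-k hub nodes by aggregating the seven centrality measures.

    ``mean_rank`` (default) averages each node's descending rank over the
    seven measures and keeps the k smallest; ``topk_count`` counts how often a
    node appears in a measure's top-k and keeps the k most frequent.  Ties are
    broken by higher degree, then lexicographic node id, making the ordering
    total and deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if table is None:
        table = centrality_table(graph)
    tab = table.table
    k_eff = min(k, len(tab))
    ranks = table.ranks()
    degree = tab["degree"]

    if method == "mean_rank":
        agg = ranks.mean(axis=1)
        order = sorted(tab.index, key=lambda v: (agg[v], -degree[v], str(v)))
    elif method == "topk_count":
        counts = pd.Series(0, index=tab.index, dtype=int)
        for m in MEASURES:
            top = sorted(tab.index, key=lambda v: (-tab[m][v], str(v)))[:k_eff]
            counts[top] += 1
        agg = counts
        order = sorted(tab.index, key=lambda v: (-counts[v], -degree[v], str(v)))
    else:
        raise ValueError(f"unknown hub selection method {method!r}")

    return HubSelection(genes=list(order[:k_eff]), aggregate=agg, ranks=ranks,
                        k=k_eff, method=method)


# ---------------------------------------------------------------------------
# bipartite regulator network
# ---------------------------------------------------------------------------


@dataclass
class BipartiteRegulatorNetwork:
    """Directed regulator→gene edges; regulators typed TF or miRNA."""

    edges: list[tuple[str, str, str]]  # (regulator, kind, gene)

    def __post_init__(self) -> None:
        seen = set()
        for reg, kind, gene in self.edges:
            if kind not in ("TF", "miRNA"):
                raise ValueError(f"unknown regulator kind {kind!r} for {reg!r}")
            key = (reg, gene)
            if key in seen:
                raise ValueError(f"duplicate edge {reg!r} -> {gene!r}")
            seen.add(key)

    def targets_of(self, regulator: str) -> set[str]:
        return {g for r, _, g in self.edges if r == regulator}


def rank_regulators(network: BipartiteRegulatorNetwork,
                    target_genes: Iterable[str],
                    top_n: int | None = None) -> dict[str, list[tuple[str, int]]]:
    """Order regulators by distinct targets hit, independently per kind.

    Returns ``{"TF": [(regulator, n_targets), ...], "miRNA": [...]}`` with the
    top ``top_n`` rows per kind (all rows when ``top_n`` is None); regulators
    hitting no target are excluded.  Ties are ordered lexicographically.
    """
    targets = set(target_genes)
    if not targets:
        raise ValueError("target gene set is empty")
    if not network.edges:
        raise ValueError("regulator network is empty")
    hits: dict[tuple[str, str], set[str]] = {}
    for reg, kind, gene in network.edges:
        if gene in targets:
            hits.setdefault((reg, kind), set()).add(gene)
    out: dict[str, list[tuple[str, int]]] = {"TF": [], "miRNA": []}
    for (reg, kind), genes in hits.items():
        out[kind].append((reg, len(genes)))
    for kind in out:
        out[kind].sort(key=lambda t: (-t[1], t[0]))
        if top_n is not None:
            out[kind] = out[kind][:top_n]
    return out
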