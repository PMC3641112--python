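"""Interaction-network construction and bottleneck focus-hub ranking.

A pattern network is the reference interaction graph induced on the genes
of one temporal pattern (optionally expanded by first neighbors that
connect at least two pattern genes). Hubs are ranked with the bottleneck
score: for every root s in a component, build the breadth-first
shortest-path tree T_s — parents resolved deterministically as the
neighbor at depth d-1 with the smallest identifier — and call a non-root
node v a bottleneck of T_s when its subtree (v included) holds more than
|T_s| / 4 nodes. BN(v) counts the rooted trees in which v is a
bottleneck; the top-k BN nodes are the focus hubs (smaller rank = higher
confidence). Graphs are simple and undirected; directed interaction
semantics are flattened to edge presence.
"""

from __future__ import annotations

import logging
from collections import deque
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)


class NetworkError(ValueError):
    pass


def build_pattern_network(genes: Sequence[str], reference: nx.Graph,
                          expand_neighbors: bool = False) -> nx.Graph:
    """Subgraph of the reference network over one pattern's genes.

    With ``expand_neighbors`` the node set also includes reference nodes
    adjacent to at least two input genes (connectors), and the returned
    graph is the reference graph induced on the expanded node set. Input
    genes present in the reference but without any induced edge remain as
    singletons (count logged); genes absent from the reference are
    dropped, and an empty intersection is an error.
    """
    present = [g for g in genes if g in reference]
    if not present:
        raise NetworkError("no input gene matches a reference network node")
    nodes = set(present)
    if expand_neighbors:
        for node in reference.nodes:
            if node in nodes:
                continue
            if sum(1 for nb in reference.neighbors(node) if nb in nodes) >= 2:
                nodes.add(node)
    sub = reference.subgraph(nodes).copy()
    isolated = [g for g in present if sub.degree(g) == 0]
    if isolated:
        log.info("%d pattern genes are singletons in the network", len(isolated))
    return sub


# ---------------------------------------------------------------------------
# bottleneck scores


def _bfs_tree_parents(adj: Mapping[str, list[str]], root: str
                      ) -> dict[str, str]:
    """Parent map of the deterministic BFS shortest-path tree from root.

    Each non-root node's parent is its smallest-identifier neighbor at
    the previous depth, which makes the tree unique.
    """
    depth = {root: 0}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in depth:
                depth[v] = depth[u] + 1
                queue.append(v)
    parents: dict[str, str] = {}
    for v, d in depth.items():
        if v == root:
            continue
        parents[v] = min(u for u in adj[v] if depth.get(u) == d - 1)
    return parents


def bottleneck_scores(network: nx.Graph) -> pd.Series:
    """BN score per node: rooted shortest-path trees where it is a bottleneck.

    Computed per connected component; isolated nodes score 0. A node is a
    bottleneck of a rooted tree when its subtree (itself included) has
    strictly more than a quarter of the tree's nodes and it is not the
    root.
    """
    scores = {node: 0 for node in network.nodes}
    adj = {u: sorted(network.neighbors(u)) for u in network.nodes}
    for component in nx.connected_components(network):
        comp = sorted(component)
        size = len(comp)
        if size == 1:
            continue
        threshold = size / 4.0
        for root in comp:
            parents = _bfs_tree_parents(adj, root)
            subtree = {v: 1 for v in comp}
            # accumulate subtree sizes bottom-up by walking parent chains
            order = sorted(parents, key=lambda v: -_depth_of(parents, v))
            for v in order:
                subtree[parents[v]] += subtree[v]
            for v in parents:  # non-root nodes
                if subtree[v] > threshold:
                    scores[v] += 1
    return pd.Series(scores, name="bn").sort_index()


def _depth_of(parents: Mapping[str, str], v: str) -> int:
    d = 0
    while v in parents:
        v = parents[v]
        d += 1
    return d


def rank_top_hubs(scores: pd.Series | Mapping[str, int], k: int = 20
                  ) -> pd.DataFrame:
    """Top-k focus hubs by descending BN score, ties by identifier.

    Ranks run 1..k (smaller = higher confidence); if the graph has fewer
    than k nodes, all nodes are ranked.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    s = pd.Series(scores, name="bn")
    if s.empty:
        raise ValueError("no scored nodes to rank")
    ordered = (s.rename_axis("node").reset_index()
               .sort_values(["bn", "node"], ascending=[False, True],
                            kind="stable")
               .head(k))
    ordered["rank"] = range(1, len(ordered) + 1)
    return ordered.set_index("node")


def hub_ranking(network: nx.Graph, k: int = 20) -> pd.DataFrame:
    """BN scores, ranks and component ids for the top-k focus hubs."""
    scores = bottleneck_scores(network)
    comp_of: dict[str, int] = {}
    for cid, comp in enumerate(sorted(nx.connected_components(network),
                                      key=lambda c: sorted(c)[0])):
        for node in comp:
            comp_of[node] = cid
    ranking = rank_top_hubs(scores, k)
    ranking["component"] = [comp_of[n] for n in ranking.index]
    return ranking


def merge_networks(networks: Iterable[nx.Graph]) -> nx.Graph:
    """Node and edge union of several networks (duplicate edges collapse)."""
    networks = list(networks)
    if len(networks) < 2:
        raise ValueError("need at least two networks to merge")
    return nx.compose_all(networks)
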