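"""Steiner trees connecting AS-impacted genes inside the SAS network.

The workhorse is the shortest-path (Takahashi-Matsuyama) approximation:
grow the tree from one terminal, repeatedly attaching the terminal whose
shortest path to the current tree is cheapest, then prune with a minimum
spanning tree and iterative removal of non-terminal leaves.  An exact
solver (Dreyfus-Wagner dynamic program over terminal subsets) is
provided for validation on small instances.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx

__all__ = [
    "SteinerTree",
    "steiner_sp_approx",
    "steiner_exact",
    "tree_composition",
    "DisconnectedTerminalsError",
]


class DisconnectedTerminalsError(ValueError):
    """Terminals span more than one connected component."""


@dataclass
class SteinerTree:
    terminals: set[str]
    nodes: set[str]
    edges: list[tuple[str, str]]
    weights: dict[tuple[str, str], float]

    @property
    def total_weight(self) -> float:
        return sum(self.weights.values())

    def steiner_nodes(self) -> set[str]:
        return self.nodes - self.terminals

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for u, v in self.edges:
            g.add_edge(u, v, weight=self.weights[(u, v)])
        return g


def _as_tree(graph: nx.Graph, nodes: set[str], terminals: set[str],
             weight: str) -> SteinerTree:
    """MST of the induced sub-graph, then drop non-terminal leaves."""
    sub = nx.minimum_spanning_tree(graph.subgraph(nodes), weight=weight)
    changed = True
    while changed:
        changed = False
        for v in [v for v in sub.nodes if sub.degree(v) <= 1 and v not in terminals]:
            sub.remove_node(v)
            changed = True
    edges = [tuple(sorted((u, v))) for u, v in sub.edges()]
    weights = {
        e: float(graph[e[0]][e[1]].get(weight, 1.0)) for e in edges
    }
    return SteinerTree(set(terminals), set(sub.nodes), sorted(edges), weights)


def steiner_sp_approx(
    graph: nx.Graph,
    terminals: set[str],
    seed: int | None = None,
    weight: str = "weight",
    partial: bool = False,
) -> SteinerTree | list[SteinerTree]:
    """Shortest-path Steiner approximation.

    Starts from one terminal (lexicographically smallest when ``seed`` is
    None, otherwise drawn with the seed), attaches the closest remaining
    terminal via its shortest path until all are connected, then prunes.
    Terminals in several components raise
    :class:`DisconnectedTerminalsError` unless ``partial`` is set, in
    which case one tree per component is returned with a warning.
    """
    terminals = {str(t) for t in terminals}
    missing = terminals - set(graph.nodes)
    if missing:
        raise KeyError(f"terminals absent from graph: {sorted(missing)}")
    if not terminals:
        raise ValueError("empty terminal set")

    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(graph)):
        for v in comp:
            comp_of[v] = ci
    groups: dict[int, set[str]] = {}
    for t in terminals:
        groups.setdefault(comp_of[t], set()).add(t)
    if len(groups) > 1:
        if not partial:
            raise DisconnectedTerminalsError(
                f"terminals span {len(groups)} components"
            )
        warnings.warn(
            f"terminals span {len(groups)} components; returning partial trees",
            stacklevel=2,
        )
        return [
            steiner_sp_approx(graph, grp, seed=seed, weight=weight)
            for grp in sorted(groups.values(), key=lambda g: min(g))
        ]

    ordered = sorted(terminals)
    if seed is None:
        start = ordered[0]
    else:
        import numpy as np

        start = ordered[int(np.random.default_rng(seed).integers(len(ordered)))]

    tree_nodes: set[str] = {start}
    remaining = set(terminals) - {start}
    while remaining:
        # multi-source shortest paths from the current tree
        dist, paths = nx.multi_source_dijkstra(graph, tree_nodes, weight=weight)
        t = min(remaining, key=lambda v: (dist.get(v, float("inf")), v))
        tree_nodes.update(paths[t])
        remaining.discard(t)

    return _as_tree(graph, tree_nodes, terminals, weight)


def steiner_exact(
    graph: nx.Graph,
    terminals: set[str],
    weight: str = "weight",
    max_terminals: int = 12,
) -> SteinerTree:
    """Minimum Steiner tree by the Dreyfus-Wagner dynamic program.

    Exponential in the number of terminals only (3^k states), so it
    handles moderately sized graphs with small terminal sets — exactly
    the regime needed to validate the approximation.
    """
    terminals = sorted({str(t) for t in terminals})
    missing = set(terminals) - set(graph.nodes)
    if missing:
        raise KeyError(f"terminals absent from graph: {sorted(missing)}")
    k = len(terminals)
    if k == 0:
        raise ValueError("empty terminal set")
    if k > max_terminals:
        raise ValueError(
            f"{k} terminals exceed the exact-solver limit ({max_terminals}); "
            "use steiner_sp_approx"
        )
    if k == 1:
        return SteinerTree({terminals[0]}, {terminals[0]}, [], {})

    dist = dict(nx.all_pairs_dijkstra_path_length(graph, weight=weight))
    path = dict(nx.all_pairs_dijkstra_path(graph, weight=weight))
    for t in terminals:
        for u in terminals:
            if u not in dist[t]:
                raise DisconnectedTerminalsError(
                    "terminals span more than one component"
                )

    nodes = list(graph.nodes)
    INF = float("inf")
    # dp[mask][v]: min cost of a tree spanning terminals in mask plus node v
    dp = [dict.fromkeys(nodes, INF) for _ in range(1 << k)]
    back: list[dict[str, tuple]] = [{} for _ in range(1 << k)]
    for i, t in enumerate(terminals):
        for v in nodes:
            d = dist[t].get(v, INF)
            dp[1 << i][v] = d
            if d < INF:
                back[1 << i][v] = ("path", t)

    for mask in range(1, 1 << k):
        if mask & (mask - 1) == 0:
            continue
        # merge two sub-trees at the same node; canonical splits only
        # (sub keeps the lowest set bit of mask) to visit each pair once
        lowest = mask & (-mask)
        sub = (mask - 1) & mask
        while sub:
            if sub & lowest:
                other = mask ^ sub
                for v in nodes:
                    c = dp[sub][v] + dp[other][v]
                    if c < dp[mask][v]:
                        dp[mask][v] = c
                        back[mask][v] = ("merge", sub)
            sub = (sub - 1) & mask
        # extend along shortest paths (Dijkstra over precomputed dists)
        for v in nodes:
            dv = dist[v]
            base = dp[mask][v]
            if base == INF:
                continue
            for u in nodes:
                c = base + dv.get(u, INF)
                if c < dp[mask][u]:
                    dp[mask][u] = c
                    back[mask][u] = ("extend", v)

    full = (1 << k) - 1
    root = min(nodes, key=lambda v: dp[full][v])
    if dp[full][root] == INF:
        raise DisconnectedTerminalsError("terminals span more than one component")

    tree_nodes: set[str] = set()

    def expand(mask: int, v: str) -> None:
        tree_nodes.add(v)
        move = back[mask].get(v)
        if move is None:
            return
        kind, arg = move
        if kind == "path":
            tree_nodes.update(path[arg][v])
        elif kind == "merge":
            expand(arg, v)
            expand(mask ^ arg, v)
        else:  # extend from node arg
            tree_nodes.update(path[arg][v])
            expand(mask, arg)

    expand(full, root)
    return _as_tree(graph, tree_nodes, set(terminals), weight)


def tree_composition(
    tree: SteinerTree, s_network: nx.Graph | None = None
) -> dict:
    """Node counts of a Steiner tree, split by role and strand.

    When the S network is supplied, also counts its edges among terminals
    that are absent from the tree (interactions lost to anti-sense
    rewiring).
    """
    steiner_nodes = tree.steiner_nodes()
    summary = {
        "n_terminals": len(tree.terminals),
        "n_steiner": len(steiner_nodes),
        "n_steiner_sense": sum(1 for v in steiner_nodes if not v.endswith("_AS")),
        "n_steiner_antisense": sum(1 for v in steiner_nodes if v.endswith("_AS")),
        "n_nodes": len(tree.nodes),
        "n_edges": len(tree.edges),
        "total_weight": tree.total_weight,
    }
    if s_network is not None:
        tree_edges = {frozenset(e) for e in tree.edges}
        lost = [
            (u, v)
            for u, v in itertools.combinations(sorted(tree.terminals), 2)
            if s_network.has_edge(u, v) and frozenset((u, v)) not in tree_edges
        ]
        summary["s_edges_lost"] = len(lost)
        summary["s_edges_lost_list"] = lost
    return summary
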