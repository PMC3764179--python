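"""Clique-percolation community detection (CPM) on projected networks.

A k-clique community is the union of all k-cliques reachable from one
another through adjacent k-cliques, where two k-cliques are adjacent when
they share exactly k-1 nodes.  Communities may overlap; isolated nodes never
appear.  k-cliques are enumerated as size-k subsets of maximal cliques,
which is exact and fast at the scale of these networks (tens of nodes).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import networkx as nx


@dataclass(frozen=True)
class CliqueCommunity:
    k: int
    members: frozenset[str]
    cliques: tuple[frozenset[str], ...]


def maximal_cliques(graph: nx.Graph) -> list[tuple[str, ...]]:
    """All maximal cliques, deterministically sorted.

    Uses Bron-Kerbosch with pivoting; isolated nodes are reported as
    singleton cliques (the enumeration convention, distinct from CPM output
    which never contains them).
    """
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph)]
    return sorted(cliques)


def k_cliques(graph: nx.Graph, k: int) -> list[frozenset[str]]:
    """All complete subgraphs on exactly k nodes, each reported once."""
    if k < 2:
        raise ValueError(f"clique size k must be >= 2, got {k}")
    found: set[frozenset[str]] = set()
    for clique in nx.find_cliques(graph):
        if len(clique) >= k:
            for subset in combinations(sorted(clique), k):
                found.add(frozenset(subset))
    return sorted(found, key=lambda c: tuple(sorted(c)))


def cpm_communities(graph: nx.Graph, k: int) -> list[CliqueCommunity]:
    """Fixed-k clique-percolation communities.

    Builds the clique graph whose nodes are the k-cliques and whose edges
    join cliques sharing exactly k-1 nodes; communities are its connected
    components, reported with both their member union and composing cliques.
    Output order is deterministic (by sorted member tuple).
    """
    cliques = k_cliques(graph, k)
    if not cliques:
        return []
    # index k-cliques by their (k-1)-subsets; two cliques sharing k-1 nodes
    # have a common (k-1)-subset, and distinct cliques cannot share all k.
    clique_graph = nx.Graph()
    clique_graph.add_nodes_from(range(len(cliques)))
    by_subset: dict[frozenset[str], list[int]] = {}
    for idx, clique in enumerate(cliques):
        for subset in combinations(sorted(clique), k - 1):
            by_subset.setdefault(frozenset(subset), []).append(idx)
    for indices in by_subset.values():
        for a, b in combinations(indices, 2):
            clique_graph.add_edge(a, b)

    communities = []
    for component in nx.connected_components(clique_graph):
        comp_cliques = sorted(
            (cliques[i] for i in component), key=lambda c: tuple(sorted(c))
        )
        members = frozenset().union(*comp_cliques)
        communities.append(
            CliqueCommunity(k=k, members=members, cliques=tuple(comp_cliques))
        )
    return sorted(communities, key=lambda c: tuple(sorted(c.members)))


def cpm_sweep(
    graph: nx.Graph, ks: Sequence[int] | None = None
) -> dict[int, list[CliqueCommunity]]:
    """Communities for every k from 2 up to the largest clique size."""
    if ks is None:
        largest = max((len(c) for c in nx.find_cliques(graph)), default=0)
        ks = range(2, max(largest + 1, 2))
    return {k: cpm_communities(graph, k) for k in ks}
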