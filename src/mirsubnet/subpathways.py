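"""Subpathway mining by the distance-k clique method, plus enrichment scoring.

A subpathway of a pathway is a maximal set of genes whose pairwise
shortest-path distance in the pathway's gene graph is at most k.  These are
exactly the maximal cliques of the "closeness graph" that joins every gene
pair at distance 1..k, so mining reduces to maximal-clique enumeration on
that graph.  Enrichment of a gene set in a subpathway uses the upper-tail
hypergeometric test against a user-supplied gene universe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .io import PathwayGraph


@dataclass(frozen=True)
class Subpathway:
    """A mined gene set with its parent pathway and a deterministic id."""

    subpathway_id: str
    pathway_id: str
    genes: frozenset[str]


@dataclass(frozen=True)
class EnrichmentResult:
    mirna_id: str
    subpathway_id: str
    overlap: int
    pvalue: float


def distances(pathway: PathwayGraph) -> dict[str, dict[str, float]]:
    """All-pairs shortest-path lengths with unit edge weights.

    Returns a nested mapping ``d[u][v]`` defined for every ordered gene pair;
    unreachable pairs map to ``math.inf`` and ``d[u][u] == 0``.
    """
    graph = pathway.graph
    nodes = list(graph.nodes)
    reachable = dict(nx.all_pairs_shortest_path_length(graph))
    return {
        u: {v: float(reachable[u].get(v, math.inf)) for v in nodes}
        for u in nodes
    }


def closeness_graph(pathway: PathwayGraph, k: int) -> nx.Graph:
    """Graph on the same genes with an edge iff 0 < distance <= k.

    ``k=1`` reproduces the pathway graph itself; ``k=0`` is edgeless; edge
    sets are monotone non-decreasing in k.
    """
    if k < 0:
        raise ValueError(f"distance parameter k must be >= 0, got {k}")
    close = nx.Graph()
    close.add_nodes_from(pathway.graph.nodes)
    if k == 0:
        return close
    for u, lengths in nx.all_pairs_shortest_path_length(pathway.graph, cutoff=k):
        for v, d in lengths.items():
            if 0 < d <= k:
                close.add_edge(u, v)
    return close


def mine_subpathways(
    pathway: PathwayGraph, k: int = 4, min_genes: int = 1
) -> list[Subpathway]:
    """Mine all subpathways of one pathway at distance parameter ``k``.

    The result is exactly the set of maximal cliques of
    :func:`closeness_graph`, each reported once, ordered by their
    lexicographically sorted gene lists and numbered ``<pathway_id>_<j>``
    with a 1-based index.  ``min_genes`` optionally drops small gene sets
    (disabled by default).
    """
    close = closeness_graph(pathway, k)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(close)]
    cliques = sorted(c for c in cliques if len(c) >= min_genes)
    return [
        Subpathway(f"{pathway.pathway_id}_{j}", pathway.pathway_id, frozenset(c))
        for j, c in enumerate(cliques, start=1)
    ]


def mine_all(
    pathways: Iterable[PathwayGraph], k: int = 4, min_genes: int = 1
) -> list[Subpathway]:
    """Mine every pathway; identical gene sets in different pathways stay
    distinct subpathways (they carry distinct ids)."""
    out: list[Subpathway] = []
    for pathway in pathways:
        out.extend(mine_subpathways(pathway, k=k, min_genes=min_genes))
    return out


def pathway_universe(pathways: Iterable[PathwayGraph]) -> frozenset[str]:
    """Default enrichment background: the union of genes across pathways."""
    genes: set[str] = set()
    for pathway in pathways:
        genes |= pathway.genes
    return frozenset(genes)


def enrich(
    target_genes: Iterable[str],
    subpathway: Subpathway,
    universe: Iterable[str],
    mirna_id: str = "",
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of a gene set in one subpathway.

    With population ``|universe|``, successes ``|subpathway genes|`` and
    draws ``|targets ∩ universe|``, the p-value is P(X >= j') for the
    observed overlap j' = ``|targets ∩ subpathway genes|`` (so j' = 0 gives
    p = 1 exactly).
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("enrichment universe must be non-empty")
    if not subpathway.genes <= universe:
        raise ValueError(
            f"subpathway {subpathway.subpathway_id} has genes outside the universe"
        )
    draws = frozenset(target_genes) & universe
    overlap = len(draws & subpathway.genes)
    if overlap == 0:
        pvalue = 1.0
    else:
        pvalue = float(
            hypergeom.sf(
                overlap - 1, len(universe), len(subpathway.genes), len(draws)
            )
        )
    return EnrichmentResult(mirna_id, subpathway.subpathway_id, overlap, min(pvalue, 1.0))


def enrich_all(
    targets: Mapping[str, Iterable[str]],
    subpathways: Sequence[Subpathway],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Enrichment of every miRNA target set against every subpathway.

    Returns a DataFrame with columns mirna, subpathway_id, overlap, pvalue,
    one row per (miRNA, subpathway) pair (including non-significant ones).
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("enrichment universe must be non-empty")
    population = len(universe)
    rows = []
    for mirna_id in sorted(targets):
        draws = frozenset(targets[mirna_id]) & universe
        n_draws = len(draws)
        for sp in subpathways:
            overlap = len(draws & sp.genes)
            if overlap == 0:
                pvalue = 1.0
            else:
                pvalue = min(
                    float(hypergeom.sf(overlap - 1, population, len(sp.genes), n_draws)),
                    1.0,
                )
            rows.append((mirna_id, sp.subpathway_id, overlap, pvalue))
    return pd.DataFrame(rows, columns=["mirna", "subpathway_id", "overlap", "pvalue"])
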