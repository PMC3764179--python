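"""One-mode projections of the bipartite network by the cumulative
hypergeometric co-regulation test.

Two miRNAs are linked when the number of subpathways they both regulate is
larger than expected if each drew its subpathways at random from the
population of n subpathways; symmetrically for subpathway pairs over the
population of miRNAs.  With neighbor counts m and i and overlap j, the
p-value is the upper tail including the observed overlap:

    p = sum_{x=j}^{min(m, i)} C(m, x) C(n-m, i-x) / C(n, i)

so j = 0 gives p = 1 and the test is symmetric in (m, i).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import pandas as pd
from scipy.stats import hypergeom

from .bipartite import BipartiteNetwork

NETWORK_COLUMNS = ["node_a", "node_b", "pvalue"]

DEFAULT_ALPHA = {"mirna": 0.01, "subpathway": 0.001}
# miRNA pairs use strict p < alpha; subpathway pairs use p <= alpha.
DEFAULT_STRICT = {"mirna": True, "subpathway": False}


@dataclass(frozen=True)
class ProjectedNetwork:
    """A significance-thresholded one-mode network (miRNA or subpathway)."""

    mode: str  # "mirna" | "subpathway"
    edges: pd.DataFrame  # node_a, node_b, pvalue (unordered pairs, a < b)
    directions: Mapping[str, str] | None = None

    @property
    def nodes(self) -> frozenset[str]:
        if not len(self.edges):
            return frozenset()
        return frozenset(self.edges["node_a"]) | frozenset(self.edges["node_b"])


def coreg_pvalue(n: int, m: int, i: int, j: int) -> float:
    """Cumulative hypergeometric co-regulation p-value P(X >= j).

    ``n`` population size, ``m`` and ``i`` the two neighbor counts, ``j``
    the shared-neighbor count.
    """
    if n < 1:
        raise ValueError(f"population size n must be >= 1, got {n}")
    if not (0 <= m <= n and 0 <= i <= n):
        raise ValueError(f"neighbor counts must be in 0..n: m={m}, i={i}, n={n}")
    if not 0 <= j <= min(m, i):
        raise ValueError(f"overlap j must be in 0..min(m, i): j={j}, m={m}, i={i}")
    if j == 0:
        return 1.0
    return min(float(hypergeom.sf(j - 1, n, m, i)), 1.0)


def project(
    net: BipartiteNetwork,
    mode: str,
    alpha: float | None = None,
    n_convention: str = "observed_nodes",
    n_total: int | None = None,
    strict: bool | None = None,
) -> ProjectedNetwork:
    """Project the bipartite network onto miRNA or subpathway nodes.

    Every unordered pair of same-mode nodes with at least one shared
    neighbor is tested; pairs passing the threshold are retained.  The
    population size n follows ``n_convention``:

    - ``observed_nodes``: distinct nodes of the *other* mode present in the
      bipartite network (e.g. distinct subpathways when projecting miRNAs);
    - ``all_mined`` / ``user_value``: an externally supplied total via
      ``n_total`` (e.g. the number of all mined subpathways).

    ``strict=True`` keeps p < alpha, ``strict=False`` keeps p <= alpha; the
    per-mode defaults are strict 0.01 for miRNA pairs and non-strict 0.001
    for subpathway pairs.
    """
    if mode not in ("mirna", "subpathway"):
        raise ValueError(f"unknown projection mode {mode!r}")
    if alpha is None:
        alpha = DEFAULT_ALPHA[mode]
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if strict is None:
        strict = DEFAULT_STRICT[mode]

    neighbors = net.neighbor_sets(mode)
    other = net.subpathways if mode == "mirna" else net.mirnas
    if n_convention == "observed_nodes":
        n = len(other)
    elif n_convention in ("all_mined", "user_value"):
        if n_total is None:
            raise ValueError(f"n_convention {n_convention!r} requires n_total")
        n = int(n_total)
    else:
        raise ValueError(f"unknown n_convention {n_convention!r}")
    if neighbors and n < max(len(s) for s in neighbors.values()):
        raise ValueError(
            f"population n={n} smaller than a node's neighbor count"
        )

    rows = []
    for a, b in combinations(sorted(neighbors), 2):
        shared = len(neighbors[a] & neighbors[b])
        if shared == 0:
            continue  # p = 1 by identity, never significant
        p = coreg_pvalue(n, len(neighbors[a]), len(neighbors[b]), shared)
        if (p < alpha) if strict else (p <= alpha):
            rows.append((a, b, p))
    edges = pd.DataFrame(rows, columns=NETWORK_COLUMNS)
    directions = dict(net.directions) if mode == "mirna" else None
    return ProjectedNetwork(mode, edges, directions)


def degree_table(pnet: ProjectedNetwork) -> pd.DataFrame:
    """Node degrees of a projected network (sum of degrees = 2 x edges)."""
    if not len(pnet.edges):
        return pd.DataFrame(columns=["node", "degree"])
    counts = (
        pd.concat([pnet.edges["node_a"], pnet.edges["node_b"]])
        .value_counts()
        .sort_index()
    )
    return pd.DataFrame({"node": counts.index, "degree": counts.values})


def to_graph(pnet: ProjectedNetwork):
    """The projected network as an undirected networkx graph."""
    import networkx as nx

    graph = nx.Graph()
    for row in pnet.edges.itertuples(index=False):
        graph.add_edge(row.node_a, row.node_b, pvalue=float(row.pvalue))
    return graph
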