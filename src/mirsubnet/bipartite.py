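"""The significance-thresholded miRNA-subpathway bipartite network."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .subpathways import EnrichmentResult

BIPARTITE_COLUMNS = ["mirna", "subpathway_id", "pvalue"]


@dataclass(frozen=True)
class BipartiteNetwork:
    """Significant miRNA->subpathway edges plus per-miRNA direction labels.

    Node sets are implicit: only miRNAs and subpathways with at least one
    retained edge count as nodes (zero-degree subpathways are dropped).
    """

    edges: pd.DataFrame  # columns: mirna, subpathway_id, pvalue
    directions: Mapping[str, str]

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(self.edges["mirna"]) if len(self.edges) else frozenset()

    @property
    def subpathways(self) -> frozenset[str]:
        return (
            frozenset(self.edges["subpathway_id"]) if len(self.edges) else frozenset()
        )

    def neighbor_sets(self, mode: str) -> dict[str, frozenset[str]]:
        """Per-node neighbor sets on the other side of the bipartite graph."""
        if mode == "mirna":
            key, value = "mirna", "subpathway_id"
        elif mode == "subpathway":
            key, value = "subpathway_id", "mirna"
        else:
            raise ValueError(f"unknown mode {mode!r}")
        out: dict[str, frozenset[str]] = {}
        for node, group in self.edges.groupby(key):
            out[str(node)] = frozenset(group[value])
        return out


def _as_frame(
    enrichments: Sequence[EnrichmentResult] | pd.DataFrame,
) -> pd.DataFrame:
    if isinstance(enrichments, pd.DataFrame):
        return enrichments
    return pd.DataFrame(
        [(e.mirna_id, e.subpathway_id, e.pvalue) for e in enrichments],
        columns=BIPARTITE_COLUMNS,
    )


def build_bipartite(
    enrichments: Sequence[EnrichmentResult] | pd.DataFrame,
    alpha: float = 0.05,
    directions: Mapping[str, str] | None = None,
) -> BipartiteNetwork:
    """Keep exactly the enrichment results with p-value strictly below alpha.

    Every retained miRNA must carry a direction label ('up' or 'down');
    boundary p-values (p == alpha) are excluded.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    directions = dict(directions or {})
    frame = _as_frame(enrichments)
    if len(frame):
        frame = frame.loc[frame["pvalue"] < alpha, BIPARTITE_COLUMNS]
    else:
        frame = pd.DataFrame(columns=BIPARTITE_COLUMNS)
    frame = frame.reset_index(drop=True)
    retained = set(frame["mirna"]) if len(frame) else set()
    missing = {m for m in retained if directions.get(m) not in ("up", "down")}
    if missing:
        raise ValueError(
            f"retained miRNAs without a direction label: {sorted(missing)}"
        )
    return BipartiteNetwork(frame, directions)


def split_by_direction(
    net: BipartiteNetwork,
) -> tuple[BipartiteNetwork, BipartiteNetwork]:
    """Partition edges into the upregulated and downregulated sub-networks.

    Subpathway nodes may appear in both halves; the edge sets partition the
    total network exactly.
    """
    labels = net.edges["mirna"].map(lambda m: net.directions[m])
    up = net.edges[labels == "up"].reset_index(drop=True)
    down = net.edges[labels == "down"].reset_index(drop=True)
    return (
        BipartiteNetwork(up, net.directions),
        BipartiteNetwork(down, net.directions),
    )


def bipartite_degrees(net: BipartiteNetwork) -> pd.DataFrame:
    """Per-node degrees: a miRNA's degree is its number of linked subpathways
    and vice versa.  Degree sums on both sides equal the edge count."""
    if not len(net.edges):
        return pd.DataFrame(columns=["node", "side", "degree"])
    mirna_deg = net.edges.groupby("mirna").size()
    sp_deg = net.edges.groupby("subpathway_id").size()
    rows = [(m, "mirna", int(d)) for m, d in mirna_deg.items()]
    rows += [(s, "subpathway", int(d)) for s, d in sp_deg.items()]
    return pd.DataFrame(rows, columns=["node", "side", "degree"])
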