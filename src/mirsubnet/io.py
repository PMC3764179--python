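"""Readers and writers for every external artifact of the pipeline.

All formats are plain tab-delimited text so they can be produced and consumed
by anything (including Cytoscape via the SIF/GraphML exports).  Identifiers
are opaque strings and are never case-folded or otherwise rewritten; p-values
are serialized with six significant digits while in-memory comparisons always
use full precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

log = logging.getLogger(__name__)

PVALUE_FORMAT = "{:.6g}"

NETWORK_COLUMNS = ["node_a", "node_b", "pvalue"]
SIF_RELATION = "coreg"


class ParseError(ValueError):
    """A malformed line in an input file (message names the line number)."""


@dataclass(frozen=True)
class PathwayGraph:
    """One pathway as an undirected gene graph.

    Nodes are gene identifiers; edges are unordered gene pairs.  Self-loops
    are never stored (they are dropped at parse time with a warning).
    """

    pathway_id: str
    graph: nx.Graph = field(compare=False)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.graph.edges)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"PathwayGraph({self.pathway_id!r}, "
            f"{self.graph.number_of_nodes()} genes, "
            f"{self.graph.number_of_edges()} edges)"
        )


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-sample expression with a tumor/normal tag per sample."""

    values: pd.DataFrame  # genes x samples, strictly positive by contract
    condition: pd.Series  # sample -> "tumor" | "normal"

    def __post_init__(self) -> None:
        unknown = set(self.condition.unique()) - {"tumor", "normal"}
        if unknown:
            raise ValueError(f"unknown sample conditions: {sorted(unknown)}")
        if list(self.values.columns) != list(self.condition.index):
            raise ValueError("condition index must match sample columns")

    @property
    def tumor(self) -> pd.DataFrame:
        return self.values.loc[:, self.condition == "tumor"]

    @property
    def normal(self) -> pd.DataFrame:
        return self.values.loc[:, self.condition == "normal"]


# ---------------------------------------------------------------------------
# pathway edge lists: pathway_id <TAB> gene_a <TAB> gene_b
# ---------------------------------------------------------------------------

_PATHWAY_HEADER = ["pathway_id", "gene_a", "gene_b"]


def read_pathways(path: str | Path) -> list[PathwayGraph]:
    """Read tab-delimited pathway edge lists into one graph per pathway.

    Duplicate edges collapse; self-loops are dropped (the gene is kept as an
    isolated node) with a logged warning.  An optional header line matching
    ``pathway_id<TAB>gene_a<TAB>gene_b`` is skipped.
    """
    graphs: dict[str, nx.Graph] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts == _PATHWAY_HEADER:
                continue
            if len(parts) != 3 or any(p == "" for p in parts):
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields, "
                    f"got {line!r}"
                )
            pathway_id, gene_a, gene_b = parts
            graph = graphs.setdefault(pathway_id, nx.Graph())
            if gene_a == gene_b:
                log.warning(
                    "%s: line %d: self-loop on %r in pathway %r dropped",
                    path, lineno, gene_a, pathway_id,
                )
                graph.add_node(gene_a)
            else:
                graph.add_edge(gene_a, gene_b)
    return [PathwayGraph(pid, g) for pid, g in graphs.items()]


def write_pathways(pathways: Iterable[PathwayGraph], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(_PATHWAY_HEADER) + "\n")
        for pw in pathways:
            for a, b in sorted(tuple(sorted(e)) for e in pw.graph.edges):
                handle.write(f"{pw.pathway_id}\t{a}\t{b}\n")
            for node in sorted(nx.isolates(pw.graph)):
                handle.write(f"{pw.pathway_id}\t{node}\t{node}\n")


# ---------------------------------------------------------------------------
# target prediction tables: mirna <TAB> gene <TAB> support
# ---------------------------------------------------------------------------

TARGET_COLUMNS = ["mirna", "gene", "support"]


def read_targets(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"mirna": str, "gene": str})
    missing = set(TARGET_COLUMNS) - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    table["support"] = table["support"].astype(int)
    if (table["support"] < 0).any():
        raise ParseError(f"{path}: negative support count")
    if table.duplicated(subset=["mirna", "gene"]).any():
        raise ParseError(f"{path}: duplicate (mirna, gene) rows")
    return table[TARGET_COLUMNS]


def write_targets(table: pd.DataFrame, path: str | Path) -> None:
    table[TARGET_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices: gene rows, sample columns tagged tumor/normal
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV whose header tags samples as ``name:condition``."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    samples, conditions = [], []
    for column in frame.columns:
        name, sep, condition = column.rpartition(":")
        if not sep:
            raise ParseError(
                f"{path}: sample column {column!r} lacks a ':tumor' or "
                f"':normal' tag"
            )
        samples.append(name)
        conditions.append(condition)
    frame.columns = samples
    frame.index = frame.index.astype(str)
    return ExpressionMatrix(frame, pd.Series(conditions, index=samples))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.values.copy()
    out.columns = [f"{s}:{c}" for s, c in expr.condition.items()]
    out.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# miRNA direction labels: mirna <TAB> direction
# ---------------------------------------------------------------------------

def read_directions(path: str | Path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mirna", "direction"} <= set(table.columns):
        raise ParseError(f"{path}: expected columns mirna, direction")
    bad = set(table["direction"]) - {"up", "down"}
    if bad:
        raise ParseError(f"{path}: unknown directions {sorted(bad)}")
    return dict(zip(table["mirna"], table["direction"]))


def write_directions(directions: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(directions.items()), columns=["mirna", "direction"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# subpathway tables: subpathway_id <TAB> pathway_id <TAB> comma-joined genes
# ---------------------------------------------------------------------------

def write_subpathways(subpathways: Iterable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("subpathway_id\tpathway_id\tgenes\n")
        for sp in subpathways:
            genes = ",".join(sorted(sp.genes))
            handle.write(f"{sp.subpathway_id}\t{sp.pathway_id}\t{genes}\n")


def read_subpathways(path: str | Path) -> list:
    from .subpathways import Subpathway

    table = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in table.itertuples(index=False):
        out.append(
            Subpathway(
                subpathway_id=row.subpathway_id,
                pathway_id=row.pathway_id,
                genes=frozenset(row.genes.split(",")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# bipartite / enrichment tables
# ---------------------------------------------------------------------------

BIPARTITE_COLUMNS = ["mirna", "subpathway_id", "pvalue"]
ENRICHMENT_COLUMNS = ["mirna", "subpathway_id", "overlap", "pvalue"]


def read_bipartite(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(
        path, sep="\t", dtype={"mirna": str, "subpathway_id": str}
    )
    missing = set(BIPARTITE_COLUMNS) - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return table


def write_bipartite(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["pvalue"] = out["pvalue"].map(PVALUE_FORMAT.format)
    out.to_csv(path, sep="\t", index=False)


def read_enrichment(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(
        path, sep="\t", dtype={"mirna": str, "subpathway_id": str}
    )
    missing = set(ENRICHMENT_COLUMNS) - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return table


def write_enrichment(table: pd.DataFrame, path: str | Path) -> None:
    out = table[ENRICHMENT_COLUMNS].copy()
    out["pvalue"] = out["pvalue"].map(PVALUE_FORMAT.format)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic networks (edge lists with p-value weights)
# ---------------------------------------------------------------------------

def _validate_edge_list(net: pd.DataFrame) -> pd.DataFrame:
    missing = set(NETWORK_COLUMNS) - set(net.columns)
    if missing:
        raise ValueError(f"edge list missing columns {sorted(missing)}")
    pairs = net.apply(lambda r: frozenset((r.node_a, r.node_b)), axis=1)
    if len(net) and pairs.duplicated().any():
        raise ValueError("edge list contains duplicate unordered pairs")
    if len(net) and ((net["pvalue"] <= 0) | (net["pvalue"] > 1)).any():
        raise ValueError("edge weights must be p-values in (0, 1]")
    return net[NETWORK_COLUMNS]


def write_network(net: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write an edge list as TSV, Cytoscape SIF, or GraphML.

    TSV round-trips through :func:`read_network`; SIF uses the relation tag
    ``coreg``; GraphML stores the weight as edge attribute ``pvalue``.
    """
    net = _validate_edge_list(net)
    if format == "tsv":
        out = net.copy()
        out["pvalue"] = out["pvalue"].map(PVALUE_FORMAT.format)
        out.to_csv(path, sep="\t", index=False)
    elif format == "sif":
        with open(path, "w", encoding="utf-8") as handle:
            for row in net.itertuples(index=False):
                handle.write(f"{row.node_a}\t{SIF_RELATION}\t{row.node_b}\n")
    elif format == "graphml":
        graph = nx.Graph()
        for row in net.itertuples(index=False):
            graph.add_edge(row.node_a, row.node_b, pvalue=float(row.pvalue))
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        table = pd.read_csv(
            path, sep="\t", dtype={"node_a": str, "node_b": str}
        )
        return _validate_edge_list(table)
    if format == "graphml":
        graph = nx.read_graphml(path)
        rows = [
            (a, b, float(data["pvalue"])) for a, b, data in graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=NETWORK_COLUMNS)
    raise ValueError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# patients: patient_id, expr_a, expr_b, time, event
# ---------------------------------------------------------------------------

PATIENT_COLUMNS = ["patient_id", "expr_a", "expr_b", "time", "event"]


def read_patients(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing = set(PATIENT_COLUMNS) - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if (table["time"] < 0).any():
        raise ParseError(f"{path}: negative follow-up time")
    if not set(table["event"].unique()) <= {0, 1}:
        raise ParseError(f"{path}: event flags must be 0/1")
    return table[PATIENT_COLUMNS]


def write_patients(table: pd.DataFrame, path: str | Path) -> None:
    table[PATIENT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Tunable thresholds of the analysis chain.

    Defaults are the study conditions: subpathway mining distance k=4,
    target support >=4 of 11 predictors, 1.5-fold DEG threshold, enrichment
    alpha 0.05, projection alphas 0.01 (miRNA) / 0.001 (subpathway), and
    clique percolation at k=4.
    """

    k_subpathway: int = 4
    min_programs: int = 4
    fold_change: float = 1.5
    alpha_bipartite: float = 0.05
    alpha_mm: float = 0.01
    alpha_ss: float = 0.001
    cpm_k: int = 4
    seed: int = 0


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle) or {}
    known = PipelineConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**raw)
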