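"""Degree-distribution statistics and the simple power-law fit.

The fit replicates the NetworkAnalyzer convention: ordinary least squares on
the log-log degree-distribution points (k, count) with k >= 1, reported as
y = beta * x^a.  R^2 measures linearity on the log-log data; the separate
correlation column is the Pearson correlation between the observed counts
and the fitted curve on the original scale.  This is deliberately not a
maximum-likelihood power-law estimate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .bipartite import BipartiteNetwork, bipartite_degrees
from .projection import ProjectedNetwork, degree_table


@dataclass(frozen=True)
class PowerLawFit:
    beta: float
    a: float
    r2: float
    correlation: float


def _degrees(net) -> list[int]:
    if isinstance(net, BipartiteNetwork):
        table = bipartite_degrees(net)
        return [int(d) for d in table["degree"]] if len(table) else []
    if isinstance(net, ProjectedNetwork):
        table = degree_table(net)
        return [int(d) for d in table["degree"]] if len(table) else []
    if isinstance(net, Mapping):
        return [int(d) for d in net.values()]
    if hasattr(net, "degree"):  # networkx graph
        return [int(d) for _, d in net.degree()]
    return [int(d) for d in net]


def degree_distribution(net) -> pd.DataFrame:
    """Points (k, count) of the degree distribution, degree-0 nodes excluded.

    Accepts a bipartite or projected network, a networkx graph, a mapping
    node -> degree, or a plain iterable of degrees.
    """
    counts = Counter(d for d in _degrees(net) if d >= 1)
    points = sorted(counts.items())
    return pd.DataFrame(points, columns=["k", "count"])


def fit_power_law(dist: pd.DataFrame | Iterable[tuple[int, int]]) -> PowerLawFit:
    """Least-squares power-law fit y = beta * x^a on (k, count) points.

    The line is fitted on (log k, log count); a is the slope and beta the
    exponential of the intercept.  R^2 is the coefficient of determination
    on the log-log data (defined as 1 when the fit is exact, including the
    degenerate all-counts-equal case).  Requires at least two points.
    """
    if isinstance(dist, pd.DataFrame):
        ks = np.asarray(dist["k"], dtype=float)
        counts = np.asarray(dist["count"], dtype=float)
    else:
        pairs = list(dist)
        ks = np.asarray([p[0] for p in pairs], dtype=float)
        counts = np.asarray([p[1] for p in pairs], dtype=float)
    if len(ks) < 2:
        raise ValueError("power-law fit requires at least 2 distribution points")
    if (ks <= 0).any() or (counts <= 0).any():
        raise ValueError("power-law fit requires positive coordinates")

    log_k, log_c = np.log(ks), np.log(counts)
    slope, intercept = np.polyfit(log_k, log_c, 1)
    fitted_log = slope * log_k + intercept
    ss_res = float(np.sum((log_c - fitted_log) ** 2))
    ss_tot = float(np.sum((log_c - log_c.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if np.isclose(ss_res, 0.0) else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot

    beta = float(np.exp(intercept))
    fitted = beta * ks ** slope
    if np.std(counts) == 0.0 or np.std(fitted) == 0.0:
        correlation = 1.0 if np.allclose(counts, fitted) else 0.0
    else:
        correlation = float(np.corrcoef(counts, fitted)[0, 1])
    return PowerLawFit(beta=beta, a=float(slope), r2=float(r2), correlation=correlation)


def network_summary(net, name: str = "") -> dict:
    """Node/edge counts plus the power-law fit, as one table row."""
    if isinstance(net, BipartiteNetwork):
        n_nodes = len(net.mirnas) + len(net.subpathways)
        n_edges = len(net.edges)
    else:
        n_nodes = len(net.nodes)
        n_edges = len(net.edges)
    row = {"network": name, "nodes": n_nodes, "edges": n_edges}
    dist = degree_distribution(net)
    if len(dist) >= 2:
        fit = fit_power_law(dist)
        row.update(
            beta=fit.beta, a=fit.a, r2=fit.r2, correlation=fit.correlation
        )
    else:
        row.update(beta=np.nan, a=np.nan, r2=np.nan, correlation=np.nan)
    return row
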