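"""End-to-end analysis chain over one input bundle.

Curate effective targets, mine subpathways, build the significant bipartite
miRNA-subpathway network, project it into miRNA-miRNA and
subpathway-subpathway networks, and summarize topology and clique
communities.  Every stage is the library function the tests exercise; this
module only wires them together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .bipartite import BipartiteNetwork, build_bipartite, split_by_direction
from .cpm import cpm_communities
from .io import PipelineConfig
from .projection import ProjectedNetwork, project, to_graph
from .simulate import SyntheticBundle
from .subpathways import enrich_all, pathway_universe
from .targets import call_degs, effective_targets, filter_by_support
from .topology import network_summary


@dataclass
class PipelineResult:
    degs: frozenset[str]
    effective: dict[str, frozenset[str]]
    enrichment: pd.DataFrame
    bipartite: BipartiteNetwork
    bipartite_up: BipartiteNetwork
    bipartite_down: BipartiteNetwork
    mirna_net: ProjectedNetwork
    mirna_net_up: ProjectedNetwork
    mirna_net_down: ProjectedNetwork
    subpathway_net: ProjectedNetwork | None = None
    summaries: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_pipeline(
    bundle: SyntheticBundle,
    config: PipelineConfig | None = None,
    project_subpathways: bool = True,
) -> PipelineResult:
    cfg = config or PipelineConfig()

    filtered = filter_by_support(bundle.targets, cfg.min_programs)
    degs = call_degs(bundle.expression, cfg.fold_change)
    effective = effective_targets(filtered, degs)

    universe = pathway_universe(bundle.pathways)
    enrichment = enrich_all(effective, bundle.subpathways, universe)
    bip = build_bipartite(enrichment, cfg.alpha_bipartite, bundle.directions)
    bip_up, bip_down = split_by_direction(bip)

    # miRNA pairs are tested against the population of ALL mined subpathways
    # (the pipeline mined them itself); subpathway pairs against the miRNAs
    # observed to regulate subpathways.
    n_sp = len(bundle.subpathways)
    mm = project(bip, "mirna", alpha=cfg.alpha_mm,
                 n_convention="all_mined", n_total=n_sp)
    mm_up = project(bip_up, "mirna", alpha=cfg.alpha_mm,
                    n_convention="all_mined", n_total=n_sp)
    mm_down = project(bip_down, "mirna", alpha=cfg.alpha_mm,
                      n_convention="all_mined", n_total=n_sp)
    ss = project(bip, "subpathway", alpha=cfg.alpha_ss) if project_subpathways else None

    rows = [
        network_summary(bip, "mirna-subpathway/total"),
        network_summary(bip_up, "mirna-subpathway/up"),
        network_summary(bip_down, "mirna-subpathway/down"),
        network_summary(mm, "mirna-mirna/total"),
        network_summary(mm_up, "mirna-mirna/up"),
        network_summary(mm_down, "mirna-mirna/down"),
    ]
    if ss is not None:
        rows.append(network_summary(ss, "subpathway-subpathway/total"))
    return PipelineResult(
        degs=degs,
        effective=effective,
        enrichment=enrichment,
        bipartite=bip,
        bipartite_up=bip_up,
        bipartite_down=bip_down,
        mirna_net=mm,
        mirna_net_up=mm_up,
        mirna_net_down=mm_down,
        subpathway_net=ss,
        summaries=pd.DataFrame(rows),
    )


def mirna_communities(result: PipelineResult, k: int):
    """Clique-percolation communities of the total miRNA-miRNA network."""
    return cpm_communities(to_graph(result.mirna_net), k)
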