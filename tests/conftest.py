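import networkx as nx
import pytest

from mirsubnet import PipelineConfig, PlantedGroup, SimulationConfig, simulate
from mirsubnet.io import PathwayGraph
from mirsubnet.pipeline import run_pipeline


def make_pathway(pathway_id, edges, isolated=()):
    graph = nx.Graph()
    graph.add_edges_from(edges)
    graph.add_nodes_from(isolated)
    return PathwayGraph(pathway_id, graph)


def path_pathway(n, pathway_id="p"):
    """A chain pathway v1 - v2 - ... - vn."""
    return make_pathway(
        pathway_id, [(f"v{i}", f"v{i + 1}") for i in range(1, n)]
    )


@pytest.fixture(scope="session")
def planted_cfg():
    """Desk-scale config with one planted 5-miRNA co-regulation group."""
    return SimulationConfig(
        n_pathways=6,
        genes_per_pathway=25,
        n_mirnas=8,
        n_up=5,
        n_down=3,
        planted_groups=(
            PlantedGroup(
                members=tuple(f"miR-{i:03d}" for i in range(1, 6)),
                shared_subpathways=3,
                sharing=0.9,
            ),
        ),
        background_target_rate=0.02,
        universe_size=200,
        n_targets_per_mirna=20,
        n_patients=60,
        seed=11,
    )


@pytest.fixture(scope="session")
def planted_bundle(planted_cfg):
    return simulate(planted_cfg)


@pytest.fixture(scope="session")
def planted_result(planted_bundle):
    return run_pipeline(planted_bundle, PipelineConfig())
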