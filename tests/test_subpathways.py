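"""Distance-k subpathway mining and hypergeometric enrichment.

Brute-force oracles: maximal distance-bounded gene sets by subset
enumeration, and enrichment tails by exhaustive draws over the universe.
"""

import math
from itertools import combinations

import networkx as nx
import pytest

from mirsubnet.subpathways import (
    Subpathway,
    closeness_graph,
    distances,
    enrich,
    mine_all,
    mine_subpathways,
)

from conftest import make_pathway, path_pathway


# --- independent oracles ----------------------------------------------------

def brute_force_subpathways(pathway, k):
    """All maximal gene sets with pairwise graph distance <= k, by subset
    enumeration over the power set (bitmask form)."""
    nodes = sorted(pathway.graph.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    close = [0] * n
    for u, lengths in nx.all_pairs_shortest_path_length(pathway.graph, cutoff=k):
        for v, d in lengths.items():
            if 0 < d <= k:
                close[index[u]] |= 1 << index[v]
    valid = []
    for mask in range(1, 1 << n):
        ok = True
        for i in range(n):
            if mask >> i & 1 and (mask & ~(1 << i)) & ~close[i]:
                ok = False
                break
        if ok:
            valid.append(mask)
    valid_set = set(valid)
    maximal = []
    for mask in valid:
        if not any(
            mask | (1 << i) in valid_set
            for i in range(n)
            if not mask >> i & 1
        ):
            maximal.append(frozenset(nodes[i] for i in range(n) if mask >> i & 1))
    return set(maximal)


def enumerate_enrichment_tail(population, successes, draws, observed):
    """P(overlap >= observed) by exhaustive enumeration of all draws."""
    hits = total = 0
    success_set = set(range(successes))
    for subset in combinations(range(population), draws):
        total += 1
        if len(success_set.intersection(subset)) >= observed:
            hits += 1
    return hits / total


# --- distances --------------------------------------------------------------

class TestDistances:
    def test_path_distance(self):
        d = distances(path_pathway(3))
        assert d["v1"]["v3"] == 2 and d["v1"]["v1"] == 0

    def test_disconnected_is_infinite(self):
        p = make_pathway("p", [], isolated=["a", "b"])
        d = distances(p)
        assert math.isinf(d["a"]["b"])

    def test_five_cycle_all_pairs(self):
        p = make_pathway("p", [(f"v{i}", f"v{(i % 5) + 1}") for i in range(1, 6)])
        d = distances(p)
        pair_dists = [
            d[u][v] for u, v in combinations(sorted(p.graph.nodes), 2)
        ]
        assert sorted(pair_dists) == [1, 1, 1, 1, 1, 2, 2, 2, 2, 2]
        for u in p.graph.nodes:
            for v in p.graph.nodes:
                assert d[u][v] == d[v][u]


# --- closeness graph --------------------------------------------------------

class TestClosenessGraph:
    def test_path5_k4_complete(self):
        g = closeness_graph(path_pathway(5), 4)
        assert g.number_of_edges() == 10  # K5

    def test_path6_k4_misses_only_extreme_pair(self):
        g = closeness_graph(path_pathway(6), 4)
        missing = [
            (u, v)
            for u, v in combinations(sorted(g.nodes), 2)
            if not g.has_edge(u, v)
        ]
        assert missing == [("v1", "v6")]

    def test_k0_edgeless_and_k1_identity(self):
        p = path_pathway(4)
        assert closeness_graph(p, 0).number_of_edges() == 0
        assert set(closeness_graph(p, 1).edges) == set(p.graph.edges)

    def test_monotone_in_k(self):
        p = make_pathway(
            "p", [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("b", "e")]
        )
        for k in range(4):
            smaller = {frozenset(e) for e in closeness_graph(p, k).edges}
            larger = {frozenset(e) for e in closeness_graph(p, k + 1).edges}
            assert smaller <= larger

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            closeness_graph(path_pathway(3), -1)


# --- mining -----------------------------------------------------------------

class TestMineSubpathways:
    def test_path5_single_subpathway(self):
        (sp,) = mine_subpathways(path_pathway(5), k=4)
        assert sp.genes == {"v1", "v2", "v3", "v4", "v5"}
        assert sp.subpathway_id == "p_1"

    def test_path6_two_windows(self):
        sps = mine_subpathways(path_pathway(6), k=4)
        assert [set(sp.genes) for sp in sps] == [
            {"v1", "v2", "v3", "v4", "v5"},
            {"v2", "v3", "v4", "v5", "v6"},
        ]

    def test_triangle_k1(self):
        p = make_pathway("t", [("a", "b"), ("b", "c"), ("a", "c")])
        (sp,) = mine_subpathways(p, k=1)
        assert sp.genes == {"a", "b", "c"}

    def test_connected_pathway_with_k_at_diameter_is_one_subpathway(self):
        p = make_pathway("p", [("a", "b"), ("b", "c"), ("c", "d"), ("b", "d")])
        diameter = nx.diameter(p.graph)
        sps = mine_subpathways(p, k=diameter)
        assert len(sps) == 1 and sps[0].genes == p.genes

    def test_identical_gene_sets_in_distinct_pathways_stay_distinct(self):
        p1 = make_pathway("p1", [("a", "b")])
        p2 = make_pathway("p2", [("a", "b")])
        sps = mine_all([p1, p2], k=2)
        assert {sp.subpathway_id for sp in sps} == {"p1_1", "p2_1"}
        assert all(sp.genes == {"a", "b"} for sp in sps)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng_graph = nx.gnp_random_graph(10, 0.3, seed=seed)
        p = make_pathway("r", list(rng_graph.edges), isolated=rng_graph.nodes)
        k = seed % 5 + 1
        mined = {sp.genes for sp in mine_subpathways(p, k=k)}
        assert mined == brute_force_subpathways(p, k)

    def test_mined_sets_satisfy_distance_invariant(self):
        rng_graph = nx.gnp_random_graph(12, 0.25, seed=99)
        p = make_pathway("r", list(rng_graph.edges), isolated=rng_graph.nodes)
        d = distances(p)
        for sp in mine_subpathways(p, k=3):
            for u, v in combinations(sorted(sp.genes), 2):
                assert d[u][v] <= 3


# --- enrichment -------------------------------------------------------------

class TestEnrich:
    def sp(self, genes):
        return Subpathway("s_1", "s", frozenset(genes))

    def test_zero_overlap_pvalue_one(self):
        universe = {f"g{i}" for i in range(10)}
        result = enrich({"x1", "x2"}, self.sp(["g1", "g2"]), universe)
        assert result.overlap == 0 and result.pvalue == 1.0

    def test_worked_example_66_over_252(self):
        universe = [f"g{i}" for i in range(10)]
        sp = self.sp(universe[:4])
        targets = set(universe[:3]) | {"g8", "g9"}  # 5 draws, overlap 3
        result = enrich(targets, sp, universe)
        assert result.overlap == 3
        assert result.pvalue == pytest.approx(66 / 252, abs=1e-12)

    def test_full_overlap_certain(self):
        universe = {"a", "b", "c"}
        result = enrich(universe, self.sp(universe), universe)
        assert result.pvalue == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            enrich({"a"}, self.sp([]), [])

    @pytest.mark.parametrize(
        "population,successes,draws,observed",
        [(8, 3, 4, 1), (9, 4, 4, 2), (10, 5, 6, 3), (7, 2, 5, 2), (11, 6, 3, 3)],
    )
    def test_matches_enumeration_oracle(self, population, successes, draws, observed):
        universe = [f"g{i}" for i in range(population)]
        sp = self.sp(universe[:successes])
        targets = set(universe[successes - observed : successes]) | set(
            universe[population - (draws - observed) :]
        )
        assert len(targets) == draws
        result = enrich(targets, sp, universe)
        assert result.overlap == observed
        expected = enumerate_enrichment_tail(population, successes, draws, observed)
        assert result.pvalue == pytest.approx(expected, abs=1e-12)
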