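"""Closed spatial-cluster mining: support, DFS miner vs oracles, verification."""

from itertools import combinations

import numpy as np
import pytest

from stcluster import (
    MiningParams,
    SpatialCluster,
    brute_force_spatial,
    build_cooccurrence_graph,
    mine_spatial_clusters,
    support,
    verify_cluster,
)
from conftest import graph_from_edges, make_random_graph
from test_cograph import make_tensor


def clique_support(graph, marks):
    """Third, independent support oracle: per-region clique membership in
    the thresholded correlation graph implied by the edge sets."""
    idx = sorted(graph.mark_index(m) for m in marks)
    out = set()
    for r in range(graph.n_regions):
        if all(
            r in graph.edges.get((a, b), frozenset()) for a, b in combinations(idx, 2)
        ):
            out.add(r)
    return frozenset(out)


class TestMiningParams:
    def test_min_region_count_is_ceiling(self):
        p = MiningParams(min_region_fraction=0.001)
        assert p.min_region_count(1000) == 1
        assert p.min_region_count(1001) == 2
        assert p.min_region_count(5) == 1  # never below 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_marks": 1},
            {"min_region_fraction": 0.0},
            {"min_region_fraction": 1.5},
            {"threshold": 0.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MiningParams(**kwargs)


class TestSupport:
    def test_single_pair_is_edge_set(self):
        g = graph_from_edges(("a", "b", "c"), {("a", "b"): {0, 1, 2}}, 5)
        assert support(g, {"a", "b"}) == {0, 1, 2}

    def test_missing_edge_empties_support(self):
        g = graph_from_edges(
            ("a", "b", "c"), {("a", "b"): {0, 1}, ("b", "c"): {0, 1}}, 5
        )
        assert support(g, {"a", "b", "c"}) == frozenset()

    def test_matches_per_region_clique_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            g = make_random_graph(rng, K=6, N=40)
            marks = list(rng.choice(g.marks, size=4, replace=False))
            assert support(g, marks) == clique_support(g, marks)

    def test_anti_monotone_in_marks(self):
        rng = np.random.default_rng(22)
        for _ in range(10):
            g = make_random_graph(rng, K=7, N=50)
            picks = list(rng.choice(g.marks, size=5, replace=False))
            assert support(g, picks) <= support(g, picks[:3])

    def test_unknown_mark(self):
        g = graph_from_edges(("a", "b"), {("a", "b"): {0}}, 2)
        with pytest.raises(KeyError):
            support(g, {"a", "zz"})


class TestMiner:
    def test_empty_graph_yields_nothing(self):
        g = graph_from_edges(("a", "b", "c", "d", "e"), {}, 10)
        assert mine_spatial_clusters(g, MiningParams()) == []

    def test_complete_graph_single_closed_cluster(self):
        marks = ("a", "b", "c", "d", "e")
        regions = set(range(10))
        edges = {(x, y): regions for x, y in combinations(marks, 2)}
        g = graph_from_edges(marks, edges, 10)
        params = MiningParams(min_marks=5, min_region_fraction=0.1)
        out = mine_spatial_clusters(g, params)
        assert len(out) == 1
        assert out[0].marks == frozenset(marks)
        assert out[0].regions == frozenset(regions)

    def test_single_edge_graph_brute_force(self):
        g = graph_from_edges(("a", "b", "c"), {("a", "b"): {0, 3}}, 10)
        params = MiningParams(min_marks=2, min_region_fraction=0.1)
        out = brute_force_spatial(g, params)
        assert len(out) == 1 and out[0].marks == {"a", "b"} and out[0].regions == {0, 3}

    @pytest.mark.parametrize("seed", range(20))
    def test_set_equality_with_brute_force(self, seed):
        """Oracle equivalence on random instances (K <= 8, N <= 200)."""
        rng = np.random.default_rng(1000 + seed)
        K = int(rng.integers(5, 9))
        N = int(rng.integers(50, 201))
        g = make_random_graph(rng, K, N)
        params = MiningParams(min_marks=3, min_region_fraction=0.02)
        mined = {(c.marks, c.regions) for c in mine_spatial_clusters(g, params)}
        brute = {(c.marks, c.regions) for c in brute_force_spatial(g, params)}
        assert mined == brute

    def test_brute_force_cross_validated_with_clique_oracle(self):
        """At K <= 6 the brute-force oracle agrees with a third path that
        recomputes support by per-region clique checks."""
        rng = np.random.default_rng(31)
        for _ in range(5):
            g = make_random_graph(rng, K=6, N=30)
            params = MiningParams(min_marks=3, min_region_fraction=0.05)
            for cl in brute_force_spatial(g, params):
                assert cl.regions == clique_support(g, cl.marks)

    def test_emitted_clusters_are_closed_and_fully_supported(self):
        rng = np.random.default_rng(32)
        g = make_random_graph(rng, K=8, N=100)
        params = MiningParams(min_marks=3, min_region_fraction=0.02)
        for cl in mine_spatial_clusters(g, params):
            assert cl.regions == support(g, cl.marks)  # full support
            for h in set(g.marks) - cl.marks:  # closedness
                assert support(g, cl.marks | {h}) != cl.regions

    def test_output_order_deterministic(self):
        rng = np.random.default_rng(33)
        g = make_random_graph(rng, K=7, N=80)
        params = MiningParams(min_marks=3, min_region_fraction=0.02)
        a = mine_spatial_clusters(g, params)
        b = mine_spatial_clusters(g, params)
        assert [(c.sorted_marks, c.sorted_regions) for c in a] == [
            (c.sorted_marks, c.sorted_regions) for c in b
        ]
        sizes = [len(c.regions) for c in a]
        assert sizes == sorted(sizes, reverse=True)

    def test_brute_force_guard(self):
        g = graph_from_edges(tuple(f"m{i}" for i in range(17)), {}, 5)
        with pytest.raises(ValueError, match="refused"):
            brute_force_spatial(g, MiningParams())


class TestVerifyCluster:
    def _tensor_and_graph(self):
        rng = np.random.default_rng(41)
        # plant one coherent block: marks 0..4 share a profile in regions 0..5
        data = rng.standard_normal((12, 6, 25)) * 0.01 + 1.0
        bump = np.exp(-((np.arange(25) - 12.0) ** 2) / 18.0)
        for r in range(6):
            for k in range(5):
                data[r, k] = (k + 1) * bump + rng.standard_normal(25) * 0.001
        t = make_tensor(data)
        g = build_cooccurrence_graph(t, threshold=0.9)
        return t, g

    def test_mined_clusters_pass(self):
        t, g = self._tensor_and_graph()
        params = MiningParams(min_marks=5, min_region_fraction=0.1, threshold=0.9)
        clusters = mine_spatial_clusters(g, params)
        assert clusters
        for cl in clusters:
            rep = verify_cluster(t, cl, params)
            assert rep.passed and rep.is_full_support

    def test_subset_of_support_flags_completeness(self):
        t, g = self._tensor_and_graph()
        params = MiningParams(min_marks=5, min_region_fraction=0.1, threshold=0.9)
        cl = mine_spatial_clusters(g, params)[0]
        dropped = sorted(cl.regions)[0]
        sub = SpatialCluster(
            cell_type=cl.cell_type, marks=cl.marks, regions=cl.regions - {dropped}
        )
        rep = verify_cluster(t, sub, params)
        assert rep.pairwise_ok
        assert not rep.is_full_support
        assert dropped in rep.missing_regions

    def test_invalid_cluster_fails_naming_offender(self):
        t, _ = self._tensor_and_graph()
        params = MiningParams(min_marks=2, min_region_fraction=0.05, threshold=0.9)
        bad = SpatialCluster(cell_type="c", marks=frozenset({"m0", "m5"}), regions=frozenset({11}))
        rep = verify_cluster(t, bad, params)
        assert not rep.passed
        region, pair, value = rep.failures[0]
        assert region == 11 and set(pair) == {"m0", "m5"} and not value >= 0.9
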