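import networkx as nx
import numpy as np
import pytest

from complexmap import (
    ClusteringParams,
    ComplexSet,
    ScoredNetwork,
    cluster_one,
    generate_planted_complexes,
    mcl,
    parameter_sweep,
    select_and_union,
    threshold_network,
    two_stage_cluster,
)
from complexmap.complex_clustering import (
    DEFAULT_INFLATIONS,
    DEFAULT_MAX_OVERLAPS,
    DEFAULT_DENSITIES,
    DEFAULT_SCORE_THRESHOLDS,
    DEFAULT_SELECTED_PARAMS,
    _cohesiveness,
    _merge_overlapping,
    select_tiers,
)
from complexmap.core import iter_pairs


def net(edges):
    return ScoredNetwork({tuple(sorted((a, b))): s for a, b, s in edges})


def triangle(prefix, score=1.0):
    a, b, c = f"{prefix}1", f"{prefix}2", f"{prefix}3"
    return [(a, b, score), (a, c, score), (b, c, score)]


class TestThresholdNetwork:
    def test_zero_keeps_all(self):
        g = threshold_network(net([("a", "b", 0.2), ("c", "d", 0.9)]), 0.0)
        assert g.number_of_edges() == 2

    def test_above_max_empty(self):
        with pytest.warns(UserWarning):
            g = threshold_network(net([("a", "b", 0.5)]), 0.9)
        assert g.number_of_nodes() == 0

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        edges = [(f"n{i}", f"n{i+1}", float(rng.random())) for i in range(50)]
        s = net(edges)
        counts = []
        import warnings
        for t in [0.0, 0.3, 0.6, 0.9, 1.0]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                counts.append(threshold_network(s, t).number_of_edges())
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestClusterOne:
    def test_isolated_triangle_returned(self):
        g = nx.Graph([("a", "b"), ("a", "c"), ("b", "c")])
        out = cluster_one(g, density_threshold=0.5, max_overlap=0.8, penalty=2.0)
        assert out == [frozenset("abc")]
        # cohesiveness of the full triangle at penalty 2: 3/(3+0+6)
        assert _cohesiveness(3, 0, 3, 2.0) == pytest.approx(1 / 3)

    def test_two_triangles_with_bridge_split(self):
        g = nx.Graph(
            [("a", "b"), ("a", "c"), ("b", "c"),
             ("x", "y"), ("x", "z"), ("y", "z"), ("c", "x")]
        )
        out = cluster_one(g, density_threshold=0.5, max_overlap=0.6)
        assert len(out) == 2
        assert frozenset("abc") in out and frozenset("xyz") in out

    def test_density_one_keeps_only_cliques(self):
        g = nx.Graph([("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")])
        out = cluster_one(g, density_threshold=1.0, max_overlap=0.8)
        for c in out:
            n = len(c)
            assert g.subgraph(c).number_of_edges() == n * (n - 1) // 2

    def test_merge_terminates_and_reduces_count(self):
        clusters = [frozenset("abcd"), frozenset("abce"), frozenset("abcf")]
        merged = _merge_overlapping(clusters, 0.5)
        assert len(merged) < len(clusters)
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                inter = len(merged[i] & merged[j])
                assert inter**2 / (len(merged[i]) * len(merged[j])) < 0.5


class TestMcl:
    def test_disconnected_triangles_never_mix(self):
        g = nx.Graph()
        for a, b, s in triangle("p") + triangle("q"):
            g.add_edge(a, b, weight=s)
        for inflation in (1.5, 2, 5, 11):
            out = mcl(g, inflation=inflation)
            assert sorted(map(sorted, out)) == [
                ["p1", "p2", "p3"], ["q1", "q2", "q3"]
            ]

    def test_barbell_splits_at_high_inflation(self):
        g = nx.Graph()
        for a, b, s in triangle("p") + triangle("q"):
            g.add_edge(a, b, weight=1.0)
        g.add_edge("p1", "q1", weight=0.3)
        out = mcl(g, inflation=5.0)
        assert len(out) == 2

    def test_columns_stochastic_after_every_inflation(self):
        g = nx.Graph()
        rng = np.random.default_rng(4)
        nodes = [f"n{i}" for i in range(12)]
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if rng.random() < 0.4:
                    g.add_edge(nodes[i], nodes[j], weight=float(rng.random()))
        log = []
        mcl(g, inflation=3.0, stochasticity_log=log)
        assert log and max(log) < 1e-9

    def test_partition_covers_subgraph(self):
        g = nx.path_graph(7)
        nx.set_edge_attributes(g, 1.0, "weight")
        out = mcl(g, inflation=2.0)
        assert set().union(*out) == set(g.nodes)


class TestTwoStageCluster:
    def test_perfect_indicator_scores_recover_planted_cliques(self):
        world = generate_planted_complexes(6, (3, 6), 0.0, 10, seed=51)
        scores = {}
        for c in world.complexes:
            for p in iter_pairs(c):
                scores[p] = 1.0
        network = ScoredNetwork(scores)
        out = two_stage_cluster(network, DEFAULT_SELECTED_PARAMS[0])
        expected = {c for c in world.complexes if len(c) >= 3}
        assert set(out) == expected

    def test_subthreshold_hub_removed_by_post_filter(self):
        edges = triangle("p", 0.9)
        # hub attached to the triangle only by sub-threshold edges
        edges += [("p1", "hub", 0.4), ("p2", "hub", 0.4), ("p3", "hub", 0.4)]
        out = two_stage_cluster(
            net(edges), ClusteringParams(0.5, c1_density=0.3, c1_max_overlap=0.8,
                                         mcl_inflation=2.0)
        )
        assert all("hub" not in c for c in out)

    def test_deterministic(self):
        world = generate_planted_complexes(5, (3, 5), 0.2, 10, seed=52)
        rng = np.random.default_rng(5)
        scores = {}
        for c in world.complexes:
            for p in iter_pairs(c):
                scores[p] = float(0.8 + 0.2 * rng.random())
        network = ScoredNetwork(scores)
        params = ClusteringParams(0.5, 0.3, 0.8, 2.0)
        assert two_stage_cluster(network, params) == two_stage_cluster(network, params)


class TestSweepAndUnion:
    def test_default_grids_match_published_sweep(self):
        assert len(DEFAULT_SCORE_THRESHOLDS) == 21
        assert len(DEFAULT_MAX_OVERLAPS) == 3
        assert len(DEFAULT_DENSITIES) == 5
        assert len(DEFAULT_INFLATIONS) == 9
        n = (len(DEFAULT_SCORE_THRESHOLDS) * len(DEFAULT_MAX_OVERLAPS)
             * len(DEFAULT_DENSITIES) * len(DEFAULT_INFLATIONS))
        assert n >= 1700

    def test_tier1_selected_params(self):
        p = DEFAULT_SELECTED_PARAMS[0]
        assert (p.score_threshold, p.c1_density, p.c1_max_overlap, p.mcl_inflation) == (
            1.0, 0.4, 0.6, 9)
        assert len(DEFAULT_SELECTED_PARAMS) == 5

    def test_sweep_row_count_is_grid_product(self):
        world = generate_planted_complexes(4, (3, 4), 0.0, 5, seed=53)
        scores = {p: 1.0 for c in world.complexes for p in iter_pairs(c)}
        res = parameter_sweep(
            ScoredNetwork(scores), world.complexes,
            (0.9, 0.5), (0.6,), (0.3,), (2.0, 4.0),
        )
        assert len(res) == 2 * 1 * 1 * 2

    def test_planted_cliques_max_precision_row_is_perfect(self):
        world = generate_planted_complexes(5, (3, 5), 0.0, 5, seed=54)
        scores = {p: 1.0 for c in world.complexes for p in iter_pairs(c)}
        res = parameter_sweep(
            ScoredNetwork(scores), world.complexes, (1.0,), (0.6,), (0.4,), (9.0,),
        )
        assert res["kpr_precision"].max() == pytest.approx(1.0)

    def test_union_deduplicates_to_highest_tier(self):
        world = generate_planted_complexes(4, (3, 4), 0.0, 5, seed=55)
        scores = {p: 1.0 for c in world.complexes for p in iter_pairs(c)}
        network = ScoredNetwork(scores)
        # same clustering at every tier -> union keeps each complex once
        params = tuple(ClusteringParams(1.0, 0.4, 0.6, infl) for infl in (9, 9, 4, 2, 2))
        union = select_and_union(network, params)
        assert len(union) == len(set(union.complexes))
        assert all(t == "ExtremelyHigh" for t in union.tiers)

    def test_select_tiers_orders_by_precision(self):
        import pandas as pd

        sweep = pd.DataFrame({
            "score_threshold": [0.9, 0.5, 0.1],
            "c1_density": [0.4, 0.4, 0.1],
            "c1_max_overlap": [0.6, 0.6, 0.6],
            "mcl_inflation": [2.0, 2.0, 2.0],
            "kpr_precision": [0.95, 0.7, 0.4],
            "kpr_recall": [0.2, 0.5, 0.8],
            "n_clusters": [3, 5, 9],
        })
        chosen = select_tiers(sweep, n_tiers=3)
        assert [p.score_threshold for p in chosen] == [0.9, 0.5, 0.1]
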