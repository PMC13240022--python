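"""Fate networks: core-gene intersection, topology oracles and CoreScore."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from regfate import (assemble_fate_network, build_network, core_score,
                     generate_hub_network, intersect_core_genes, topology_metrics)
from regfate.errors import ValidationError


def calls_frame(rows):
    return pd.DataFrame(rows, columns=["regulon", "state", "z", "p", "selected"])


# --------------------------------------------------------------------------
# exhaustive-path oracles
# --------------------------------------------------------------------------

def oracle_betweenness(graph: nx.DiGraph) -> dict:
    """Brute-force shortest-path counting over all ordered (s, t) pairs."""
    nodes = list(graph.nodes)
    n = len(nodes)
    scores = {v: 0.0 for v in nodes}
    for s, t in itertools.permutations(nodes, 2):
        paths = list(nx.all_shortest_paths(graph, s, t)) \
            if nx.has_path(graph, s, t) else []
        if not paths:
            continue
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            scores[v] += through / sigma
    norm = (n - 1) * (n - 2)
    return {v: (scores[v] / norm if norm else 0.0) for v in nodes}


def oracle_closeness(graph: nx.DiGraph) -> dict:
    """Incoming-path closeness with the Wasserman–Faust component scaling."""
    nodes = list(graph.nodes)
    n = len(nodes)
    out = {}
    for v in nodes:
        dists = [nx.shortest_path_length(graph, u, v) for u in nodes
                 if u != v and nx.has_path(graph, u, v)]
        r = len(dists)  # nodes that reach v
        if r == 0 or sum(dists) == 0:
            out[v] = 0.0
        else:
            out[v] = (r / sum(dists)) * (r / (n - 1))
    return out


# --------------------------------------------------------------------------
# core-gene intersection
# --------------------------------------------------------------------------

class TestIntersect:
    def test_hand_fixture(self):
        """2 regulons × 5 targets; 4 drivers under 0.05; overlap by hand."""
        regulons = {"TF1": ["a", "b", "c", "d", "e"],
                    "TF2": ["c", "d", "f", "g", "h"]}
        calls = calls_frame([("TF1", "fateX", 2.0, 0.001, True),
                             ("TF2", "fateX", 1.8, 0.002, True)])
        drivers = pd.DataFrame({
            "gene": ["a", "c", "f", "TF1", "b", "z"],
            "fate": ["fateX"] * 6,
            "fdr": [0.01, 0.02, 0.03, 0.04, 0.2, 0.01],
        })
        core = intersect_core_genes(calls, regulons, drivers, fdr_threshold=0.05)
        # by hand: candidates = {a..h} ∪ {TF1, TF2}; sub-0.05 drivers = {a, c, f, TF1, z}
        assert core["fateX"] == {"a", "c", "f", "TF1"}

    def test_zero_threshold_empties_core_sets(self):
        regulons = {"TF1": ["a", "b"]}
        calls = calls_frame([("TF1", "f0", 2.0, 0.001, True)])
        drivers = pd.DataFrame({"gene": ["a"], "fate": ["f0"], "fdr": [0.001]})
        core = intersect_core_genes(calls, regulons, drivers, fdr_threshold=0.0)
        assert core["f0"] == set()

    def test_fate_without_selected_regulons_warns_empty(self, caplog):
        regulons = {"TF1": ["a"]}
        calls = calls_frame([("TF1", "f0", 0.2, 0.9, False)])
        drivers = pd.DataFrame({"gene": ["a"], "fate": ["f0"], "fdr": [0.001]})
        with caplog.at_level("WARNING", logger="regfate"):
            core = intersect_core_genes(calls, regulons, drivers)
        assert core["f0"] == set()
        assert "no selected regulons" in caplog.text


# --------------------------------------------------------------------------
# network construction
# --------------------------------------------------------------------------

class TestBuild:
    def test_single_regulon_star(self):
        regulons = {"TF1": ["a", "b", "c", "d"]}
        calls = calls_frame([("TF1", "f0", 2.0, 0.001, True)])
        graph = build_network("f0", {"a", "b", "c"}, calls, regulons)
        assert graph.number_of_nodes() == 4
        assert graph.number_of_edges() == 3
        assert graph.nodes["TF1"]["kind"] == "TF"
        assert graph.nodes["a"]["kind"] == "target"

    def test_overlapping_regulons_deduplicate_edges(self):
        regulons = {"TF1": ["a", "b"], "TF2": ["a", "b"]}
        calls = calls_frame([("TF1", "f0", 2.0, 0.001, True),
                             ("TF2", "f0", 1.9, 0.002, True)])
        graph = build_network("f0", {"a", "b"}, calls, regulons)
        assert graph.number_of_edges() == 4  # distinct (TF, target) pairs only

    def test_tf_tf_edges_and_isolated_tf_dropped(self):
        regulons = {"TF1": ["TF2", "a"], "TF2": ["zzz"]}
        calls = calls_frame([("TF1", "f0", 2.0, 0.001, True),
                             ("TF2", "f0", 1.9, 0.002, True)])
        graph = build_network("f0", {"TF2", "a"}, calls, regulons)
        assert graph.has_edge("TF1", "TF2")
        assert graph.nodes["TF2"]["kind"] == "TF"
        assert graph.out_degree("TF2") == 0  # its own target survived nowhere

    def test_empty_core_set_gives_valid_empty_network(self):
        regulons = {"TF1": ["a"]}
        calls = calls_frame([("TF1", "f0", 2.0, 0.001, True)])
        graph, nodes = assemble_fate_network("f0", set(), calls, regulons)
        assert graph.number_of_nodes() == 0
        assert nodes.empty


# --------------------------------------------------------------------------
# topology metrics
# --------------------------------------------------------------------------

class TestTopology:
    def test_directed_star_closed_form(self):
        graph = nx.DiGraph([("TF", f"t{j}") for j in range(9)])
        table = topology_metrics(graph)
        assert table.loc["TF", "out_degree"] == 9
        assert table.loc["TF", "betweenness"] == 0.0
        assert (table.loc[[f"t{j}" for j in range(9)], "in_degree"] == 1).all()

    def test_path_betweenness(self):
        graph = nx.DiGraph([("A", "B"), ("B", "C")])
        table = topology_metrics(graph)
        assert table.loc["B", "betweenness"] == pytest.approx(0.5)

    def test_triangle_clustering(self):
        graph = nx.DiGraph([("A", "B"), ("B", "C"), ("C", "A")])
        table = topology_metrics(graph)
        np.testing.assert_allclose(table["clustering"], 1.0)

    def test_single_node_all_zero(self):
        graph = nx.DiGraph()
        graph.add_node("solo")
        table = topology_metrics(graph)
        assert (table.loc["solo"] == 0).all()

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_oracles_on_small_digraphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        graph = nx.DiGraph()
        graph.add_nodes_from([f"v{j}" for j in range(n)])
        for a, b in itertools.permutations(range(n), 2):
            if rng.random() < 0.35:
                graph.add_edge(f"v{a}", f"v{b}")
        table = topology_metrics(graph)
        bet = oracle_betweenness(graph)
        clo = oracle_closeness(graph)
        for v in graph.nodes:
            assert table.loc[v, "betweenness"] == pytest.approx(bet[v], abs=1e-9)
            assert table.loc[v, "closeness"] == pytest.approx(clo[v], abs=1e-9)


# --------------------------------------------------------------------------
# CoreScore
# --------------------------------------------------------------------------

class TestCoreScore:
    def _random_metrics(self, rng, n=12):
        return pd.DataFrame(
            rng.uniform(size=(n, 5)),
            columns=["in_degree", "out_degree", "betweenness", "closeness", "clustering"],
            index=pd.Index([f"n{j:02d}" for j in range(n)], name="node"))

    def test_corescore_sums_to_zero(self, rng):
        scored = core_score(self._random_metrics(rng))
        assert scored["corescore"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_core_set_size_is_ceiling(self, rng):
        for n in (5, 10, 13, 30):
            scored = core_score(self._random_metrics(rng, n=n), core_fraction=0.30)
            assert scored["core"].sum() == math.ceil(0.30 * n)

    def test_dominant_node_ranks_first(self, rng):
        metrics = self._random_metrics(rng)
        metrics.loc["n00"] = metrics.max() + 1.0
        scored = core_score(metrics)
        assert scored["corescore"].idxmax() == "n00"
        assert scored.loc["n00", "core"]

    def test_degenerate_metrics_tie_break_lexicographically(self, caplog):
        metrics = pd.DataFrame(
            1.0, index=pd.Index([f"x{j}" for j in range(10)], name="node"),
            columns=["in_degree", "out_degree", "betweenness", "closeness", "clustering"])
        with caplog.at_level("WARNING", logger="regfate"):
            scored = core_score(metrics, core_fraction=0.30)
        np.testing.assert_allclose(scored["corescore"], 0.0)
        assert list(scored.index[scored["core"]]) == ["x0", "x1", "x2"]
        assert "degenerate" in caplog.text

    def test_collapse_degree_variant(self, rng):
        metrics = self._random_metrics(rng)
        five = core_score(metrics, collapse_degree=False)
        four = core_score(metrics, collapse_degree=True)
        # both are valid composite scores over the same nodes
        assert five["corescore"].sum() == pytest.approx(0.0, abs=1e-9)
        assert four["corescore"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_planted_hubs_land_in_core_set(self):
        graph, hubs = generate_hub_network(n_nodes=30, n_hubs=2, seed=5)
        scored = core_score(topology_metrics(graph), core_fraction=0.30)
        core_nodes = set(scored.index[scored["core"]])
        assert hubs <= core_nodes

    def test_metrics_match_independent_brute_force(self):
        """12-node network with 2 planted hubs: the packaged metric table equals
        an independent recomputation (degrees by edge counting, centralities by
        exhaustive path enumeration)."""
        graph, hubs = generate_hub_network(n_nodes=12, n_hubs=2, seed=3)
        table = topology_metrics(graph)
        bet = oracle_betweenness(graph)
        clo = oracle_closeness(graph)
        for v in graph.nodes:
            assert table.loc[v, "in_degree"] == sum(1 for _ in graph.predecessors(v))
            assert table.loc[v, "out_degree"] == sum(1 for _ in graph.successors(v))
            assert table.loc[v, "betweenness"] == pytest.approx(bet[v], abs=1e-9)
            assert table.loc[v, "closeness"] == pytest.approx(clo[v], abs=1e-9)
        scored = core_score(table, core_fraction=0.30)
        assert hubs <= set(scored.index[scored["core"]])


class TestAssemble:
    def test_core_restricted_to_tfs_flag(self):
        regulons = {"TF1": [f"t{j}" for j in range(10)],
                    "TF2": [f"t{j}" for j in range(5, 15)]}
        calls = calls_frame([("TF1", "f0", 2.0, 0.001, True),
                             ("TF2", "f0", 1.9, 0.002, True)])
        core = {f"t{j}" for j in range(15)}
        _, nodes = assemble_fate_network("f0", core, calls, regulons,
                                         core_tfs_only=True)
        flagged = nodes[nodes["core"]]
        assert (flagged["kind"] == "TF").all()
        assert len(flagged) == math.ceil(0.30 * 2)


    def test_target_module_inherited_from_best_tf(self):
        regulons = {"TF1": ["a", "b"], "TF2": ["b", "c", "d", "e"]}
        calls = calls_frame([("TF1", "f0", 2.0, 0.001, True),
                             ("TF2", "f0", 1.9, 0.002, True)])
        modules = pd.Series({"TF1": "Module 1", "TF2": "Module 2"})
        core = {"a", "b", "c", "d", "e"}
        graph, nodes = assemble_fate_network("f0", core, calls, regulons, modules)
        # b is regulated by both TFs; it inherits the higher-CoreScore one
        better = max(["TF1", "TF2"], key=lambda tf: nodes.loc[tf, "corescore"])
        assert graph.nodes["b"]["module"] == modules[better]

    def test_assembled_network_is_deterministic(self, small_dataset):
        expression, cells, regulons, truth = small_dataset
        calls = calls_frame([(tf, state, 2.0, 0.001, True)
                             for state, tfs in truth.state_specific_regulons.items()
                             for tf in tfs])
        core = {g for tf in truth.state_specific_regulons["fate2"]
                for g in regulons[tf]}
        g1, n1 = assemble_fate_network("fate2", core, calls, regulons)
        g2, n2 = assemble_fate_network("fate2", core, calls, regulons)
        assert list(g1.edges) == list(g2.edges)
        pd.testing.assert_frame_equal(n1, n2)
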