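"""Mixing statistics, configuration-model nulls, and aura contrasts."""

import networkx as nx
import numpy as np
import pytest

from fmnet.errors import InputError, StatisticalError
from fmnet.io import ExternalNormTable
from fmnet.stats import (
    aura_contrast,
    configuration_null_ensemble,
    degree_preserving_swap,
    edge_endpoint_tau,
    kendall_tau,
    node_neighborhood_tau,
)

from oracles import brute_tau_b, neighborhood_mean_scores


def _attributed(graph, attributes):
    for node, attr in attributes.items():
        graph.nodes[node]["valence"] = attr
        graph.nodes[node]["unrated"] = False
    return graph


class TestKendallTau:
    def test_perfect_concordance(self):
        tau, _ = kendall_tau([1, 2, 3, 4], [10, 20, 30, 40])
        assert tau == pytest.approx(1.0)

    def test_perfect_discordance(self):
        tau, _ = kendall_tau([1, 2, 3, 4], [4, 3, 2, 1])
        assert tau == pytest.approx(-1.0)

    def test_constant_vector_signalled(self):
        with pytest.raises(StatisticalError, match="constant"):
            kendall_tau([1, 1, 1], [1, 2, 3])
        with pytest.raises(StatisticalError, match="constant"):
            kendall_tau([1, 2, 3], [5, 5, 5])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            kendall_tau([1, 2], [1, 2, 3])

    def test_exact_mode_bounded(self):
        with pytest.raises(InputError, match="n <= 8"):
            kendall_tau(list(range(9)), list(range(9)), method="exact")

    def test_tied_vectors_match_pair_counting_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(3, 31))
            x = rng.integers(-1, 2, size=n)
            y = rng.integers(-1, 2, size=n)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            tau, _ = kendall_tau(x, y)
            assert tau == pytest.approx(brute_tau_b(list(x), list(y)), abs=1e-12)


class TestEdgeEndpointTau:
    def test_pure_homophily_gives_tau_one(self):
        graph = nx.Graph()
        graph.add_edges_from([("p1", "p2"), ("p2", "p3"), ("n1", "n2"), ("n2", "n3")])
        attrs = {n: ("positive" if n.startswith("p") else "negative") for n in graph}
        tau, _ = edge_endpoint_tau(_attributed(graph, attrs))
        assert tau == pytest.approx(1.0)

    def test_complete_bipartite_heterophily_matches_oracle(self):
        graph = nx.complete_bipartite_graph(4, 4)
        attrs = {n: ("positive" if n < 4 else "negative") for n in graph}
        _attributed(graph, attrs)
        tau, _ = edge_endpoint_tau(graph)
        scores = {n: 1.0 if attrs[n] == "positive" else -1.0 for n in graph}
        edges = list(graph.edges())
        x = [scores[u] for u, v in edges] + [scores[v] for u, v in edges]
        y = [scores[v] for u, v in edges] + [scores[u] for u, v in edges]
        assert tau == pytest.approx(brute_tau_b(x, y), abs=1e-12)
        assert tau == pytest.approx(-1.0)

    def test_invariant_to_score_magnitude(self, toy_network):
        tau1, p1 = edge_endpoint_tau(toy_network, m=1.0)
        tau7, p7 = edge_endpoint_tau(toy_network, m=7.3)
        assert tau1 == pytest.approx(tau7, abs=1e-12)
        assert p1 == pytest.approx(p7, abs=1e-12)

    def test_single_attribute_network_signalled(self):
        graph = nx.path_graph(4)
        _attributed(graph, {n: "positive" for n in graph})
        with pytest.raises(StatisticalError, match="share one attribute"):
            edge_endpoint_tau(graph)

    def test_randomly_attributed_graph_is_calibrated(self):
        """On a fixed graph with shuffled attributes the mixing statistic
        should look null: |z| <= 2 in at least 90% of seeds."""
        graph = nx.gnm_random_graph(1000, 5000, seed=42)
        rng = np.random.default_rng(0)
        attrs = np.array(["positive", "neutral", "negative"])
        covered = 0
        n_trials = 100
        for _ in range(n_trials):
            assignment = {n: attrs[rng.integers(0, 3)] for n in graph.nodes}
            _attributed(graph, assignment)
            _, p = edge_endpoint_tau(graph)
            if p >= 0.0455:
                covered += 1
        assert covered >= 0.90 * n_trials


class TestNodeNeighborhoodTau:
    def test_two_opposite_cliques_align_perfectly(self):
        graph = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        attrs = {n: ("positive" if n < 4 else "negative") for n in graph}
        tau, _ = node_neighborhood_tau(_attributed(graph, attrs))
        assert tau == pytest.approx(1.0)

    def test_star_with_opposite_leaves_matches_oracle(self):
        graph = nx.star_graph(5)
        attrs = {0: "positive", **{n: "negative" for n in range(1, 6)}}
        tau, _ = node_neighborhood_tau(_attributed(graph, attrs))
        scores = {n: 1.0 if attrs[n] == "positive" else -1.0 for n in graph}
        pairs = neighborhood_mean_scores(list(graph.edges()), scores)
        xs = [v[0] for v in pairs.values()]
        ys = [v[1] for v in pairs.values()]
        assert tau == pytest.approx(brute_tau_b(xs, ys), abs=1e-12)
        assert tau == pytest.approx(-1.0)

    def test_edgeless_network_signalled(self):
        graph = nx.empty_graph(5)
        _attributed(graph, {n: "positive" for n in graph})
        with pytest.raises(StatisticalError):
            node_neighborhood_tau(graph)


class TestConfigurationNull:
    def test_rewiring_preserves_degrees_and_attributes(self, toy_network):
        rng = np.random.default_rng(3)
        rewired = degree_preserving_swap(toy_network, rng)
        assert dict(rewired.degree()) == dict(toy_network.degree())
        assert {n: d["valence"] for n, d in rewired.nodes(data=True)} == {
            n: d["valence"] for n, d in toy_network.nodes(data=True)
        }
        assert rewired.number_of_edges() == toy_network.number_of_edges()
        assert not any(u == v for u, v in rewired.edges())

    def test_single_edge_graph_cannot_swap(self):
        graph = nx.Graph()
        graph.add_edge("a", "b", weight=1)
        _attributed(graph, {"a": "positive", "b": "negative"})
        with pytest.raises(StatisticalError):
            degree_preserving_swap(graph, np.random.default_rng(0))

    def test_ensemble_is_seed_reproducible(self, toy_network):
        r1 = configuration_null_ensemble(toy_network, n_realisations=10, seed=11)
        r2 = configuration_null_ensemble(toy_network, n_realisations=10, seed=11)
        assert r1 == r2
        r3 = configuration_null_ensemble(toy_network, n_realisations=10, seed=12)
        assert r3.null_taus != r1.null_taus

    def test_percentile_consistent_with_null_taus(self, toy_network):
        result = configuration_null_ensemble(toy_network, n_realisations=20, seed=5)
        null = np.array(result.null_taus)
        expected = 100.0 * (
            np.sum(null < result.tau_observed)
            + 0.5 * np.sum(null == result.tau_observed)
        ) / len(null)
        assert result.percentile_of_observed == pytest.approx(expected)
        assert len(result.null_taus) == result.n_realisations

    def test_unknown_statistic_rejected(self, toy_network):
        with pytest.raises(InputError, match="unknown statistic"):
            configuration_null_ensemble(toy_network, statistic="modularity")

    def test_json_round_trip(self, toy_network, tmp_path):
        import json

        result = configuration_null_ensemble(toy_network, n_realisations=5, seed=2)
        path = result.to_json(tmp_path / "h.json")
        data = json.loads(path.read_text())
        assert data["tau_observed"] == result.tau_observed
        assert data["n_realisations"] == 5


class TestAuraContrast:
    def _network(self):
        """16 negative target words: t1..t8 in negative neighborhoods,
        t9..t16 in positive ones.  Helper words carry the auras but are
        kept out of the norm tables so the contrast groups are the targets."""
        graph = nx.Graph()
        attrs = {}
        for i in range(1, 17):
            target = f"t{i}"
            helper = f"x{i}" if i <= 8 else f"p{i}"
            graph.add_edge(target, helper, weight=1)
            attrs[target] = "negative"
            attrs[helper] = "negative" if i <= 8 else "positive"
        return _attributed(graph, attrs)

    def _targets(self, graph):
        return [w for w in graph.nodes if w.startswith("t")]

    def test_identical_measure_values_give_null_result(self):
        graph = self._network()
        norms = ExternalNormTable(
            valence={w: 2.0 for w in self._targets(graph)}, arousal={}, source="t"
        )
        result = aura_contrast(graph, norms)
        assert result.p_value == pytest.approx(1.0)
        assert result.direction == "none"

    def test_separated_measure_values_detected(self):
        graph = self._network()
        arousal = {
            w: (5.0 if int(w[1:]) <= 8 else 1.0) for w in self._targets(graph)
        }
        norms = ExternalNormTable(
            valence={w: 2.0 for w in self._targets(graph)},
            arousal=arousal,
            source="t",
        )
        result = aura_contrast(graph, norms, measure="arousal")
        assert result.direction == "condition > any"
        assert result.p_value < 0.1
        assert result.n_condition == 8
        assert result.n_any == 16

    def test_disjoint_norm_table_reports_overlap(self):
        graph = self._network()
        norms = ExternalNormTable(valence={"zzz": 3.0}, arousal={}, source="t")
        with pytest.raises(StatisticalError, match="only 0"):
            aura_contrast(graph, norms)
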