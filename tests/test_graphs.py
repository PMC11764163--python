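"""Connectivity graphs and network metrics against brute-force oracles."""

import itertools
from collections import deque

import networkx as nx
import numpy as np
import pytest

from leida_eeg.graphs import (
    ConnectivityMatrix,
    build_graph,
    characteristic_path_length,
    clustering_coefficient,
    compare_conditions,
    degree_stats,
    graph_metrics,
    modularity,
    time_average_connectivity,
)
from leida_eeg.phase import DPLSeries
from leida_eeg.stats import bonferroni_adjust

# ---------------------------------------------------------------- oracles


def brute_clustering(g: nx.Graph) -> dict:
    out = {}
    for node in g.nodes:
        nbrs = list(g.neighbors(node))
        k = len(nbrs)
        if k < 2:
            out[node] = 0.0
            continue
        links = sum(1 for u, v in itertools.combinations(nbrs, 2) if g.has_edge(u, v))
        out[node] = 2.0 * links / (k * (k - 1))
    return out


def brute_path_length(g: nx.Graph) -> float:
    nodes = list(g.nodes)
    total, count = 0, 0
    for src in nodes:
        dist = {src: 0}
        q = deque([src])
        while q:
            u = q.popleft()
            for v in g.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        if len(dist) < len(nodes):
            return float("nan")
        total += sum(d for n, d in dist.items() if n != src)
        count += len(nodes) - 1
    return total / count


def brute_modularity(g: nx.Graph, partition) -> float:
    m = g.number_of_edges()
    q = 0.0
    for u, v in itertools.combinations_with_replacement(g.nodes, 2):
        same = any(u in c and v in c for c in partition)
        if not same:
            continue
        a = 1.0 if g.has_edge(u, v) else 0.0
        q += (a - g.degree(u) * g.degree(v) / (2 * m)) / (2 * m) * (2 if u != v else 1)
    return q


def all_partitions(items):
    if len(items) == 1:
        yield [set(items)]
        return
    first, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [subset | {first}] + smaller[i + 1 :]
        yield [{first}] + smaller


def best_modularity_exhaustive(g: nx.Graph) -> float:
    return max(brute_modularity(g, p) for p in all_partitions(list(g.nodes)))


def random_graph(rng, n, p=0.4) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for u, v in itertools.combinations(range(n), 2):
        if rng.random() < p:
            g.add_edge(u, v)
    return g


def wrap(g: nx.Graph):
    from leida_eeg.graphs import ConnectivityGraph

    return ConnectivityGraph(g, "absolute", 0.0, [str(n) for n in g.nodes])


# ---------------------------------------------------------------- tests


class TestTimeAverage:
    def test_constant_slices_equal_any_slice(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 4)
        slc = np.cos(theta[:, None] - theta[None, :])
        dpl = DPLSeries(np.repeat(slc[:, :, None], 7, axis=2), list("abcd"), np.arange(7))
        cm = time_average_connectivity(dpl)
        np.testing.assert_allclose(cm.values, np.abs(slc), atol=1e-12)

    def test_alternating_antiphase_averages_to_one(self):
        t = np.arange(10)
        theta = np.vstack([np.zeros(10), np.where(t % 2 == 0, 0.0, np.pi)])
        dpl = np.cos(theta[:, None, :] - theta[None, :, :])
        cm = time_average_connectivity(DPLSeries(dpl, ["a", "b"], t))
        assert cm.values[0, 1] == pytest.approx(1.0)

    def test_matches_elementwise_mean_oracle(self, rng):
        theta = rng.uniform(-np.pi, np.pi, size=(5, 50))
        dpl = np.cos(theta[:, None, :] - theta[None, :, :])
        cm = time_average_connectivity(DPLSeries(dpl, list("abcde"), np.arange(50)))
        expected = np.abs(dpl).mean(axis=2)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(cm.values, expected, atol=1e-12)


def conn(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"c{i}" for i in range(len(values))]
    return ConnectivityMatrix(values, labels)


class TestBuildGraph:
    def test_subthreshold_matrix_gives_empty_graph(self):
        m = np.full((4, 4), 0.1)
        np.fill_diagonal(m, 1.0)
        g = build_graph(conn(m), "absolute", 0.2)
        assert g.graph.number_of_edges() == 0

    def test_absolute_threshold_counts_edges(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.25
        m[0, 2] = m[2, 0] = 0.15
        m[1, 2] = m[2, 1] = 0.05
        g = build_graph(conn(m), "absolute", 0.2)
        assert g.graph.number_of_edges() == 1
        assert g.graph.has_edge("c0", "c1")

    def test_proportional_keeps_largest_pairs(self, rng):
        vals = rng.uniform(0, 1, 10)
        m = np.eye(5)
        iu = np.triu_indices(5, 1)
        m[iu] = vals
        m += np.triu(m, 1).T
        g = build_graph(conn(m), "proportional", 0.2)
        assert g.graph.number_of_edges() == 2  # ceil(0.2 * 10)
        kept = sorted(d["weight"] for _, _, d in g.graph.edges(data=True))
        assert kept == sorted(vals)[-2:]

    def test_proportional_q1_is_complete(self, rng):
        m = np.eye(4) + 0.3
        np.fill_diagonal(m, 1.0)
        g = build_graph(conn(np.clip(m, 0, 1)), "proportional", 1.0)
        assert g.graph.number_of_edges() == 6

    def test_absolute_monotone_in_cutoff(self, rng):
        m = rng.uniform(0, 1, (6, 6))
        m = np.clip((m + m.T) / 2, 0, 1)
        np.fill_diagonal(m, 1.0)
        prev = None
        for cutoff in (0.1, 0.3, 0.5, 0.7):
            edges = set(build_graph(conn(m), "absolute", cutoff).graph.edges)
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_invalid_thresholds_rejected(self):
        m = np.eye(3)
        with pytest.raises(ValueError):
            build_graph(conn(m), "absolute", 1.5)
        with pytest.raises(ValueError):
            build_graph(conn(m), "proportional", 0.0)
        with pytest.raises(ValueError):
            build_graph(conn(m), "nonsense", 0.2)


class TestMetricOracles:
    def test_triangle_graph_clustering(self):
        per_node, avg = clustering_coefficient(wrap(nx.complete_graph(3)))
        assert all(v == 1.0 for v in per_node.values()) and avg == 1.0

    def test_star_graph_clustering_zero(self):
        per_node, avg = clustering_coefficient(wrap(nx.star_graph(3)))
        assert avg == 0.0

    def test_path_graph_characteristic_length(self):
        assert characteristic_path_length(wrap(nx.path_graph(3))) == pytest.approx(4 / 3)

    def test_isolated_node_gives_nan_path_length(self):
        g = nx.path_graph(3)
        g.add_node(99)
        assert np.isnan(characteristic_path_length(wrap(g)))

    def test_degrees_on_k3_and_empty(self):
        degs, mean = degree_stats(wrap(nx.complete_graph(3)))
        assert list(degs.values()) == [2, 2, 2] and mean == 2.0
        g = nx.Graph()
        g.add_nodes_from(range(5))
        degs, mean = degree_stats(wrap(g))
        assert mean == 0.0

    def test_metrics_match_brute_force_on_random_graphs(self):
        """cc / path length / degrees agree exactly with enumeration oracles."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            g = random_graph(rng, int(rng.integers(3, 11)), p=float(rng.uniform(0.2, 0.8)))
            w = wrap(g)
            per_node, avg = clustering_coefficient(w)
            oracle = brute_clustering(g)
            for node in g.nodes:
                assert per_node[node] == pytest.approx(oracle[node], abs=1e-12)
            cpl = characteristic_path_length(w)
            expected = brute_path_length(g)
            if np.isnan(expected):
                assert np.isnan(cpl)
            else:
                assert cpl == pytest.approx(expected, abs=1e-12)
            degs, _ = degree_stats(w)
            assert sum(degs.values()) == 2 * g.number_of_edges()  # handshake

    def test_two_triangles_modularity_half(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        q, comms = modularity(wrap(g))
        assert q == pytest.approx(0.5, abs=1e-12)
        assert {frozenset(c) for c in comms} == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}
        assert q == pytest.approx(best_modularity_exhaustive(g), abs=1e-12)

    def test_complete_graph_modularity_zero(self):
        g = nx.complete_graph(4)
        q, comms = modularity(wrap(g))
        assert q == pytest.approx(0.0, abs=1e-12)
        assert best_modularity_exhaustive(g) == pytest.approx(0.0, abs=1e-12)

    def test_greedy_modularity_bounded_by_exhaustive(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            g = random_graph(rng, 7, p=0.45)
            if g.number_of_edges() == 0:
                continue
            q, comms = modularity(wrap(g))
            # the returned Q must equal the direct formula on its partition
            assert q == pytest.approx(brute_modularity(g, comms), abs=1e-9)
            assert q <= best_modularity_exhaustive(g) + 1e-9

    def test_edgeless_graph_q_undefined(self):
        g = nx.Graph()
        g.add_nodes_from(range(3))
        q, comms = modularity(wrap(g))
        assert np.isnan(q) and len(comms) == 3

    def test_metrics_invariant_to_relabeling(self, rng):
        g = random_graph(rng, 8, 0.5)
        mapping = dict(zip(g.nodes, rng.permutation(list(g.nodes))))
        h = nx.relabel_nodes(g, {k: f"x{v}" for k, v in mapping.items()})
        for a, b in [(wrap(g), wrap(h))]:
            assert clustering_coefficient(a)[1] == pytest.approx(clustering_coefficient(b)[1])
            cpl_a, cpl_b = characteristic_path_length(a), characteristic_path_length(b)
            assert (np.isnan(cpl_a) and np.isnan(cpl_b)) or cpl_a == pytest.approx(cpl_b)
            assert degree_stats(a)[1] == degree_stats(b)[1]
            assert modularity(a)[0] == pytest.approx(modularity(b)[0])


class TestCompareConditions:
    def _records(self, rng, n, degree_shift=0.0):
        out = []
        for i in range(n):
            theta = rng.uniform(-np.pi, np.pi, size=(6, 30))
            dpl = np.cos(theta[:, None, :] - theta[None, :, :])
            rec = graph_metrics(DPLSeries(dpl, list("abcdef"), np.arange(30)), "absolute", 0.2)
            rec.mean_degree += degree_shift
            out.append(rec)
        return out

    def test_identical_record_sets_give_null_result(self, rng):
        recs = self._records(rng, 4)
        df = compare_conditions(recs, recs)
        tested = df[~df["skipped"]]
        assert np.allclose(tested["t"], 0.0)
        assert np.allclose(tested["p_raw"], 1.0)

    def test_planted_degree_shift_detected(self, rng):
        a = self._records(rng, 8)
        b = self._records(rng, 8, degree_shift=5.0)
        df = compare_conditions(a, b).set_index("metric")
        assert df.loc["mean_degree", "p_bonferroni"] < 0.05
        assert df.loc["mean_degree", "t"] > 0

    def test_bonferroni_consistent_with_stats_module(self, rng):
        a = self._records(rng, 5)
        b = self._records(rng, 5, degree_shift=1.0)
        df = compare_conditions(a, b)
        tested = df[~df["skipped"] & np.isfinite(df["p_raw"])]
        expected = bonferroni_adjust(tested["p_raw"].to_numpy())
        np.testing.assert_allclose(tested["p_bonferroni"].to_numpy(), expected, atol=1e-12)

    def test_too_few_records_rejected(self, rng):
        recs = self._records(rng, 2)
        with pytest.raises(ValueError):
            compare_conditions(recs[:1], recs)
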