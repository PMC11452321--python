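"""Per-cluster network statistics, Laplacian machinery, eigenvector centrality."""

import networkx as nx
import numpy as np
import pytest

import oracles
from oabnet.errors import ValidationError
from oabnet.metrics import (
    adjacency_and_laplacian,
    avg_degree_centrality,
    centrality_trajectory,
    edge_density,
    eigenvector_centrality,
)
from oabnet.network import PatientGraph, build_graphs


def graph_from_edges(edges, nodes):
    G = nx.Graph()
    G.add_nodes_from(nodes)
    G.add_edges_from(tuple(e) for e in edges)
    return PatientGraph(graph=G, timepoint="T0", mode="components_at_t", r_min=0.7)


def random_patient_graph(rng, n=None, p=None):
    n = n or int(rng.integers(3, 13))
    p = p if p is not None else float(rng.uniform(0.1, 0.9))
    edges = oracles.random_graph_edges(rng, n, p)
    return graph_from_edges(edges, range(n)), edges, n


class TestAvgDegreeCentrality:
    def test_complete_graph_is_one(self):
        G = nx.complete_graph(5)
        pg = graph_from_edges([frozenset(e) for e in G.edges], range(5))
        assert avg_degree_centrality(pg, [0, 1, 2]) == pytest.approx(1.0)

    def test_empty_graph_is_zero(self):
        pg = graph_from_edges([], range(4))
        assert avg_degree_centrality(pg, [0, 1]) == 0.0

    def test_path_hand_count(self):
        """Path a–b–c–d, cluster {a,b}: (1/3 + 2/3)/2 = 0.5."""
        pg = graph_from_edges(
            [frozenset(("a", "b")), frozenset(("b", "c")), frozenset(("c", "d"))],
            "abcd",
        )
        assert avg_degree_centrality(pg, ["a", "b"]) == pytest.approx(0.5)

    def test_counts_between_cluster_edges(self):
        """Degree counts all incident edges, not just within-cluster ones."""
        pg = graph_from_edges([frozenset((0, 3)), frozenset((1, 3))], range(4))
        assert avg_degree_centrality(pg, [0, 1]) == pytest.approx(1 / 3)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            pg, edges, n = random_patient_graph(rng)
            k = int(rng.integers(1, n + 1))
            members = list(rng.choice(n, size=k, replace=False))
            assert avg_degree_centrality(pg, members) == pytest.approx(
                oracles.avg_degree_centrality(edges, members, n), abs=1e-8
            )

    def test_whole_set_equals_global_density(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            pg, edges, n = random_patient_graph(rng)
            expected = 2 * len(edges) / (n * (n - 1))
            assert avg_degree_centrality(pg, range(n)) == pytest.approx(expected)

    def test_adding_edge_never_decreases_centrality(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pg, edges, n = random_patient_graph(rng, p=0.4)
            members = list(rng.choice(n, size=max(1, n // 2), replace=False))
            before = avg_degree_centrality(pg, members)
            non_edges = [
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if frozenset((i, j)) not in edges
            ]
            if not non_edges:
                continue
            u, v = non_edges[rng.integers(len(non_edges))]
            pg.graph.add_edge(u, v)
            assert avg_degree_centrality(pg, members) >= before - 1e-12

    def test_errors(self):
        pg = graph_from_edges([], range(3))
        with pytest.raises(ValidationError):
            avg_degree_centrality(pg, [])
        with pytest.raises(ValidationError):
            avg_degree_centrality(graph_from_edges([], [0]), [0])


class TestEdgeDensity:
    def test_triangle_is_one(self):
        pg = graph_from_edges(
            [frozenset((0, 1)), frozenset((1, 2)), frozenset((0, 2))], range(3)
        )
        assert edge_density(pg, [0, 1, 2]) == 1.0

    def test_singleton_cluster_is_zero(self):
        pg = graph_from_edges([frozenset((0, 1))], range(3))
        assert edge_density(pg, [0]) == 0.0
        assert edge_density(pg, []) == 0.0

    def test_triangle_minus_edge(self):
        pg = graph_from_edges([frozenset((0, 1)), frozenset((1, 2))], range(3))
        assert edge_density(pg, [0, 1, 2]) == pytest.approx(2 / 3)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            pg, edges, n = random_patient_graph(rng)
            k = int(rng.integers(1, n + 1))
            members = list(rng.choice(n, size=k, replace=False))
            assert edge_density(pg, members) == pytest.approx(
                oracles.edge_density(edges, members), abs=1e-8
            )


class TestLaplacian:
    def test_triangle_closed_form(self):
        pg = graph_from_edges(
            [frozenset((0, 1)), frozenset((1, 2)), frozenset((0, 2))], range(3)
        )
        A, D, L = adjacency_and_laplacian(pg)
        np.testing.assert_allclose(np.diag(L), [2, 2, 2])
        np.testing.assert_allclose(L - np.diag(np.diag(L)), -(1 - np.eye(3)))
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(L)), [0, 3, 3], atol=1e-9)

    def test_empty_graph_zero_laplacian(self):
        pg = graph_from_edges([], range(4))
        _, _, L = adjacency_and_laplacian(pg)
        assert np.all(L == 0.0)

    def test_rows_sum_zero_and_psd_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            pg, edges, n = random_patient_graph(rng)
            A, D, L = adjacency_and_laplacian(pg)
            Ao, Do, Lo = oracles.adjacency_degree_laplacian(edges, list(range(n)))
            np.testing.assert_allclose(A, Ao, atol=1e-12)
            np.testing.assert_allclose(L, Lo, atol=1e-12)
            np.testing.assert_allclose(L.sum(axis=1), 0.0, atol=1e-12)
            assert np.linalg.eigvalsh(L).min() > -1e-9

    def test_zero_eigenvalue_multiplicity_counts_components(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            pg, edges, n = random_patient_graph(rng, p=0.2)
            _, _, L = adjacency_and_laplacian(pg)
            n_zero = int(np.sum(np.abs(np.linalg.eigvalsh(L)) < 1e-8))
            n_comp = nx.number_connected_components(pg.graph)
            assert n_zero == n_comp


class TestEigenvectorCentrality:
    def test_complete_k4_uniform_half(self):
        G = nx.complete_graph(4)
        pg = graph_from_edges([frozenset(e) for e in G.edges], range(4))
        scores = eigenvector_centrality(pg)
        np.testing.assert_allclose(list(scores.values()), 0.5, atol=1e-8)

    def test_star_center_dominates(self):
        pg = graph_from_edges([frozenset(("c", i)) for i in range(4)], ["c", 0, 1, 2, 3])
        scores = eigenvector_centrality(pg)
        assert scores["c"] > max(scores[i] for i in range(4))

    def test_matches_dense_eigendecomposition_on_random_graphs(self):
        """Restrict to connected samples so the dense oracle and the
        largest-component convention coincide."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            pg, edges, n = random_patient_graph(rng, p=0.5)
            if not nx.is_connected(pg.graph):
                continue
            checked += 1
            ids, A = pg.adjacency()
            x_oracle, lam = oracles.eigenvector_centrality_dense(A)
            scores = eigenvector_centrality(pg)
            x = np.array([scores[i] for i in ids])
            np.testing.assert_allclose(x, x_oracle, atol=1e-8)
            np.testing.assert_allclose(A @ x, lam * x, atol=1e-8)

    def test_disconnected_graph_zeros_outside_largest_component(self):
        edges = [frozenset((0, 1)), frozenset((1, 2)), frozenset((3, 4))]
        pg = graph_from_edges(edges, range(5))
        scores = eigenvector_centrality(pg)
        assert scores[3] == scores[4] == 0.0
        assert scores[1] > 0


class TestCentralityTrajectory:
    def test_identical_graphs_give_flat_trajectories(self, study_cohort):
        pg = build_graphs(study_cohort, r_min=0.7)["T0"]
        graphs = {t: pg for t in ("T0", "T6", "T12")}
        labels = {pid: int(c) for pid, c in
                  zip(study_cohort.patient_ids, study_cohort.true_cluster)}
        tm = centrality_trajectory(graphs, labels)
        for c in set(labels.values()):
            vals = tm.frame[tm.frame["cluster"] == c]["avg_degree_centrality"]
            assert vals.nunique() == 1

    def test_values_match_per_graph_brute_force(self, study_cohort):
        graphs = build_graphs(study_cohort, r_min=0.7)
        labels = {pid: int(c) for pid, c in
                  zip(study_cohort.patient_ids, study_cohort.true_cluster)}
        tm = centrality_trajectory(graphs, labels)
        n = study_cohort.n_patients
        for t, pg in graphs.items():
            edges = {frozenset(e) for e in pg.graph.edges}
            for c in sorted(set(labels.values())):
                members = [p for p, l in labels.items() if l == c]
                assert tm.value(c, t, "avg_degree_centrality") == pytest.approx(
                    oracles.avg_degree_centrality(edges, members, n), abs=1e-8
                )
                assert tm.value(c, t, "edge_density") == pytest.approx(
                    oracles.edge_density(edges, members), abs=1e-8
                )

    def test_all_values_within_unit_interval(self, study_cohort):
        graphs = build_graphs(study_cohort, r_min=0.7)
        tm = centrality_trajectory(
            graphs,
            study_cohort.true_cluster,
            patient_ids=study_cohort.patient_ids,
        )
        assert tm.frame["avg_degree_centrality"].between(0, 1).all()
        assert tm.frame["edge_density"].between(0, 1).all()
        # one row per (cluster, timepoint)
        assert len(tm.frame) == 3 * 5

    def test_cluster_gaining_edges_shows_rising_centrality(self):
        """A cluster whose internal similarity rises over time (more edges
        at each successive timepoint) shows strictly increasing average
        degree centrality."""
        nodes = range(6)
        labels = {i: 0 if i < 3 else 1 for i in nodes}
        g1 = graph_from_edges([frozenset((3, 4))], nodes)
        g2 = graph_from_edges([frozenset((3, 4)), frozenset((0, 1))], nodes)
        g3 = graph_from_edges(
            [frozenset((3, 4)), frozenset((0, 1)), frozenset((1, 2)),
             frozenset((0, 2))],
            nodes,
        )
        tm = centrality_trajectory({"T6": g1, "T12": g2, "T18": g3}, labels)
        vals = [tm.value(0, t, "avg_degree_centrality") for t in ("T6", "T12", "T18")]
        assert vals[0] < vals[1] < vals[2]

    def test_node_set_mismatch_rejected(self, study_cohort):
        graphs = dict(build_graphs(study_cohort, r_min=0.7))
        g = graphs["T6"].graph.copy()
        g.remove_node(study_cohort.patient_ids[0])
        graphs["T6"] = PatientGraph(g, "T6", "components_at_t", 0.7)
        with pytest.raises(ValidationError, match="node set"):
            centrality_trajectory(
                graphs,
                study_cohort.true_cluster,
                patient_ids=study_cohort.patient_ids,
            )
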