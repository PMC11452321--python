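"""Per-cluster network statistics tracked over time.

Two complementary measures quantify how a patient cluster sits inside
the whole-network structure at each timepoint:

* **average degree centrality** of cluster C at time t,
  (1/|C|) Σ_{v∈C} deg(v, t)/(|V|−1) — degrees count *all* incident
  edges, within- and between-cluster, so the measure reflects how
  connected the cluster's members are to the entire cohort;
* **edge density** of C, edges of the induced subgraph divided by
  |C|(|C|−1)/2 — internal cohesion only (0 for singleton clusters).

The adjacency/Laplacian machinery (A, D, L = D − A) and power-iteration
eigenvector centrality are provided for structural analysis of the same
graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConvergenceError, ValidationError
from .network import PatientGraph


@dataclass
class TrajectoryMetrics:
    """Tidy per-(cluster, timepoint) table of network statistics."""

    frame: pd.DataFrame  # columns: timepoint, cluster, avg_degree_centrality, edge_density
    mode: str
    r_min: float

    def value(self, cluster: int, timepoint: str, column: str) -> float:
        sel = self.frame[
            (self.frame["cluster"] == cluster) & (self.frame["timepoint"] == timepoint)
        ]
        return float(sel[column].iloc[0])


def avg_degree_centrality(graph: PatientGraph, cluster_members) -> float:
    """Mean degree centrality of the members, normalised by |V|−1."""
    members = list(cluster_members)
    if not members:
        raise ValidationError("cluster is empty")
    n = graph.n_nodes
    if n < 2:
        raise ValidationError("degree centrality needs at least 2 nodes")
    node_set = set(graph.graph.nodes)
    missing = [m for m in members if m not in node_set]
    if missing:
        raise ValidationError(f"cluster member {missing[0]!r} not in graph")
    degs = [graph.graph.degree(v) for v in members]
    return float(sum(degs)) / (len(members) * (n - 1))


def edge_density(graph: PatientGraph, cluster_members) -> float:
    """Induced-subgraph edge count over |C|(|C|−1)/2; 0 when |C| <= 1."""
    members = list(cluster_members)
    node_set = set(graph.graph.nodes)
    missing = [m for m in members if m not in node_set]
    if missing:
        raise ValidationError(f"cluster member {missing[0]!r} not in graph")
    possible = len(members) * (len(members) - 1) / 2
    if possible <= 0:
        return 0.0
    sub = graph.graph.subgraph(members)
    return sub.number_of_edges() / possible


def centrality_trajectory(
    graphs: dict[str, PatientGraph],
    labels: dict[str, int] | np.ndarray,
    patient_ids: list[str] | None = None,
) -> TrajectoryMetrics:
    """Evaluate both statistics for every (cluster, timepoint) pair.

    ``labels`` maps patient id → cluster, or is an array aligned with
    ``patient_ids``.  All graphs must share one node set covering every
    labelled patient.
    """
    graphs = dict(graphs)
    if not graphs:
        raise ValidationError("no graphs supplied")
    if isinstance(labels, dict):
        label_map = dict(labels)
    else:
        if patient_ids is None:
            raise ValidationError("patient_ids required with an array of labels")
        label_map = {pid: int(l) for pid, l in zip(patient_ids, labels, strict=True)}

    node_sets = {t: set(g.graph.nodes) for t, g in graphs.items()}
    reference = next(iter(node_sets.values()))
    for t, ns in node_sets.items():
        if ns != reference:
            raise ValidationError(f"graph at {t} has a different node set")
    if set(label_map) != reference:
        raise ValidationError("cluster labels do not cover the graph node set")

    clusters = sorted(set(label_map.values()))
    members = {c: [p for p, l in label_map.items() if l == c] for c in clusters}
    first = next(iter(graphs.values()))
    rows = []
    for t, g in graphs.items():
        for c in clusters:
            rows.append(
                {
                    "timepoint": t,
                    "cluster": c,
                    "avg_degree_centrality": avg_degree_centrality(g, members[c]),
                    "edge_density": edge_density(g, members[c]),
                }
            )
    return TrajectoryMetrics(
        frame=pd.DataFrame(rows), mode=first.mode, r_min=first.r_min
    )


def adjacency_and_laplacian(
    graph: PatientGraph,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Adjacency A, degree matrix D, and Laplacian L = D − A."""
    _, A = graph.adjacency()
    D = np.diag(A.sum(axis=1))
    return A, D, D - A


def eigenvector_centrality(
    graph: PatientGraph, tol: float = 1e-10, max_iter: int = 1000
) -> dict[str, float]:
    """Eigenvector centrality by power iteration on the adjacency matrix.

    Computed on the largest connected component (zeros elsewhere); the
    iteration runs on A + I, which shares eigenvectors with A but avoids
    oscillation on bipartite components.  The result x is nonnegative,
    L2-normalised, and satisfies Ax = λx with λ the largest eigenvalue.
    """
    if graph.n_nodes == 0:
        raise ValidationError("graph is empty")
    ids, A = graph.adjacency()
    components = sorted(nx.connected_components(graph.graph), key=len, reverse=True)
    largest = components[0]
    if len(components) > 1:
        import logging

        logging.getLogger(__name__).info(
            "eigenvector centrality defined on the largest component "
            "(%d of %d nodes); zeros elsewhere",
            len(largest),
            len(ids),
        )
    index = {u: i for i, u in enumerate(ids)}
    comp_idx = np.array(sorted(index[u] for u in largest))
    Ac = A[np.ix_(comp_idx, comp_idx)]
    m = len(comp_idx)

    x = np.ones(m) / np.sqrt(m)
    if m == 1 or Ac.sum() == 0:
        converged = True
    else:
        converged = False
        for _ in range(max_iter):
            y = Ac @ x + x  # power step on A + I
            y /= np.linalg.norm(y)
            if np.abs(y - x).max() < tol:
                x = y
                converged = True
                break
            x = y
    if not converged:
        raise ConvergenceError(
            f"power iteration did not converge in {max_iter} iterations",
            iterations=max_iter,
        )
    x = np.abs(x)
    x /= np.linalg.norm(x)
    scores = np.zeros(len(ids))
    scores[comp_idx] = x
    return {ids[i]: float(scores[i]) for i in range(len(ids))}
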