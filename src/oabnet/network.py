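"""Per-timepoint patient similarity graphs.

Nodes are patients; an edge joins two patients whose symptom-score
vectors have Pearson correlation r above an explicit threshold
``r_min``, with edge length

    length = (1/r − 1) × 1000

so perfectly correlated patients sit at length 0 and length grows
without bound as r → 0⁺.  Non-positive correlations never form edges
(the formula is undefined there) and pairs involving a constant score
vector are excluded and logged.

Two correlation bases are supported:

* ``components_at_t`` (default): r between the two patients' four item
  scores (Q1..Q4) at the timepoint — each timepoint gets a genuinely
  different graph;
* ``trajectory_up_to_t``: r between total-score trajectories over all
  timepoints up to and including t.  At T0 a single timepoint gives no
  trajectory, so construction falls back to ``components_at_t`` with a
  warning.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .cohort import TIMEPOINTS, Cohort
from .errors import ConfigurationError, ConstantVectorError, ValidationError

logger = logging.getLogger(__name__)

MODES = ("components_at_t", "trajectory_up_to_t")


def edge_length(r: float) -> float:
    """Map a correlation in (0, 1] to the unitless ×1000 length scale."""
    if r <= 0:
        raise ValidationError(f"edge length undefined for r={r} <= 0")
    return (1.0 / r - 1.0) * 1000.0


def patient_similarity(a, b) -> float:
    """Pearson product-moment correlation between two score vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("score vectors must be 1-D, equal length >= 2")
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.sqrt((da**2).sum()), np.sqrt((db**2).sum())
    if na == 0 or nb == 0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    return float(np.clip((da * db).sum() / (na * nb), -1.0, 1.0))


@dataclass
class PatientGraph:
    """One timepoint's weighted patient-similarity network."""

    graph: nx.Graph
    timepoint: str
    mode: str
    r_min: float

    @property
    def node_ids(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def adjacency(self) -> tuple[list[str], np.ndarray]:
        """0/1 adjacency matrix in node order (symmetric, zero diagonal)."""
        ids = self.node_ids
        index = {u: i for i, u in enumerate(ids)}
        A = np.zeros((len(ids), len(ids)))
        for u, v in self.graph.edges:
            A[index[u], index[v]] = A[index[v], index[u]] = 1.0
        return ids, A


def build_graph(
    cohort: Cohort,
    timepoint: str,
    mode: str = "components_at_t",
    r_min: float = 0.7,
    cluster_labels: np.ndarray | None = None,
) -> PatientGraph:
    """Build the similarity graph at one timepoint.

    An edge (i, j) is included iff r_ij > r_min strictly; exact ties at
    the threshold are excluded for determinism.
    """
    if timepoint not in TIMEPOINTS:
        raise ValidationError(f"unknown timepoint {timepoint!r}")
    if mode not in MODES:
        raise ConfigurationError(f"mode must be one of {MODES}; got {mode!r}")
    if not 0.0 <= r_min < 1.0:
        raise ConfigurationError(f"r_min must lie in [0, 1); got {r_min}")

    effective_mode = mode
    if mode == "trajectory_up_to_t" and timepoint == "T0":
        warnings.warn(
            "trajectory_up_to_t needs >=2 timepoints; falling back to "
            "components_at_t for T0",
            stacklevel=2,
        )
        effective_mode = "components_at_t"

    if effective_mode == "components_at_t":
        vectors = cohort.components_at(timepoint)  # FormatError on totals-only
    else:
        upto = TIMEPOINTS[: TIMEPOINTS.index(timepoint) + 1]
        totals = cohort.totals()
        vectors = totals[:, : len(upto)]

    ids = cohort.patient_ids
    n = len(ids)
    G = nx.Graph()
    labels = None if cluster_labels is None else np.asarray(cluster_labels)
    for i, pid in enumerate(ids):
        attrs = {"patient_id": pid}
        if labels is not None:
            attrs["cluster"] = int(labels[i])
        G.add_node(pid, **attrs)

    sd = vectors.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.info(
            "%s: %d patient(s) with constant score vectors excluded from edges",
            timepoint,
            int(constant.sum()),
        )
    n_nonpositive = 0
    for i in range(n):
        if constant[i]:
            continue
        for j in range(i + 1, n):
            if constant[j]:
                continue
            r = patient_similarity(vectors[i], vectors[j])
            if r <= 0:
                n_nonpositive += 1
                continue
            if r > r_min:
                G.add_edge(ids[i], ids[j], r=r, length=edge_length(r))
    if n_nonpositive:
        logger.debug(
            "%s: %d pair(s) with non-positive correlation excluded",
            timepoint,
            n_nonpositive,
        )
    return PatientGraph(graph=G, timepoint=timepoint, mode=mode, r_min=r_min)


def build_graphs(
    cohort: Cohort,
    mode: str = "components_at_t",
    r_min: float = 0.7,
    cluster_labels: np.ndarray | None = None,
) -> dict[str, PatientGraph]:
    """One similarity graph per timepoint, keyed T0..T24."""
    return {
        t: build_graph(cohort, t, mode=mode, r_min=r_min, cluster_labels=cluster_labels)
        for t in TIMEPOINTS
    }


def write_graphml(pg: PatientGraph, path) -> None:
    nx.write_graphml(pg.graph, path)


def write_edgelist_csv(pg: PatientGraph, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["u", "v", "r", "length"])
        for u, v, data in sorted(pg.graph.edges(data=True)):
            writer.writerow([u, v, repr(data["r"]), repr(data["length"])])
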