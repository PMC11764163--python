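"""Thresholded connectivity graphs and between-condition network comparison.

Per subject and condition, the dPL tensor is collapsed into a static
connectivity matrix by time-averaging |dPL| per channel pair — a
phase-locking-value-style synchrony index in [0, 1].  The matrix is
thresholded (absolute cutoff, default 0.2, or proportional top-q fraction)
into an undirected weighted graph; topology metrics — average clustering
coefficient, characteristic path length, degree statistics, greedy
modularity — are computed on the binarized topology, with edge weights kept
as attributes.  A disconnected graph has an undefined (NaN) characteristic
path length.  Condition contrasts use a Welch t per metric with Bonferroni
adjustment over the metric family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .phase import DPLSeries
from .stats import bonferroni_adjust, two_sample_t

COMPARED_METRICS = [
    "mean_connectivity",
    "avg_clustering",
    "char_path_length",
    "mean_degree",
    "modularity_q",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N matrix of time-averaged |dPL| with unit diagonal."""

    values: np.ndarray
    channel_labels: list[str]
    subject_id: str = "S0"
    condition: str = "A"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if np.any((v < -1e-12) | (v > 1 + 1e-12)):
            raise ValueError("entries must lie in [0, 1]")
        self.values = v


@dataclass
class ConnectivityGraph:
    """Thresholded undirected weighted graph over channels."""

    graph: nx.Graph
    threshold_mode: str
    threshold_value: float
    channel_labels: list[str] = field(default_factory=list)


@dataclass
class GraphMetricsRecord:
    mean_connectivity: float
    avg_clustering: float
    char_path_length: float  # NaN when disconnected
    degrees: dict
    mean_degree: float
    modularity_q: float
    n_components: int
    subject_id: str = "S0"
    condition: str = "A"


def time_average_connectivity(dpl: DPLSeries) -> ConnectivityMatrix:
    """Entry (n, p) = mean over t of |dPL(n, p, t)|; diagonal 1."""
    mat = np.abs(dpl.dpl).mean(axis=2)
    mat = 0.5 * (mat + mat.T)
    np.fill_diagonal(mat, 1.0)
    return ConnectivityMatrix(mat, list(dpl.channel_labels), dpl.subject_id, dpl.condition)


def build_graph(
    matrix: ConnectivityMatrix, mode: str = "absolute", value: float = 0.2
) -> ConnectivityGraph:
    """Threshold a connectivity matrix into an undirected weighted graph.

    ``mode="absolute"`` keeps channel pairs whose connectivity exceeds
    ``value`` (default 0.2).  ``mode="proportional"`` keeps the
    ceil(q * N(N-1)/2) strongest pairs (q = ``value``), ties broken by
    ascending channel-index pair order.
    """
    n = matrix.values.shape[0]
    labels = matrix.channel_labels
    g = nx.Graph()
    g.add_nodes_from(labels)
    iu = np.triu_indices(n, k=1)
    weights = matrix.values[iu]
    pairs = list(zip(iu[0], iu[1]))
    if mode == "absolute":
        if not (0.0 <= value <= 1.0):
            raise ValueError("absolute cutoff must lie in [0, 1]")
        keep = [i for i, w in enumerate(weights) if w > value]
    elif mode == "proportional":
        if not (0.0 < value <= 1.0):
            raise ValueError("proportional fraction must lie in (0, 1]")
        n_keep = math.ceil(value * len(pairs))
        # sort by descending weight; ties by ascending (i, j) pair order
        order = sorted(range(len(pairs)), key=lambda i: (-weights[i], pairs[i]))
        keep = order[:n_keep]
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    for i in keep:
        a, b = pairs[i]
        g.add_edge(labels[a], labels[b], weight=float(weights[i]))
    return ConnectivityGraph(g, mode, value, list(labels))


def clustering_coefficient(graph: ConnectivityGraph) -> tuple[dict, float]:
    """Binary local clustering coefficient per node and its average.

    Nodes with degree < 2 score 0.  Weights are ignored (binary topology).
    """
    cc = nx.clustering(graph.graph)  # unweighted by default
    avg = float(np.mean(list(cc.values()))) if cc else float("nan")
    return cc, avg


def characteristic_path_length(graph: ConnectivityGraph) -> float:
    """Mean shortest-path hop count over all node pairs; NaN if disconnected."""
    g = graph.graph
    if g.number_of_nodes() < 2 or not nx.is_connected(g):
        return float("nan")
    return float(nx.average_shortest_path_length(g))


def degree_stats(graph: ConnectivityGraph) -> tuple[dict, float]:
    degrees = dict(graph.graph.degree())
    mean_degree = float(np.mean(list(degrees.values()))) if degrees else float("nan")
    return degrees, mean_degree


def modularity(graph: ConnectivityGraph, seed: int = 0) -> tuple[float, list[set]]:
    """Greedy (Clauset-Newman-Moore) modularity on the binarized graph.

    Returns the best Q and its partition.  The agglomeration is
    deterministic (networkx breaks ties by heap order on node identity);
    ``seed`` is accepted for interface stability but unused by the greedy
    algorithm.  An edgeless graph has undefined Q (NaN) with the trivial
    singleton partition.
    """
    g = graph.graph
    if g.number_of_edges() == 0:
        return float("nan"), [{n} for n in g.nodes]
    communities = list(nx.community.greedy_modularity_communities(g, weight=None))
    q = float(nx.community.modularity(g, communities, weight=None))
    return q, [set(c) for c in communities]


def graph_metrics(
    dpl: DPLSeries, mode: str = "absolute", value: float = 0.2, seed: int = 0
) -> GraphMetricsRecord:
    """Full metric record for one epoch's dPL tensor."""
    cm = time_average_connectivity(dpl)
    g = build_graph(cm, mode, value)
    n = cm.values.shape[0]
    iu = np.triu_indices(n, k=1)
    _, avg_cc = clustering_coefficient(g)
    degrees, mean_degree = degree_stats(g)
    q, _ = modularity(g, seed=seed)
    return GraphMetricsRecord(
        mean_connectivity=float(cm.values[iu].mean()),
        avg_clustering=avg_cc,
        char_path_length=characteristic_path_length(g),
        degrees=degrees,
        mean_degree=mean_degree,
        modularity_q=q,
        n_components=nx.number_connected_components(g.graph),
        subject_id=dpl.subject_id,
        condition=dpl.condition,
    )


def compare_conditions(
    records_a: list[GraphMetricsRecord], records_b: list[GraphMetricsRecord]
) -> pd.DataFrame:
    """Welch t per graph metric between conditions, Bonferroni adjusted.

    Records with an undefined characteristic path length (disconnected
    graphs) are excluded pairwise from that metric; the exclusion count is
    reported.  A metric left with fewer than 2 defined values in either
    group is skipped entirely.
    """
    if len(records_a) < 2 or len(records_b) < 2:
        raise ValueError("need at least 2 records per condition")
    rows = []
    for metric in COMPARED_METRICS:
        va = np.array([getattr(r, metric) for r in records_a], dtype=float)
        vb = np.array([getattr(r, metric) for r in records_b], dtype=float)
        n_excluded = int(np.isnan(va).sum() + np.isnan(vb).sum())
        va, vb = va[~np.isnan(va)], vb[~np.isnan(vb)]
        if va.size < 2 or vb.size < 2:
            rows.append(
                {
                    "metric": metric,
                    "t": float("nan"),
                    "p_raw": float("nan"),
                    "n_excluded": n_excluded,
                    "skipped": True,
                }
            )
            continue
        t = two_sample_t(va, vb)
        from scipy import stats as sps

        if np.isfinite(t):
            import warnings

            with warnings.catch_warnings():
                # near-identical groups trip scipy's precision-loss warning;
                # the degenerate cases are handled explicitly below
                warnings.simplefilter("ignore", RuntimeWarning)
                p = float(sps.ttest_ind(vb, va, equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0 if t == 0.0 else float(np.finfo(float).tiny)
            p = max(p, np.finfo(float).tiny)  # keep p in (0, 1] for adjustment
        else:
            p = float(np.finfo(float).tiny)
        rows.append(
            {"metric": metric, "t": t, "p_raw": p, "n_excluded": n_excluded, "skipped": False}
        )
    df = pd.DataFrame(rows)
    tested = ~df["skipped"] & np.isfinite(df["p_raw"])
    adj = np.full(len(df), np.nan)
    if tested.any():
        adj[tested.to_numpy()] = bonferroni_adjust(df.loc[tested, "p_raw"].to_numpy())
    df["p_bonferroni"] = adj
    return df
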