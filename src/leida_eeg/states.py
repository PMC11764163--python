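"""PL-state identification: k-means over pooled eigenvectors, and state metrics.

Leading eigenvectors from every subject and condition are pooled into one
matrix and clustered with k-means (Euclidean distance on unit-norm vectors,
monotonically related to cosine distance).  Each cluster centroid is a
recurrent phase-locking (PL) state; states are renumbered 1..k by descending
total occupancy so that state identity is stable across runs with the same
seed.  Per subject and condition the module derives fractional occupancy,
mean dwell time (consecutive run length), and the empirical state-transition
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .phase import LeadingEigenvectorSeries


@dataclass
class EigenvectorPool:
    """Pooled V1(t) rows with a (subject, condition, time) index."""

    vectors: np.ndarray
    index: pd.DataFrame  # columns: subject_id, condition, time
    channel_labels: list[str]

    def __post_init__(self) -> None:
        if len(self.index) != self.vectors.shape[0]:
            raise ValueError("index length must match vector count")


@dataclass
class PLStateModel:
    """Converged k-means solution over an eigenvector pool."""

    k: int
    centroids: np.ndarray  # (k, N), ordered by descending total occupancy
    labels: np.ndarray  # per pooled row, values in 1..k
    inertia: float
    seed: int

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "k": self.k,
                "seed": self.seed,
                "inertia": self.inertia,
                "centroids": self.centroids.tolist(),
            }
        )


@dataclass
class StateMetrics:
    """Tidy per-(subject, condition, state) occupancy and dwell, plus transitions.

    ``occupancy`` columns: subject_id, condition, state, occupancy,
    dwell_steps, dwell_seconds (NaN when no step duration was given; dwell
    is NaN for unvisited states).  ``transitions`` maps (subject, condition)
    to a k x k row-stochastic matrix; rows of unvisited states are NaN.
    """

    occupancy: pd.DataFrame
    transitions: dict[tuple[str, str], np.ndarray]
    k: int


def pool_eigenvectors(series: list[LeadingEigenvectorSeries]) -> EigenvectorPool:
    """Concatenate eigenvector series in deterministic (subject, condition, time) order."""
    if not series:
        raise ValueError("no series to pool")
    labels0 = series[0].channel_labels
    for s in series:
        if list(s.channel_labels) != list(labels0):
            raise ValueError("channel labels differ across series")
    order = sorted(range(len(series)), key=lambda i: (series[i].subject_id, series[i].condition))
    blocks, idx_rows = [], []
    for i in order:
        s = series[i]
        blocks.append(s.vectors)
        idx_rows.append(
            pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "condition": s.condition,
                    "time": np.asarray(s.time_index),
                }
            )
        )
    return EigenvectorPool(
        np.vstack(blocks), pd.concat(idx_rows, ignore_index=True), list(labels0)
    )


def _renumber_by_occupancy(raw_labels: np.ndarray, centers: np.ndarray, k: int):
    counts = np.bincount(raw_labels, minlength=k)
    order = np.argsort(-counts, kind="stable")  # descending occupancy, stable ties
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    return remap[raw_labels], centers[order]


def cluster_eigenvectors(
    pool: EigenvectorPool, k: int, n_init: int = 20, seed: int = 0
) -> PLStateModel:
    """Best-of-``n_init`` k-means solution by inertia, renumbered by occupancy.

    k-means++ seeding with a fixed random state makes the result
    deterministic; empty clusters are re-seeded internally by the solver.
    Labels are 1-based, state 1 being the most occupied.
    """
    m = pool.vectors.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m:
        raise ValueError(f"k={k} exceeds the {m} pooled vectors")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(pool.vectors)
    labels, centers = _renumber_by_occupancy(km.labels_, km.cluster_centers_, k)
    return PLStateModel(k, centers, labels, float(km.inertia_), seed)


def scan_k(
    pool: EigenvectorPool,
    k_range,
    n_init: int = 20,
    seed: int = 0,
    silhouette_max_rows: int = 2000,
) -> pd.DataFrame:
    """Fit one model per k; report inertia and silhouette.  No automatic selection.

    k = 8 is the configured default of the headline analysis; this scan only
    characterises alternatives.  Silhouette is computed on a seeded subsample
    when the pool is large.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    rows = []
    rng = np.random.default_rng(seed)
    m = pool.vectors.shape[0]
    sub = (
        rng.choice(m, size=silhouette_max_rows, replace=False)
        if m > silhouette_max_rows
        else np.arange(m)
    )
    for k in ks:
        model = cluster_eigenvectors(pool, k, n_init=n_init, seed=seed)
        if k >= 2 and len(np.unique(model.labels[sub])) >= 2:
            sil = float(silhouette_score(pool.vectors[sub], model.labels[sub]))
        else:
            sil = float("nan")
        rows.append({"k": k, "inertia": model.inertia, "silhouette": sil})
    return pd.DataFrame(rows)


def _run_lengths(seq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(state, length) of each maximal run of identical consecutive labels."""
    change = np.nonzero(np.diff(seq))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(seq)]))
    return seq[starts], ends - starts


def compute_state_metrics(
    model: PLStateModel, pool: EigenvectorPool, step_seconds: float | None = None
) -> StateMetrics:
    """Occupancy, mean dwell, and transition matrices per subject x condition.

    Runs and transitions are evaluated within each epoch only (the pooled
    index identifies epochs by subject x condition); nothing crosses epoch
    boundaries.  ``step_seconds`` converts dwell steps to seconds when given.
    """
    k = model.k
    df = pool.index.copy()
    df["label"] = model.labels
    occ_rows = []
    transitions: dict[tuple[str, str], np.ndarray] = {}
    for (subj, cond), grp in df.groupby(["subject_id", "condition"], sort=True):
        if len(grp) == 0:  # pragma: no cover - groupby never yields empty
            raise ValueError(f"no time points for {subj}/{cond}")
        seq = grp.sort_values("time")["label"].to_numpy()
        counts = np.bincount(seq, minlength=k + 1)[1:]
        occ = counts / counts.sum()
        run_states, run_lens = _run_lengths(seq)
        trans = np.zeros((k, k))
        np.add.at(trans, (seq[:-1] - 1, seq[1:] - 1), 1)
        row_sums = trans.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            trans = np.where(row_sums > 0, trans / row_sums, np.nan)
        transitions[(subj, cond)] = trans
        for s in range(1, k + 1):
            lens = run_lens[run_states == s]
            dwell = float(lens.mean()) if lens.size else float("nan")
            occ_rows.append(
                {
                    "subject_id": subj,
                    "condition": cond,
                    "state": s,
                    "occupancy": occ[s - 1],
                    "dwell_steps": dwell,
                    "dwell_seconds": dwell * step_seconds if step_seconds else float("nan"),
                }
            )
    return StateMetrics(pd.DataFrame(occ_rows), transitions, k)


def occupancy_matrix(metrics: StateMetrics, condition: str) -> pd.DataFrame:
    """Subjects x states occupancy table for one condition."""
    sub = metrics.occupancy[metrics.occupancy["condition"] == condition]
    return sub.pivot(index="subject_id", columns="state", values="occupancy").sort_index()
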