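"""Assign continuous times (in minutes) to cells from pooled sampling intervals.

Cells are embedded in a low-dimensional PC space of their program's genes,
each collection pool (or cell-cycle phase) contributes a centroid with a
known real-world time, shortest paths between consecutive centroids are
traced on a euclidean cell k-NN graph with Dijkstra's algorithm, and each
cell's time is the fractional scalar projection of its embedding onto the
straight centroid-to-centroid vector, mapped onto the centroid time interval.
Periodic processes (the cell cycle) wrap at a stated period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import dijkstra
from scipy.stats import spearmanr
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .data import RawCounts
from .programs import mcv_select_components, _normalize_log

__all__ = [
    "CentroidSpec",
    "TrajectoryGraph",
    "CellTimes",
    "build_trajectory_graph",
    "trajectory_graph_from_embedding",
    "project_cell_times",
    "wrap_times",
    "pca_pseudotime",
    "ordering_score",
    "RAPAMYCIN_CENTROID_TIMES",
    "CELL_CYCLE_CENTROID_TIMES",
    "CELL_CYCLE_PERIOD",
]

# Shipped defaults for the rapamycin-response pools and cell-cycle phases.
RAPAMYCIN_CENTROID_TIMES = (-5.0, 5.0, 15.0, 25.0, 35.0, 45.0, 55.0)
CELL_CYCLE_CENTROID_TIMES = {"M1G": 7.0, "G1": 22.5, "S": 39.5, "G2": 56.5, "M": 77.5}
CELL_CYCLE_PERIOD = 88.0


@dataclass
class CentroidSpec:
    """Ordered cell groups with centroid times, optionally on a circle."""

    labels: list
    members: list  # list of integer index arrays, one per group
    times: list  # centroid time in minutes per group
    wrap_period: float | None = None

    def __post_init__(self):
        if not (len(self.labels) == len(self.members) == len(self.times)):
            raise ValueError("labels, members and times must align")
        t = np.asarray(self.times, float)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("centroid times must be strictly increasing")
        seen = np.concatenate([np.asarray(m, int) for m in self.members])
        if len(seen) != len(set(seen.tolist())):
            raise ValueError("each cell must belong to exactly one group")

    def segments(self):
        """Consecutive (i, j, t_i, t_j) centroid pairs, closing the circle if wrapped."""
        pairs = [
            (i, i + 1, self.times[i], self.times[i + 1])
            for i in range(len(self.labels) - 1)
        ]
        if self.wrap_period is not None and len(self.labels) > 1:
            pairs.append(
                (len(self.labels) - 1, 0, self.times[-1], self.times[0] + self.wrap_period)
            )
        return pairs


@dataclass
class TrajectoryGraph:
    embedding: np.ndarray  # (n, N)
    centroids: np.ndarray  # (n_groups, N)
    knn: object  # sparse distance-weighted graph
    paths: list  # one dict per consecutive centroid pair
    n_components: int


@dataclass
class CellTimes:
    t: np.ndarray
    program: str = "response"
    wrapped: bool = False
    wrap_period: float | None = None


def trajectory_graph_from_embedding(
    U: np.ndarray, spec: CentroidSpec, k: int = 10
) -> TrajectoryGraph:
    """Build the centroid/k-NN/Dijkstra structure on a given embedding."""
    U = np.asarray(U, float)
    n = U.shape[0]
    centroids = np.stack(
        [U[np.asarray(m, int)].mean(axis=0) for m in spec.members]
    )
    knn = kneighbors_graph(
        U, n_neighbors=min(k, n - 1), mode="distance", include_self=False
    )
    knn = knn.maximum(knn.T)  # symmetric, undirected

    nearest_node = [
        int(np.argmin(np.linalg.norm(U - c, axis=1))) for c in centroids
    ]
    paths = []
    for i, j, t_i, t_j in spec.segments():
        src, dst = nearest_node[i], nearest_node[j]
        dist, pred = dijkstra(
            knn, directed=False, indices=src, return_predecessors=True
        )
        if np.isinf(dist[dst]):
            raise ValueError(
                f"centroids {spec.labels[i]!r} and {spec.labels[j]!r} are "
                "disconnected in the k-NN graph"
            )
        node_path = [dst]
        while node_path[-1] != src:
            node_path.append(int(pred[node_path[-1]]))
        node_path.reverse()
        v = centroids[j] - centroids[i]
        paths.append(
            dict(
                pair=(spec.labels[i], spec.labels[j]),
                a=centroids[i],
                b=centroids[j],
                t_a=float(t_i),
                t_b=float(t_j),
                v=v,
                nodes=np.asarray(node_path, int),
                cost=float(dist[dst]),
            )
        )
    return TrajectoryGraph(
        embedding=U,
        centroids=centroids,
        knn=knn,
        paths=paths,
        n_components=U.shape[1],
    )


def build_trajectory_graph(
    Z_P,
    spec: CentroidSpec,
    k: int = 10,
    pc_candidates=(5, 6, 7, 8),
    seed: int = 0,
) -> TrajectoryGraph:
    """Embed program counts into MCV-selected PCs and trace centroid paths."""
    M = Z_P.Z if isinstance(Z_P, RawCounts) else np.asarray(Z_P)
    if any(len(np.asarray(m)) == 0 for m in spec.members):
        raise ValueError("every centroid group must be nonempty")
    X = _normalize_log(M)
    cand = [c for c in pc_candidates if c < min(M.shape)] or [min(M.shape) - 1]
    N = mcv_select_components(M, cand, seed)
    U = PCA(n_components=N, random_state=0).fit_transform(X)
    return trajectory_graph_from_embedding(U, spec, k=k)


def project_time(u, a, v, t_a, t_b) -> float:
    """Fractional scalar projection of u - a onto v, mapped to [t_a, t_b]."""
    v = np.asarray(v, float)
    vv = float(v @ v)
    if vv == 0:
        raise ValueError("zero-length centroid vector")
    return float(((np.asarray(u, float) - np.asarray(a, float)) @ v) / vv * (t_b - t_a) + t_a)


def project_cell_times(
    graph: TrajectoryGraph,
    spec: CentroidSpec,
    program: str = "response",
    clamp: bool = False,
) -> CellTimes:
    """Assign each cell the projected time of its nearest Dijkstra path segment.

    A cell belongs to the consecutive centroid pair whose shortest-path nodes
    contain the cell's nearest node (euclidean, ties to the earlier segment);
    its time is the fractional projection onto that pair's straight vector.
    Projections may extrapolate beyond the segment's time interval;
    ``clamp=True`` truncates them to [t_a, t_b].
    """
    if not graph.paths:
        raise ValueError("trajectory graph has no centroid paths")
    U = graph.embedding
    n = U.shape[0]

    seg_nodes = np.concatenate([p["nodes"] for p in graph.paths])
    seg_index = np.concatenate(
        [np.full(len(p["nodes"]), s) for s, p in enumerate(graph.paths)]
    )
    # distance of every cell to every path node; earlier segments win ties
    d = np.linalg.norm(U[:, None, :] - U[seg_nodes][None, :, :], axis=2)
    best = np.argmin(d, axis=1)  # argmin takes the first minimum -> earlier segment
    t = np.empty(n)
    for c in range(n):
        p = graph.paths[int(seg_index[best[c]])]
        t[c] = project_time(U[c], p["a"], p["v"], p["t_a"], p["t_b"])
        if clamp:
            t[c] = min(max(t[c], p["t_a"]), p["t_b"])
    out = CellTimes(t=t, program=program, wrap_period=spec.wrap_period)
    if spec.wrap_period is not None:
        out = wrap_times(out, spec.wrap_period)
    return out


def wrap_times(times: CellTimes, period: float) -> CellTimes:
    """Wrap times onto [0, period)."""
    if period <= 0:
        raise ValueError("period must be positive")
    wrapped = np.mod(times.t, period)
    # tiny negative inputs can round to exactly `period` under fmod
    wrapped[wrapped >= period] = 0.0
    return CellTimes(
        t=wrapped,
        program=times.program,
        wrapped=True,
        wrap_period=period,
    )


def pca_pseudotime(Z) -> np.ndarray:
    """PC1 of centered, unit-scaled log1p standardized counts, min-max mapped to [0, 1]."""
    M = Z.Z if isinstance(Z, RawCounts) else np.asarray(Z)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    X = _normalize_log(M)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    pc1 = PCA(n_components=1, random_state=0).fit_transform((X - mu) / sd)[:, 0]
    rng = pc1.max() - pc1.min()
    if rng == 0:
        raise ValueError("PC1 is constant; pseudotime undefined")
    return (pc1 - pc1.min()) / rng


def ordering_score(t, interval) -> float:
    """Spearman rank correlation of assigned times against collection interval."""
    t = np.asarray(t, float)
    interval = np.asarray(interval, float)
    if len(t) < 3:
        raise ValueError("need at least 3 cells")
    if np.all(t == t[0]) or len(np.unique(interval)) < 2:
        raise ValueError("constant input; ordering score undefined")
    rho, _ = spearmanr(t, interval)
    return float(rho)
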