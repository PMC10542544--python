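"""Partition genes into temporal transcriptional programs.

Expression is PC-truncated at a rank chosen by molecular cross-validation
(binomially splitting each UMI into train/test halves), genes are clustered
on a cosine k-NN graph with the Leiden algorithm, each cluster's cells are
ordered on a circle by that cluster's first principal component, and clusters
are merged into exactly two programs by agglomerative clustering on circular
correlation distance. On interval-sampled data the two programs separate a
monotone response process from a periodic (cell-cycle-like) one.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .data import RawCounts, standardize_counts

__all__ = [
    "PCTruncation",
    "GeneClusterSet",
    "ProgramAssignment",
    "mcv_select_components",
    "pc_truncate",
    "gene_distance",
    "cluster_genes",
    "circular_correlation",
    "merge_to_programs",
]


@dataclass
class PCTruncation:
    X_PC: np.ndarray  # (n, g) reconstruction from the first N PCs
    N: int
    gene_ids: list[str]


@dataclass
class GeneClusterSet:
    cluster_of: np.ndarray  # (g,) contiguous ids from 0
    k_neighbors: int
    resolution: float
    gene_ids: list[str]

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_of.max()) + 1


@dataclass
class ProgramAssignment:
    program_of: dict  # gene id -> "response" | "cell_cycle"
    cluster_program: np.ndarray  # per-cluster program index
    cluster_times: np.ndarray  # (n_clusters, n_cells) angles on [0, 2pi)


def _normalize_log(Z: np.ndarray) -> np.ndarray:
    sums = Z.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1
    return np.log1p(Z * (np.median(Z.sum(axis=1)) / sums))


def mcv_select_components(Z, candidates, seed: int) -> int:
    """Pick a PCA rank by molecular cross-validation on raw UMI counts.

    Each molecule is split binomially (p=0.5) into train/test matrices; the
    rank whose train-PCA reconstruction best predicts the (normalized) test
    half wins.
    """
    M = Z.Z if isinstance(Z, RawCounts) else np.asarray(Z)
    if M.size == 0:
        raise ValueError("empty matrix")
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValueError("no candidate ranks supplied")
    if max(candidates) >= min(M.shape):
        raise ValueError("candidate rank must be < min(n_cells, n_genes)")
    if len(candidates) == 1:
        return candidates[0]

    rng = np.random.default_rng(seed)
    train = rng.binomial(M.astype(int), 0.5)
    test = M - train
    Xtr, Xte = _normalize_log(train), _normalize_log(test)

    pca = PCA(n_components=max(candidates), random_state=0)
    scores = pca.fit_transform(Xtr)
    errors = {}
    for N in candidates:
        recon = scores[:, :N] @ pca.components_[:N] + pca.mean_
        errors[N] = float(np.mean((recon - Xte) ** 2))
    return min(candidates, key=lambda N: (errors[N], N))


def pc_truncate(
    Z: RawCounts,
    candidates=(5, 8, 13, 21),
    seed: int = 0,
    min_variance: float = 0.01,
    min_mean: float = 0.0125,
) -> PCTruncation:
    """Filter high-variance genes, then reconstruct from MCV-selected PCs."""
    X = _normalize_log(Z.Z)
    keep = (X.var(axis=0, ddof=1) >= min_variance) & (X.mean(axis=0) >= min_mean)
    if keep.sum() < 3:
        keep = np.ones(X.shape[1], dtype=bool)
    X = X[:, keep]
    cand = [c for c in candidates if c < min(X.shape)] or [min(X.shape) - 1]
    N = mcv_select_components(Z.Z[:, keep], cand, seed)
    pca = PCA(n_components=N, random_state=0)
    X_PC = pca.fit_transform(X) @ pca.components_ + pca.mean_
    return PCTruncation(
        X_PC=X_PC, N=N, gene_ids=[g for g, k in zip(Z.gene_ids, keep) if k]
    )


def _information_distance(X: np.ndarray, bins: int) -> np.ndarray:
    g = X.shape[1]
    codes = np.empty(X.shape, dtype=int)
    for j in range(g):
        col = X[:, j]
        lo, hi = col.min(), col.max()
        if hi == lo:
            codes[:, j] = 0
        else:
            edges = np.linspace(lo, hi, bins + 1)
            codes[:, j] = np.clip(np.digitize(col, edges[1:-1]), 0, bins - 1)
    D = np.zeros((g, g))
    for i in range(g):
        for j in range(i, g):
            joint = np.zeros((bins, bins))
            np.add.at(joint, (codes[:, i], codes[:, j]), 1.0)
            p = joint / joint.sum()
            pi, pj = p.sum(axis=1), p.sum(axis=0)
            nz = p > 0
            H = -np.sum(p[nz] * np.log2(p[nz]))
            outer = np.outer(pi, pj)
            mi = np.sum(p[nz] * np.log2(p[nz] / outer[nz]))
            d = 0.0 if H == 0 else 1.0 - mi / H
            D[i, j] = D[j, i] = max(0.0, d)
    np.fill_diagonal(D, 0.0)
    return D


def gene_distance(X_PC, metric: str = "cosine", bins: int = 10) -> np.ndarray:
    """Symmetric gene-gene distance matrix on PC-truncated expression.

    Supported metrics: euclidean, cosine (1 - cosine similarity), manhattan,
    and information (1 - MI / joint entropy on equal-width binned values).
    """
    X = X_PC.X_PC if isinstance(X_PC, PCTruncation) else np.asarray(X_PC)
    G = X.T  # genes as rows
    if metric in ("euclidean", "manhattan"):
        D = cdist(G, G, "cityblock" if metric == "manhattan" else "euclidean")
    elif metric == "cosine":
        norms = np.linalg.norm(G, axis=1)
        if np.any(norms == 0):
            bad = int(np.where(norms == 0)[0][0])
            raise ValueError(f"gene {bad} is all-zero; cosine distance undefined")
        D = 1.0 - (G @ G.T) / np.outer(norms, norms)
        D = np.clip(D, 0.0, 2.0)
    elif metric == "information":
        D = _information_distance(X, bins)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def cluster_genes(
    X_PC, k: int = 21, resolution: float = 1.0, seed: int = 0
) -> GeneClusterSet:
    """Leiden-cluster genes on a cosine k-NN graph of PC-truncated expression."""
    if isinstance(X_PC, PCTruncation):
        X, gene_ids = X_PC.X_PC, X_PC.gene_ids
    else:
        X = np.asarray(X_PC)
        gene_ids = [f"gene_{i}" for i in range(X.shape[1])]
    g = X.shape[1]
    if g < 3:
        raise ValueError("need at least 3 genes to cluster")
    if k >= g:
        raise ValueError("k must be < number of genes")

    D = gene_distance(X, "cosine")
    if D.max() < 1e-12:  # all genes identical: one community by definition
        return GeneClusterSet(
            cluster_of=np.zeros(g, dtype=int),
            k_neighbors=k,
            resolution=resolution,
            gene_ids=gene_ids,
        )
    nn = NearestNeighbors(n_neighbors=k + 1, metric="precomputed").fit(D)
    _, idx = nn.kneighbors(D)
    edges = {(min(i, j), max(i, j)) for i in range(g) for j in idx[i, 1:]}
    graph = igraph.Graph(n=g, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    # contiguous ids by first appearance
    _, labels = np.unique(labels, return_inverse=True)
    return GeneClusterSet(
        cluster_of=labels, k_neighbors=k, resolution=resolution, gene_ids=gene_ids
    )


def circular_correlation(theta_a, theta_b) -> float:
    """Fisher-Lee circular correlation between two angle vectors (radians)."""
    a = np.asarray(theta_a, float)
    b = np.asarray(theta_b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length angle vectors of length >= 3")
    abar = np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))
    bbar = np.arctan2(np.mean(np.sin(b)), np.mean(np.cos(b)))
    sa, sb = np.sin(a - abar), np.sin(b - bbar)
    denom = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if denom == 0:
        raise ValueError("degenerate input: all angles identical")
    return float(np.sum(sa * sb) / denom)


def _cluster_angles(Zc: np.ndarray) -> np.ndarray:
    """Order cells by PC1 of a cluster's standardized log counts -> [0, 2pi)."""
    X = np.log1p(standardize_counts(np.asarray(Zc, float)).X)
    pca = PCA(n_components=1, random_state=0)
    pc1 = pca.fit_transform(X)[:, 0]
    # orient deterministically: PC1 correlates nonnegatively with total counts
    totals = Zc.sum(axis=1)
    if np.std(totals) > 0 and np.corrcoef(pc1, totals)[0, 1] < 0:
        pc1 = -pc1
    order = np.argsort(pc1, kind="stable")
    angles = np.empty(len(pc1))
    angles[order] = np.arange(len(pc1)) * 2 * np.pi / len(pc1)
    return angles


def merge_to_programs(
    clusters: GeneClusterSet, Z: RawCounts, labels=("response", "cell_cycle")
) -> ProgramAssignment:
    """Aggregate gene clusters into two programs via circular correlation.

    Per cluster, cells are ordered on [0, 2pi) by that cluster's PC1; the
    distance between clusters is 1 - rho_circ, and average-linkage
    agglomerative clustering cut at two groups yields the programs. The
    larger program (by gene count) receives ``labels[0]``.
    """
    n_clusters = clusters.n_clusters
    if n_clusters < 2:
        raise ValueError("need at least 2 gene clusters to merge")
    gene_pos = {g: i for i, g in enumerate(Z.gene_ids)}
    angles = np.zeros((n_clusters, Z.n_cells))
    for c in range(n_clusters):
        members = [
            gene_pos[g]
            for g, cl in zip(clusters.gene_ids, clusters.cluster_of)
            if cl == c
        ]
        if len(members) < 2:
            raise ValueError(f"cluster {c} has fewer than 2 genes")
        angles[c] = _cluster_angles(Z.Z[:, members])

    D = np.zeros((n_clusters, n_clusters))
    for i in range(n_clusters):
        for j in range(i + 1, n_clusters):
            D[i, j] = D[j, i] = 1.0 - circular_correlation(angles[i], angles[j])
    D = np.clip(D, 0.0, None)

    link = linkage(squareform(D, checks=False), method="average")
    groups = fcluster(link, t=2, criterion="maxclust") - 1

    sizes = [
        sum(
            np.sum(clusters.cluster_of == c)
            for c in range(n_clusters)
            if groups[c] == p
        )
        for p in (0, 1)
    ]
    order = np.argsort(sizes)[::-1]  # larger group first
    name_of = {int(order[0]): labels[0], int(order[1]): labels[1]}
    program_of = {
        g: name_of[int(groups[clusters.cluster_of[i]])]
        for i, g in enumerate(clusters.gene_ids)
    }
    return ProgramAssignment(
        program_of=program_of,
        cluster_program=np.array([name_of[int(p)] == labels[1] for p in groups], int),
        cluster_times=angles,
    )
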