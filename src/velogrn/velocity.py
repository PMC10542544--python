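"""RNA velocity from assigned times, and bounded mRNA decay-rate estimation.

Velocity here does not use spliced/unspliced read ratios: each cell's
expression change relative to its k-NN graph neighbors is regressed (without
intercept) on the corresponding time differences, and the slope per gene is
the cell's velocity in counts per minute. The denoising graph is selected by
self-supervision: molecules are split into two halves, and the (PCs, k) pair
whose neighbor-averaged train half best predicts the test half wins.

Plotting dx/dt against x for one gene defines a convex region; under the
constraint that transcription is nonnegative, the steepest line through the
origin below that region has slope -lambda, so an ordinary least-squares fit
through the origin on the cells with the most negative velocity/expression
ratios yields a lower bound on the decay rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .cell_times import CellTimes
from .data import ExpressionMatrix, RawCounts

__all__ = [
    "DenoisingGraph",
    "VelocityEstimate",
    "DecayBound",
    "build_denoising_graph",
    "denoise",
    "estimate_velocity",
    "decay_bound",
    "sliding_decay",
]


@dataclass
class DenoisingGraph:
    neighbors: list  # per-cell integer index arrays
    weights: list  # per-cell nonnegative weights summing to 1
    selected_pcs: int
    selected_k: int
    selection_mse: float


@dataclass
class VelocityEstimate:
    dXdt: np.ndarray  # (n, g), counts / minute; NaN rows where inestimable
    t_used: np.ndarray
    missing: np.ndarray  # (n,) bool, True where the row could not be estimated
    program: str = "response"


@dataclass
class DecayBound:
    lambda_min: np.ndarray  # (n_windows, g) or (g,)
    window_centers: np.ndarray | None
    quantile: float


def _values(X) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.X
    if isinstance(X, RawCounts):
        return X.Z.astype(float)
    return np.asarray(X, float)


def _knn_weights(E: np.ndarray, k: int, eps: float = 1e-12):
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(E))).fit(E)
    dist, idx = nn.kneighbors(E)
    neighbors, weights = [], []
    for c in range(len(E)):
        nbr = idx[c][idx[c] != c][: k]
        d = dist[c][idx[c] != c][: k]
        w = 1.0 / (d + eps)
        neighbors.append(nbr)
        weights.append(w / w.sum())
    return neighbors, weights


def build_denoising_graph(
    X, pc_candidates, k_candidates, seed: int = 0
) -> DenoisingGraph:
    """Select the (PCs, k) denoising graph that minimizes self-supervised MSE.

    Expression values are rounded to pseudo-molecules and split binomially
    into two halves; for each candidate pair, the train half is embedded,
    neighbor-averaged with inverse-distance weights, and scored against the
    test half. The winning pair defines the final graph on the full data.
    """
    V = _values(X)
    pc_candidates = [int(p) for p in pc_candidates]
    k_candidates = [int(k) for k in k_candidates]
    if not pc_candidates or not k_candidates:
        raise ValueError("candidate lists must be nonempty")

    rng = np.random.default_rng(seed)
    molecules = np.round(V).astype(int)
    train = rng.binomial(molecules, 0.5).astype(float)
    test = molecules - train

    best = None
    for p in pc_candidates:
        if p >= min(V.shape):
            continue
        E = PCA(n_components=p, random_state=0).fit_transform(np.log1p(train))
        for k in k_candidates:
            if k >= len(V):
                continue
            nbrs, wts = _knn_weights(E, k)
            denoised = np.stack(
                [w @ train[nbr] for nbr, w in zip(nbrs, wts)]
            )
            err = float(np.mean((denoised - test) ** 2))
            if np.isfinite(err) and (best is None or err < best[0]):
                best = (err, p, k)
    if best is None:
        raise ValueError("no candidate (PCs, k) pair yielded a finite MSE")

    err, p, k = best
    E = PCA(n_components=p, random_state=0).fit_transform(np.log1p(V))
    neighbors, weights = _knn_weights(E, k)
    return DenoisingGraph(
        neighbors=neighbors,
        weights=weights,
        selected_pcs=p,
        selected_k=k,
        selection_mse=err,
    )


def denoise(X, graph: DenoisingGraph) -> ExpressionMatrix:
    """Weighted neighbor average of expression over the denoising graph."""
    V = _values(X)
    out = np.empty_like(V)
    for c, (nbr, w) in enumerate(zip(graph.neighbors, graph.weights)):
        if len(nbr) == 0:
            warnings.warn(f"cell {c} has no neighbors; passing through unchanged")
            out[c] = V[c]
        else:
            out[c] = w @ V[nbr]
    gene_ids = (
        list(X.gene_ids) if isinstance(X, (ExpressionMatrix, RawCounts))
        else [f"gene_{i}" for i in range(V.shape[1])]
    )
    return ExpressionMatrix(
        X=out,
        gene_ids=gene_ids,
        depth_target=getattr(X, "depth_target", float(np.median(out.sum(axis=1)))),
        gene_scale=np.ones(V.shape[1]),
        kept_genes=np.arange(V.shape[1]),
    )


def estimate_velocity(
    X_denoised,
    times: CellTimes,
    graph: DenoisingGraph,
    wrap: float | None = None,
    program: str | None = None,
) -> VelocityEstimate:
    """Per-cell velocity: no-intercept regression of neighbor dX on neighbor dt.

    With a wrap period, time differences take the minimal signed circular
    difference so the periodic seam does not produce spurious slopes. Cells
    with fewer than two neighbors, or whose neighbors share their time
    exactly, are flagged missing (NaN) rather than zero.
    """
    V = _values(X_denoised)
    t = np.asarray(times.t, float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    n, g = V.shape
    dXdt = np.full((n, g), np.nan)
    missing = np.zeros(n, dtype=bool)
    for c in range(n):
        nbr = np.asarray(graph.neighbors[c], int)
        if len(nbr) < 2:
            missing[c] = True
            continue
        dt = t[nbr] - t[c]
        if wrap is not None:
            dt = (dt + wrap / 2.0) % wrap - wrap / 2.0
        if np.all(dt == 0):
            missing[c] = True
            continue
        dX = V[nbr] - V[c]
        dXdt[c] = (dt @ dX) / (dt @ dt)
    return VelocityEstimate(
        dXdt=dXdt,
        t_used=t,
        missing=missing,
        program=program or times.program,
    )


def decay_bound(
    x_g, v_g, quantile: float = 0.05, min_cells: int = 20, x_floor: float = 1e-8
) -> float:
    """Lower bound on a gene's decay rate from its (expression, velocity) cloud.

    Cells are ordered by the velocity/expression ratio; the smallest
    ``quantile`` fraction is kept and velocity is regressed on expression
    through the origin. The negative slope, clipped at zero, bounds lambda
    from below under the constraint alpha >= 0.
    """
    x = np.asarray(x_g, float)
    v = np.asarray(v_g, float)
    ok = (x > x_floor) & np.isfinite(v)
    if ok.sum() == 0:
        return np.nan
    if ok.sum() < min_cells:
        raise ValueError(f"need >= {min_cells} positive-expression cells")
    x, v = x[ok], v[ok]
    ratio = v / x
    n_keep = max(1, int(np.ceil(quantile * len(x))))
    keep = np.argsort(ratio, kind="stable")[:n_keep]
    slope = float((x[keep] @ v[keep]) / (x[keep] @ x[keep]))
    return max(0.0, -slope)


def sliding_decay(
    x_g,
    v_g,
    times,
    window_width: float = 10.0,
    step: float = 1.0,
    quantile: float = 0.05,
    min_cells: int = 20,
) -> DecayBound:
    """Time-resolved decay bounds on a sliding window over cell times.

    Windows with too few positive-expression cells are skipped with a
    warning; a step wider than the sampled span degenerates to the global
    bound in a single window.
    """
    x = np.asarray(x_g, float)
    v = np.asarray(v_g, float)
    t = np.asarray(times, float)
    x2 = np.atleast_2d(x.T).T if x.ndim == 1 else x  # (n, g)
    v2 = np.atleast_2d(v.T).T if v.ndim == 1 else v

    t_lo, t_hi = t.min(), t.max()
    if step >= t_hi - t_lo:
        centers = [0.5 * (t_lo + t_hi)]
        masks = [np.ones(len(t), bool)]
    else:
        centers, masks = [], []
        c = t_lo + window_width / 2.0
        while c <= t_hi - window_width / 2.0 + 1e-9:
            centers.append(c)
            masks.append(np.abs(t - c) <= window_width / 2.0)
            c += step

    rows, kept_centers = [], []
    for c, m in zip(centers, masks):
        vals = np.full(x2.shape[1], np.nan)
        usable = False
        for j in range(x2.shape[1]):
            pos = m & (x2[:, j] > 1e-8) & np.isfinite(v2[:, j])
            if pos.sum() < min_cells:
                continue
            vals[j] = decay_bound(
                x2[pos, j], v2[pos, j], quantile=quantile, min_cells=min_cells
            )
            usable = True
        if usable:
            rows.append(vals)
            kept_centers.append(c)
        else:
            warnings.warn(f"window centered at {c:.1f} min has too few cells; skipped")
    if not rows:
        raise ValueError("no window had enough positive-expression cells")
    lam = np.stack(rows)
    if x.ndim == 1:
        lam = lam[:, 0]
    return DecayBound(
        lambda_min=lam, window_centers=np.asarray(kept_centers), quantile=quantile
    )
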