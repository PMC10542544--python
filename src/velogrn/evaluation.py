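"""Model scoring: ERV edge ranking, AUPR, R-squared, marginal error, half-life.

A trained model is read out as a gene regulatory network by explained
relative variance (ERV): for each TF, the model is re-run with that TF's
hidden node zeroed (no retraining) and each gene's ERV is one minus the
ratio of the full model's residual sum of squares to the reduced model's —
the coefficient of partial determination of that TF for that gene. Edges
ranked by ERV are scored by area under the precision-recall curve against
prior-network rows that were held out of the encoder mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score

from ._autograd import mse
from .data import PriorNetwork
from .grn_models import (
    BiophysicalModel,
    DecayModule,
    DynamicalGRNModel,
    PerturbationSpec,
    StaticGRNModel,
    TrajectoryBatch,
)

__all__ = [
    "ERVMatrix",
    "NetworkScore",
    "FitScore",
    "erv_matrix",
    "aupr",
    "r_squared",
    "marginal_error",
    "half_life",
]


@dataclass
class ERVMatrix:
    erv: np.ndarray  # (g, k), <= 1
    reference_rss: np.ndarray  # (g,) full-model RSS
    tf_ids: list | None = None
    gene_ids: list | None = None


@dataclass
class NetworkScore:
    aupr: float
    evaluated_edges: int
    positive_edges: int


@dataclass
class FitScore:
    r2: float
    rss: float
    tss: float


def _forward_velocity(model, batches, perturb):
    """Predicted outputs for a list of TrajectoryBatch, as one (entries, g) stack."""
    preds, rows = [], []
    for tb in batches:
        if isinstance(model, BiophysicalModel):
            vels, _, _, _, _ = model.forward_graph(tb.X_seq, perturb)
            out = np.stack([v.data for v in vels])
        elif isinstance(model, DynamicalGRNModel):
            outs, _, _ = model.forward_graph(tb.X_seq, perturb)
            out = np.stack([o.data for o in outs])
        else:
            raise TypeError(f"unsupported model type {type(model).__name__}")
        preds.append(out.reshape(-1, out.shape[-1]))
        rows.append(tb.cell_indices.reshape(-1))
    return np.concatenate(preds), np.concatenate(rows)


def erv_matrix(model, data, targets) -> ERVMatrix:
    """Explained relative variance of every TF for every gene.

    ``data`` is a cells x genes matrix for static models or a list of
    :class:`TrajectoryBatch` for recurrent ones; ``targets`` is the full
    cells x genes target matrix (non-finite entries are ignored).
    """
    T = np.asarray(targets, float)
    k = model.n_tfs

    def rss_for(perturb):
        if isinstance(model, StaticGRNModel):
            pred, _ = model.forward_graph(np.asarray(data, float), perturb)
            resid = pred.data - T
        else:
            pred, rows = _forward_velocity(model, data, perturb)
            resid = pred - T[rows]
        resid = np.where(np.isfinite(resid), resid, 0.0)
        return (resid**2).sum(axis=0)

    rss_full = rss_for(PerturbationSpec.identity(k))
    erv = np.zeros((len(rss_full), k))
    for j in range(k):
        rss_red = rss_for(PerturbationSpec.knockout(k, [j]))
        assert np.all(rss_red >= -1e-12), "negative RSS is impossible"
        with np.errstate(divide="ignore", invalid="ignore"):
            col = 1.0 - rss_full / rss_red
        assert np.all(rss_full[rss_red == 0] <= 1e-12), (
            "reduced model cannot fit exactly while the full model does not"
        )
        col[rss_red == 0] = 0.0  # removal changed nothing and the fit is exact
        erv[:, j] = np.minimum(col, 1.0)
    return ERVMatrix(
        erv=erv,
        reference_rss=rss_full,
        tf_ids=getattr(model, "tf_ids", None),
        gene_ids=getattr(model, "gene_ids", None),
    )


def aupr(scores, gold: PriorNetwork, universe) -> NetworkScore:
    """Area under precision-recall for edges of held-out genes.

    ``universe`` is the held-out gene index set; every (gene, TF) pair in
    ``universe`` x TFs is scored, with the gold standard's entries as labels.
    """
    S = scores.erv if isinstance(scores, ERVMatrix) else np.asarray(scores, float)
    universe = np.asarray(universe, int)
    if len(universe) == 0:
        raise ValueError("empty evaluation universe")
    y = gold.P[universe].ravel()
    s = S[universe].ravel()
    if y.sum() == 0:
        raise ValueError("no positive edges in the evaluation universe")
    return NetworkScore(
        aupr=float(average_precision_score(y, s)),
        evaluated_edges=int(len(y)),
        positive_edges=int(y.sum()),
    )


def r_squared(x, x_hat) -> FitScore:
    """Coefficient of determination 1 - RSS/TSS over all entries."""
    x = np.asarray(x, float)
    x_hat = np.asarray(x_hat, float)
    rss = float(np.sum((x - x_hat) ** 2))
    tss = float(np.sum((x - x.mean()) ** 2))
    if tss == 0:
        raise ValueError("constant target; R^2 undefined")
    return FitScore(r2=1.0 - rss / tss, rss=rss, tss=tss)


def marginal_error(model, data, targets) -> np.ndarray:
    """Per-TF loss decomposition at the TFA layer via backpropagation.

    For each trajectory, (dL/dh_TF) * h_TF is summed over time and TF-wise;
    the mean over trajectories is returned, shape (k,).
    """
    T = np.asarray(targets, float)
    per_traj = []

    def accumulate(outs, h_tfs, tgt):
        loss = mse(_stack_tensors(outs), tgt)
        for h in h_tfs:
            h.retain_grad = True
        loss.backward()
        contrib = sum(
            np.where(h.grad is None, 0.0, h.grad) * h.data for h in h_tfs
        )  # (batch, k), summed over time
        per_traj.append(np.atleast_2d(contrib))

    if isinstance(model, StaticGRNModel):
        out, h_tf = model.forward_graph(np.asarray(data, float))
        accumulate([out], [h_tf], T)
    else:
        for tb in data:
            tgt = np.where(
                np.isfinite(T[tb.cell_indices]), T[tb.cell_indices], 0.0
            )
            if isinstance(model, BiophysicalModel):
                vels, _, _, h_tfs, _ = model.forward_graph(tb.X_seq)
                accumulate(vels, h_tfs, tgt)
            else:
                outs, h_tfs, _ = model.forward_graph(tb.X_seq)
                accumulate(outs, h_tfs, tgt)
    return np.concatenate(per_traj, axis=0).mean(axis=0)


def _stack_tensors(tensors):
    from ._autograd import Tensor

    return Tensor._from_op(
        np.stack([t.data for t in tensors]),
        tuple(tensors),
        lambda g: tuple(g[i] for i in range(len(tensors))),
    )


def half_life(lambda_rate) -> float | np.ndarray:
    """Half-life in minutes, ln(2) / lambda; nonpositive rates are undefined."""
    lam = np.asarray(lambda_rate, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(lam > 0, np.log(2.0) / np.where(lam > 0, lam, 1.0), np.nan)
    return float(out) if np.isscalar(lambda_rate) or out.ndim == 0 else out
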