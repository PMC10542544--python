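"""Optimization loops for the neural GRN models.

All models train with Adam plus L2 weight decay against mean squared error,
regularized by random dropout of half the input genes (re-drawn every batch
and epoch, zeroing — not inverted-scaling — the dropped columns; evaluation
passes always use the full input). The encoder's prior mask is re-applied
after every update so pruned weights stay exactly zero. The biophysical
schedule freezes a pre-trained decay module for the first 100 epochs while
the transcription module learns total velocity, then unfreezes it and adds
an auxiliary loss tying the decay output to the bounded decay-velocity
estimate (1:1 weighting).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._autograd import Adam, Tensor, mse
from .data import DataSplit, ExpressionMatrix
from .grn_models import (
    BiophysicalModel,
    DecayModule,
    DynamicalGRNModel,
    StaticGRNModel,
    make_trajectories,
)

__all__ = [
    "TrainingConfig",
    "TrainingLog",
    "train_static",
    "train_dynamical",
    "train_decay",
    "train_biophysical",
    "hyperparameter_grid",
]


@dataclass
class TrainingConfig:
    learning_rate: float = 5e-5
    weight_decay: float = 1e-7
    epochs: int = 200
    input_dropout: float = 0.5
    batch_cells: int = 250
    batch_trajectories: int = 20
    trajectory_length: int = 20
    bin_width: float = 1.0
    freeze_decay_epochs: int = 100
    trajectories_per_offset: int = 1
    decay_loss_weight: float | str = "balanced"
    dropout_scale: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.input_dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.learning_rate < 0 or self.epochs < 1:
            raise ValueError("need nonnegative learning rate and epochs >= 1")


@dataclass
class TrainingLog:
    train_mse: list = field(default_factory=list)
    validation_mse: list = field(default_factory=list)
    config: TrainingConfig | None = None


def _matrix(X) -> np.ndarray:
    return X.X if isinstance(X, ExpressionMatrix) else np.asarray(X, float)


def _dropout(batch: np.ndarray, rate: float, rng, scale: bool = True) -> np.ndarray:
    """Zero a random fraction of input genes; inverted scaling (default)
    divides the kept genes by the keep probability so the expected input
    matches the full-input evaluation pass."""
    if rate == 0:
        return batch
    drop = rng.random(batch.shape[-1]) < rate
    out = batch.copy()
    out[..., drop] = 0.0
    if scale:
        out[..., ~drop] /= 1.0 - rate
    return out


def _check_finite(loss: float, epoch: int, batch: int):
    if not np.isfinite(loss):
        raise FloatingPointError(
            f"non-finite loss at epoch {epoch}, batch {batch}"
        )


def train_static(
    model: StaticGRNModel, X, split: DataSplit, cfg: TrainingConfig, target=None
) -> tuple[StaticGRNModel, TrainingLog]:
    """Train the static model on batches of cells (target defaults to the input)."""
    Xv = _matrix(X)
    Tv = Xv if target is None else _matrix(target)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), cfg.learning_rate, cfg.weight_decay)
    log = TrainingLog(config=cfg)
    train, val = split.train_idx, split.validation_idx

    for epoch in range(cfg.epochs):
        order = rng.permutation(train)
        losses = []
        for b, i in enumerate(range(0, len(order), cfg.batch_cells)):
            idx = order[i : i + cfg.batch_cells]
            inp = _dropout(Xv[idx], cfg.input_dropout, rng, cfg.dropout_scale)
            pred, _ = model.forward_graph(inp)
            loss = mse(pred, Tv[idx])
            _check_finite(loss.data, epoch, b)
            opt.zero_grad()
            loss.backward()
            opt.step()
            model.apply_mask()
            losses.append(float(loss.data))
        log.train_mse.append(float(np.mean(losses)))
        val_pred, _ = model.forward_graph(Xv[val])
        log.validation_mse.append(float(mse(val_pred, Tv[val]).data))
    return model, log


def _velocity_target(velocity, cells: np.ndarray) -> np.ndarray:
    """Velocity rows for given cells, missing rows imputed as zero."""
    V = velocity.dXdt if hasattr(velocity, "dXdt") else np.asarray(velocity, float)
    out = V[cells]
    return np.where(np.isfinite(out), out, 0.0)


def _single_step_loss(model_fwd, Xv, target, cells) -> float:
    preds = model_fwd(Xv[cells][None, ...])
    return float(np.mean((preds[0] - target) ** 2))


def _trajectory_val_loss(model_fwd, Xv, times, target_matrix, cells, cfg) -> float:
    """Validation MSE on trajectories of validation cells.

    Falls back to a single-step (zero hidden state) pass when the validation
    cells are too sparse to fill consecutive time bins.
    """
    try:
        batches = make_trajectories(
            Xv, times, bin_width=cfg.bin_width, length=cfg.trajectory_length,
            batch=len(cells), seed=0, cells=cells,
        )
    except ValueError:
        return _single_step_loss(model_fwd, Xv, target_matrix[cells], cells)
    num = den = 0.0
    for tb in batches:
        pred = model_fwd(tb.X_seq)
        tgt = target_matrix[tb.cell_indices]
        num += float(((pred - tgt) ** 2).sum())
        den += tgt.size
    return num / den


def train_dynamical(
    model: DynamicalGRNModel,
    X,
    times,
    split: DataSplit,
    cfg: TrainingConfig,
    target: str = "counts",
    velocity=None,
) -> tuple[DynamicalGRNModel, TrainingLog]:
    """Train the recurrent model on time-binned trajectories.

    ``target="counts"`` reconstructs the input sequence; ``target="velocity"``
    predicts the velocity rows of the same cells. Trajectories are discarded
    and rebuilt every epoch. Validation MSE is a single-step (zero hidden
    state) pass over the validation cells.
    """
    if target == "velocity" and velocity is None:
        raise ValueError("velocity target requires a VelocityEstimate")
    Xv = _matrix(X)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), cfg.learning_rate, cfg.weight_decay)
    log = TrainingLog(config=cfg)
    val = split.validation_idx
    all_cells = np.arange(len(Xv))
    val_matrix = (
        Xv if target == "counts" else _velocity_target(velocity, all_cells)
    )

    for epoch in range(cfg.epochs):
        batches = make_trajectories(
            Xv,
            times,
            bin_width=cfg.bin_width,
            length=cfg.trajectory_length,
            batch=cfg.batch_trajectories,
            seed=int(rng.integers(2**31)),
            cells=split.train_idx,
            n_per_offset=cfg.trajectories_per_offset,
        )
        losses = []
        for b, tb in enumerate(batches):
            inp = _dropout(tb.X_seq, cfg.input_dropout, rng, cfg.dropout_scale)
            outs, _, _ = model.forward_graph(inp)
            if target == "counts":
                tgt = tb.X_seq
            else:
                tgt = np.stack(
                    [_velocity_target(velocity, row) for row in tb.cell_indices]
                )
            loss = mse(_stack(outs), tgt)
            _check_finite(loss.data, epoch, b)
            opt.zero_grad()
            loss.backward()
            opt.step()
            model.apply_mask()
            losses.append(float(loss.data))
        log.train_mse.append(float(np.mean(losses)))
        log.validation_mse.append(
            _trajectory_val_loss(
                lambda s: np.stack(
                    [o.data for o in model.forward_graph(s)[0]]
                ),
                Xv,
                times,
                val_matrix,
                val,
                cfg,
            )
        )
    return model, log


def _stack(tensors) -> Tensor:
    """Stack a list of equally shaped Tensors along a new leading axis."""
    out = Tensor._from_op(
        np.stack([t.data for t in tensors]),
        tuple(tensors),
        lambda g: tuple(g[i] for i in range(len(tensors))),
    )
    return out


def train_decay(
    decay: DecayModule,
    X_denoised,
    decay_target,
    split: DataSplit,
    cfg: TrainingConfig,
    times=None,
) -> tuple[DecayModule, TrainingLog]:
    """Train the decay module toward the bounded decay-velocity estimate.

    ``decay_target`` is the per-cell matrix -lambda_bound * X_denoised. With
    ``times`` the module trains on trajectories; without, on batches of
    length-1 sequences.
    """
    Xv = _matrix(X_denoised)
    Tv = np.asarray(decay_target, float)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(decay.parameters(), cfg.learning_rate, cfg.weight_decay)
    log = TrainingLog(config=cfg)
    train, val = split.train_idx, split.validation_idx

    for epoch in range(cfg.epochs):
        if times is not None:
            batches = make_trajectories(
                Xv, times, bin_width=cfg.bin_width,
                length=cfg.trajectory_length, batch=cfg.batch_trajectories,
                seed=int(rng.integers(2**31)), cells=train,
                n_per_offset=cfg.trajectories_per_offset,
            )
            seqs = [(tb.X_seq, Tv[tb.cell_indices]) for tb in batches]
        else:
            order = rng.permutation(train)
            seqs = [
                (Xv[order[i : i + cfg.batch_cells]][None, ...],
                 Tv[order[i : i + cfg.batch_cells]][None, ...])
                for i in range(0, len(order), cfg.batch_cells)
            ]
        losses = []
        for b, (seq, tgt) in enumerate(seqs):
            inp = _dropout(seq, cfg.input_dropout, rng, cfg.dropout_scale)
            _, vels, _ = decay.forward_graph(inp)
            loss = mse(_stack(vels), tgt)
            _check_finite(loss.data, epoch, b)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        log.train_mse.append(float(np.mean(losses)))
        fwd = lambda s: np.stack([v.data for v in decay.forward_graph(s)[1]])
        if times is not None:
            log.validation_mse.append(
                _trajectory_val_loss(fwd, Xv, times, Tv, val, cfg)
            )
        else:
            log.validation_mse.append(_single_step_loss(fwd, Xv, Tv[val], val))
    return decay, log


def train_biophysical(
    model: BiophysicalModel,
    X,
    times,
    velocity,
    decay_target,
    split: DataSplit,
    cfg: TrainingConfig,
) -> tuple[BiophysicalModel, TrainingLog]:
    """Freeze/unfreeze schedule for the composite velocity model.

    Epochs up to ``freeze_decay_epochs``: decay weights frozen, transcription
    trained on total-velocity MSE. Afterwards: joint training on total-
    velocity MSE plus the decay module's MSE to its bounded target, the
    auxiliary term scaled by the ratio of target variances so neither loss
    numerically dominates the other.
    """
    Xv = _matrix(X)
    Tv = np.asarray(decay_target, float)
    vel_var = float(np.nanvar(
        velocity.dXdt if hasattr(velocity, "dXdt") else np.asarray(velocity)
    ))
    ratio = vel_var / max(float(Tv.var()), 1e-12)
    if cfg.decay_loss_weight == "balanced":
        aux_weight = ratio
    elif cfg.decay_loss_weight == "sqrt":
        aux_weight = np.sqrt(ratio)
    else:
        aux_weight = float(cfg.decay_loss_weight)
    rng = np.random.default_rng(cfg.seed)
    opt_t = Adam(model.transcription.parameters(), cfg.learning_rate, cfg.weight_decay)
    opt_d = Adam(model.decay.parameters(), cfg.learning_rate, cfg.weight_decay)
    log = TrainingLog(config=cfg)
    val = split.validation_idx
    val_matrix = _velocity_target(velocity, np.arange(len(Xv)))

    for epoch in range(cfg.epochs):
        frozen = epoch < cfg.freeze_decay_epochs
        batches = make_trajectories(
            Xv, times, bin_width=cfg.bin_width,
            length=cfg.trajectory_length, batch=cfg.batch_trajectories,
            seed=int(rng.integers(2**31)), cells=split.train_idx,
            n_per_offset=cfg.trajectories_per_offset,
        )
        losses = []
        for b, tb in enumerate(batches):
            inp = _dropout(tb.X_seq, cfg.input_dropout, rng, cfg.dropout_scale)
            vels, _, _, _, _ = model.forward_graph(inp)
            tgt = np.stack(
                [_velocity_target(velocity, row) for row in tb.cell_indices]
            )
            loss = mse(_stack(vels), tgt)
            if not frozen:
                _, dvels, _ = model.decay.forward_graph(inp)
                loss = loss + aux_weight * mse(_stack(dvels), Tv[tb.cell_indices])
            _check_finite(loss.data, epoch, b)
            opt_t.zero_grad()
            opt_d.zero_grad()
            loss.backward()
            opt_t.step()
            if not frozen:
                opt_d.step()
            model.apply_mask()
            losses.append(float(loss.data))
        log.train_mse.append(float(np.mean(losses)))
        log.validation_mse.append(
            _trajectory_val_loss(
                lambda s: np.stack(
                    [v.data for v in model.forward_graph(s)[0]]
                ),
                Xv,
                times,
                val_matrix,
                val,
                cfg,
            )
        )
    return model, log


def hyperparameter_grid(
    train_fn, gamma_grid, wd_grid, cfg: TrainingConfig
) -> pd.DataFrame:
    """Grid search over learning rate and weight decay.

    ``train_fn(cfg) -> {"r2": ..., "aupr": ...}`` trains and scores one
    configuration. Returns a table sorted by held-out AUPR then validation
    R-squared.
    """
    rows = []
    for gamma in gamma_grid:
        for wd in wd_grid:
            scores = train_fn(
                replace(cfg, learning_rate=float(gamma), weight_decay=float(wd))
            )
            rows.append(
                dict(gamma=float(gamma), weight_decay=float(wd), **scores)
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["aupr", "r2"], ascending=False)
        .reset_index(drop=True)
    )
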