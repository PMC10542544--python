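"""Ground-truth simulator for interval-sampled single-cell time series.

A small gene regulatory network with smoothly varying TF activities drives a
per-gene transcription rate alpha(t) = tfa(t) @ W; transcripts decay with a
first-order rate lambda (optionally stepping once mid-course), so expression
follows dX/dt = alpha(t) - lambda(t) * X. Cells are drawn uniformly over the
sampling span, assigned to pooled 10-minute collection windows, and observed
as Poisson counts at a fixed expected sequencing depth. The generator records
true expression, velocity, times, and kinetic parameters so every estimator
upstream can be scored against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .data import PriorNetwork, RawCounts

__all__ = [
    "GroundTruthGRN",
    "KineticTruth",
    "SimulatedExperiment",
    "simulate_truth",
    "simulate_cells",
    "make_benchmark",
]


@dataclass
class GroundTruthGRN:
    W_true: np.ndarray  # (k, g) nonnegative
    tfa_curves: Callable[[np.ndarray], np.ndarray]  # times -> (t, k) activities
    tf_ids: list[str]
    gene_ids: list[str]
    seed: int


@dataclass
class KineticTruth:
    alpha: Callable[[np.ndarray], np.ndarray]  # times -> (t, g) rates
    lam: Callable[[np.ndarray], np.ndarray]  # times -> (t, g) decay rates
    lambda_base: np.ndarray  # (g,) pre-step decay rates
    step_time: float | None
    step_factor: float


@dataclass
class SimulatedExperiment:
    counts: RawCounts
    true_expression: np.ndarray
    true_velocity: np.ndarray
    true_times: np.ndarray
    pool_of: np.ndarray
    truth: GroundTruthGRN
    kinetics: KineticTruth


def _piecewise_linear(knots_t, knots_v):
    knots_t = np.asarray(knots_t, float)
    knots_v = np.asarray(knots_v, float)

    def f(t):
        return np.interp(t, knots_t, knots_v)

    return f


def _tfa_shape(kind: str, t0: float, t1: float, rng) -> Callable:
    """Rising, falling or pulsatile activity curve on [t0, t1], range [0, ~2]."""
    # activities shut off to ~zero outside their active phase, as in a strong
    # transcriptional perturbation; decay-dominated phases are what make
    # decay rates observable at all. Change-point timing is TF-specific so
    # different TFs' activity profiles are distinguishable (real regulators
    # act at staggered times; synchronized mirror-image profiles would make
    # attribution ill-posed for any method)
    # staged response: repression completes early, pulses peak mid-course,
    # induction happens late, as in a staged transcriptional response
    amp = rng.uniform(1.0, 2.0)
    span = t1 - t0
    if kind == "falling":
        s0 = rng.uniform(0.05, 0.15)
        s1 = s0 + rng.uniform(0.1, 0.2)
        return _piecewise_linear(
            [t0, t0 + s0 * span, t0 + s1 * span, t1], [amp, amp, 0.0, 0.0]
        )
    if kind == "rising":
        s0 = rng.uniform(0.45, 0.6)
        s1 = s0 + rng.uniform(0.15, 0.25)
        return _piecewise_linear(
            [t0, t0 + s0 * span, t0 + s1 * span, t1], [0.02, 0.02, amp, amp]
        )
    # pulse
    mid = t0 + rng.uniform(0.3, 0.5) * span
    width = rng.uniform(0.1, 0.2) * span
    return _piecewise_linear(
        [t0, mid - width, mid, mid + width, t1], [0.0, 0.0, amp, 0.0, 0.0]
    )


def simulate_truth(
    k: int,
    g: int,
    seed: int,
    lambda_regime: str = "constant",
    t_span: tuple[float, float] = (0.0, 80.0),
    mean_out_degree: float = 1.5,
    step_time: float = 40.0,
    step_factor: float = 2.0,
) -> tuple[GroundTruthGRN, KineticTruth]:
    """Draw a sparse nonnegative GRN, TFA curves, and per-gene decay rates.

    Every gene receives at least one regulator; decay rates are log-uniform in
    [0.01, 0.2] per minute. ``lambda_regime="step"`` multiplies all decay
    rates by ``step_factor`` at ``step_time``.
    """
    if k < 1 or g < k:
        raise ValueError("need k >= 1 and g >= k")
    rng = np.random.default_rng(seed)

    W = np.zeros((k, g))
    extra_p = max(0.0, (mean_out_degree * k / g - 1.0) / max(k - 1, 1)) if k > 1 else 0.0
    for j in range(g):
        regs = {rng.integers(k)}
        for tf in range(k):
            if tf not in regs and rng.random() < extra_p:
                regs.add(tf)
        for tf in regs:
            W[tf, j] = rng.uniform(1.0, 4.0)

    shapes = ["falling", "rising", "pulse"]
    curves = [_tfa_shape(shapes[i % 3], *t_span, rng) for i in range(k)]

    def tfa(t):
        t = np.atleast_1d(np.asarray(t, float))
        return np.stack([c(t) for c in curves], axis=1)

    lam_base = np.exp(rng.uniform(np.log(0.01), np.log(0.2), size=g))
    stepped = lambda_regime == "step"

    def lam(t):
        t = np.atleast_1d(np.asarray(t, float))
        out = np.tile(lam_base, (len(t), 1))
        if stepped:
            out[t >= step_time] *= step_factor
        return out

    def alpha(t):
        return tfa(t) @ W

    truth = GroundTruthGRN(
        W_true=W,
        tfa_curves=tfa,
        tf_ids=[f"TF{i}" for i in range(k)],
        gene_ids=[f"G{j:04d}" for j in range(g)],
        seed=seed,
    )
    kin = KineticTruth(
        alpha=alpha,
        lam=lam,
        lambda_base=lam_base,
        step_time=step_time if stepped else None,
        step_factor=step_factor if stepped else 1.0,
    )
    return truth, kin


def simulate_cells(
    truth: GroundTruthGRN,
    kinetics: KineticTruth,
    n: int,
    t_span: tuple[float, float] = (0.0, 80.0),
    pool_width: float = 10.0,
    depth: float = 2000.0,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> SimulatedExperiment:
    """Integrate the kinetics once, sample cells along it, add Poisson noise.

    The initial condition defaults to the steady state of the t=0 kinetics
    (exponential-phase culture before perturbation). Counts are Poisson with
    per-cell expected depth ``depth``.
    """
    if n < 1:
        raise ValueError("need at least one cell")
    rng = np.random.default_rng(seed)
    t0, t1 = t_span
    g = len(truth.gene_ids)

    if x0 is None:
        x0 = kinetics.alpha(t0)[0] / kinetics.lam(t0)[0]
    x0 = np.asarray(x0, float)

    def rhs(t, x):
        return kinetics.alpha(t)[0] - kinetics.lam(t)[0] * x

    sol = solve_ivp(
        rhs, (t0, t1), x0, dense_output=True, max_step=1.0, rtol=1e-8, atol=1e-10
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")

    times = np.sort(rng.uniform(t0, t1, size=n))
    X_true = sol.sol(times).T  # (n, g)
    assert np.all(X_true >= -1e-9), "expression must stay nonnegative"
    X_true = np.clip(X_true, 0.0, None)
    V_true = kinetics.alpha(times) - kinetics.lam(times) * X_true

    row_sums = X_true.sum(axis=1)
    rates = X_true * (depth / np.where(row_sums > 0, row_sums, 1.0))[:, None]
    Z = rng.poisson(rates)
    # all-zero cells are unusable downstream; give them their most likely count
    empty = np.where(Z.sum(axis=1) == 0)[0]
    if len(empty) > 0:
        Z[empty, np.argmax(rates[empty], axis=1)] = 1

    pool_of = np.floor((times - t0) / pool_width).astype(int)
    pool_of = np.minimum(pool_of, int((t1 - t0) / pool_width) - 1)
    meta = pd.DataFrame(
        {
            "pool_id": pool_of,
            "genotype": "WT",
            "replicate": "rep1",
            "true_time": times,
        }
    )
    counts = RawCounts(Z=Z, gene_ids=list(truth.gene_ids), cell_meta=meta)
    return SimulatedExperiment(
        counts=counts,
        true_expression=X_true,
        true_velocity=V_true,
        true_times=times,
        pool_of=pool_of,
        truth=truth,
        kinetics=kinetics,
    )


_PRESETS = {
    "tiny": dict(k=3, g=20, n=500),
    "small": dict(k=10, g=100, n=2000),
    "medium": dict(k=25, g=500, n=10000),
}


def make_benchmark(
    preset: str,
    seed: int,
    contamination: float = 0.2,
    lambda_regime: str = "constant",
) -> tuple[SimulatedExperiment, PriorNetwork]:
    """Simulate a named benchmark and its (contaminated) prior network.

    The prior is the true network's support with a ``contamination`` fraction
    of additional false edges; gene-level holdout for evaluation is applied
    downstream with :func:`velogrn.data.holdout_prior_genes`.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    cfg = _PRESETS[preset]
    truth, kin = simulate_truth(cfg["k"], cfg["g"], seed, lambda_regime=lambda_regime)
    # expected depth scales with panel size: ~50 counts per gene per cell,
    # as for a panel restricted to well-expressed genes
    exp = simulate_cells(
        truth, kin, cfg["n"], depth=50.0 * cfg["g"], seed=seed + 1
    )

    P = (truth.W_true.T > 0).astype(int)  # (g, k)
    if contamination > 0:
        rng = np.random.default_rng(seed + 2)
        zeros = np.argwhere(P == 0)
        n_false = round(contamination * P.sum())
        if n_false > 0 and len(zeros) > 0:
            pick = rng.choice(len(zeros), size=min(n_false, len(zeros)), replace=False)
            P[zeros[pick, 0], zeros[pick, 1]] = 1
    prior = PriorNetwork(
        P=P, gene_ids=list(truth.gene_ids), tf_ids=list(truth.tf_ids)
    )
    return exp, prior
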