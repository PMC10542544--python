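"""Estimate RNA velocity and bound mRNA decay rates from one simulation.

Builds the self-supervised denoising graph, regresses expression change on
time change per cell, bounds each gene's decay rate on sliding windows, and
reports half-lives next to the simulated ground truth.
"""

import numpy as np
from scipy.stats import spearmanr

from velogrn.data import standardize_counts
from velogrn.evaluation import half_life
from velogrn.synthetic import make_benchmark
from velogrn.velocity import (
    build_denoising_graph,
    denoise,
    estimate_velocity,
    sliding_decay,
)
from velogrn.workflows import assign_times_from_pools

exp, _ = make_benchmark("tiny", seed=0)
Z = exp.counts

X = standardize_counts(Z)
graph = build_denoising_graph(X, pc_candidates=(3, 5, 8), k_candidates=(10, 20, 30), seed=0)
X_d = denoise(X, graph)
times, _ = assign_times_from_pools(Z, seed=0)
if spearmanr(times.t, np.asarray(Z.cell_meta["pool_id"]))[0] < 0:
    times.t = times.t.max() + times.t.min() - times.t

vel = estimate_velocity(X_d, times, graph)
bound = sliding_decay(X_d.X, vel.dXdt, times.t, window_width=20.0, step=10.0)
lam_bound = np.nanmax(np.atleast_2d(bound.lambda_min), axis=0)  # tightest window

lam_true = exp.kinetics.lambda_base
rho = spearmanr(lam_bound, lam_true)[0]
sound = np.mean(lam_bound <= lam_true + 1e-9)

print(f"denoising graph: {graph.selected_pcs} PCs, k={graph.selected_k}")
print(f"windows evaluated: {len(bound.window_centers)}")
print("\ngene  lambda_bound  lambda_true  half-life bound (min)")
for j in range(5):
    print(
        f"{exp.truth.gene_ids[j]}  {lam_bound[j]:.4f}       "
        f"{lam_true[j]:.4f}      {half_life(lam_bound[j]):8.1f}"
    )
print(f"\nrank correlation of bounds with true rates: {rho:.2f}")
print(f"fraction of genes with bound <= true rate:  {sound:.2f}")
print(
    "\nOn noise-free kinetics the estimator is a strict lower bound"
    "\n(transcription is nonnegative); on estimated velocities the extreme-"
    "\nratio quantile also collects estimation noise, so individual bounds"
    "\ncan overshoot while the gene ranking stays informative."
)
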