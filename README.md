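# velogrn

Continuous cell-time assignment, RNA velocity, mRNA decay-rate bounds, and
prior-constrained neural gene regulatory network (GRN) models for
interval-sampled single-cell RNA-seq.

## The problem

A perturbation time course sampled continuously into pooled collection
windows (say, eight sequential 10-minute intervals) observes each cell at an
unknown time within a known interval. If every cell can be placed on a
continuous axis in real minutes, transcript dynamics become measurable
without intron-based splicing ratios: the rate of change of expression

    dX/dt = alpha(t) − lambda(t) · X        alpha ≥ 0, lambda > 0

can be estimated per cell by regressing expression differences on time
differences within a k-NN neighborhood, the nonnegativity of transcription
turns the (X, dX/dt) cloud of each gene into a lower bound on its decay
rate lambda, and a neural network whose first hidden layer is masked by a
prior TF→gene network can decompose the velocity into an interpretable
transcription component plus a decay component. Zeroing one TF's hidden
node deletes it in silico; ranking TF→gene pairs by how much variance the
deletion leaves unexplained (explained relative variance, ERV) yields a
GRN that is scored against prior edges held out of the mask.

The package is aimed at computational biologists who have (or simulate)
interval-sampled count matrices and a binary prior network, and want the
full chain — standardization, gene-program partitioning, time assignment,
velocity, decay bounds, linear and neural GRN inference, evaluation — as
composable Python functions.

## Worked example

`examples/01_assign_cell_times.py` simulates a pooled time course
(8 × 10-minute windows, 500 cells, 20 genes, Poisson counts), assigns each
cell a time in minutes by centroid projection, and prints:

```
cells: 500, pools: 8 x 10 minutes
ordering vs collection interval (projected times): 0.976
ordering vs collection interval (PCA pseudotime):  0.931
rank agreement with the true simulation times:     0.982
```

The projected times order cells better than a PCA pseudotime baseline and
track the hidden true sampling times at rank correlation 0.98.

`examples/02_velocity_and_decay.py` continues to velocity and decay-rate
bounds (rank correlation of the bounds with true decay rates ≈ 0.66 on the
same simulation), and `examples/03_biophysical_grn.py` trains the full
biophysical model (an ensemble of three initializations) and scores it as
a GRN; on the same simulation it prints:

```
ordering of assigned times vs pools:     0.976
velocity fit R^2 (estimated target):     0.371
decay-rate recovery (Spearman rho):      0.600
held-out edge AUPR:                      0.671
  (edge prevalence in the universe:      0.333)
```

— regulatory edges the model never saw in its prior mask are recovered at
twice the chance level, and the decay module's per-gene rates rank the
simulated true rates at Spearman 0.6. `examples/04_linear_baseline.py`
runs the linear TFA + stability-selected LASSO baseline (on an
uncontaminated prior it recovers all 20 true edges with 2 false
positives).

A minimal API tour:

```python
from velogrn import (
    standardize_counts, build_denoising_graph, denoise, estimate_velocity,
    sliding_decay, BiophysicalModel, train_biophysical, erv_matrix, aupr,
)
```

Each stage accepts and returns plain dataclasses around numpy arrays; see
`docs/methods.md` for the model, its assumptions, and every tunable
parameter with units and defaults.

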