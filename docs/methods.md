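# Methods

## The model

Transcript abundance X (counts) of each gene evolves as

    dX/dt = alpha(t) - lambda(t) * X,    alpha >= 0,  lambda > 0

with transcription rate `alpha` (counts/min) set by transcription factor
(TF) activity and first-order decay rate `lambda` (1/min). The package
estimates both terms from interval-sampled single-cell RNA-seq: cells are
collected continuously into pooled 10-minute windows, so every cell carries
an (unknown) real time within a known interval. The analysis proceeds in
stages, each usable on its own:

1. **Standardization** (`data`). Each cell is scaled to a common depth
   (default: the median per-cell sum), then each gene is divided by its
   standard deviation when the variance exceeds the squared interquartile
   range, by the IQR otherwise, and left alone when the IQR is zero;
   zero-variance genes are dropped. After this no gene has variance above
   one, which keeps the gene-wise losses of all downstream models on a
   common scale.

2. **Programs** (`programs`). Log expression is reconstructed from the
   first N principal components, N chosen by molecular cross-validation
   (each UMI split binomially into train/test halves; N minimizes the
   reconstruction error of the held-out half). Genes are Leiden-clustered
   on a cosine k-NN graph (k = 21, resolution 1 by default), each cluster's
   cells are ordered on a circle by the cluster's first principal
   component, and clusters are merged into exactly two programs by
   average-linkage agglomeration on one minus the Fisher–Lee circular
   correlation of those orderings. One program captures the perturbation
   response, the other the cell cycle; which is which is labelled by size
   (the response program is larger in the motivating design) and can be
   overridden.

3. **Time assignment** (`cell_times`). Cells of one program are embedded
   into 5–8 MCV-selected PCs; each collection pool contributes a centroid
   with a known time (defaults ship for a rapamycin-style design: −5, 5,
   …, 55 min; and for cell-cycle phases with an 88-minute period).
   Consecutive centroids are joined by Dijkstra shortest paths on a
   euclidean cell k-NN graph (k = 10); each cell is assigned to the segment
   whose path nodes contain its nearest node and receives the fractional
   scalar projection of its embedding onto the straight centroid-to-
   centroid vector, mapped onto the centroid time interval. Projections
   may extrapolate past the segment ends; a clamp option truncates them
   (the pipeline uses the clamp — unclamped projections occasionally
   produce times far outside the sampled range when PC1 curvature is
   strong). Periodic programs wrap at the stated period.

4. **Velocity** (`velocity`). A denoising k-NN graph is selected by
   self-supervision: pseudo-molecules are split in half, and the
   (PCs, k) pair whose inverse-distance-weighted neighbor average of the
   train half best predicts the test half wins. Velocity is then, per
   cell, the no-intercept regression slope of neighbor expression
   differences on neighbor time differences (minimal signed circular
   difference under wrapping). Cells with fewer than two neighbors or
   all-zero time differences are flagged missing rather than zeroed.

5. **Decay bound** (`velocity.decay_bound`). For one gene, the cells with
   the smallest 5% of velocity/expression ratios are fit by OLS through
   the origin; minus the slope, clipped at zero, bounds `lambda` from
   below under `alpha >= 0`. On noise-free kinetics this is a strict lower
   bound; on estimated velocities the extreme-ratio quantile also collects
   estimation noise, so individual bounds can overshoot while the gene
   ranking remains informative. Sliding windows (default 20 min wide,
   10 min step, at least 20 positive-expression cells) give a
   time-resolved version; the training target for the decay module uses
   each gene's tightest (maximum) window bound, because every window's
   value is a valid bound and windows without decay-dominated cells would
   otherwise drag the target toward zero.

6. **Models** (`grn_models`, `training`). All variants share a bias-free
   masked encoder: genes map to one hidden node per TF, weights are zero
   wherever the binary prior network is zero (re-applied after every
   optimizer step), and a ReLU keeps the hidden layer nonnegative so it is
   interpretable as TF activity. The static model decodes through one
   fully connected hidden layer; the dynamical model replaces it with a
   ReLU recurrence over trajectories (one random cell per consecutive
   1-minute time bin); the decay module is an unmasked tanh/Softplus
   encoder and recurrence decoding nonnegative per-gene decay rates whose
   velocity contribution is −lambda·X; the biophysical model sums a
   Softplus-positive dynamical transcription module and the decay module,
   so its output decomposes velocity into production and decay exactly.
   In-silico perturbation multiplies the TFA layer by a diagonal matrix;
   zeroing an entry deletes that TF everywhere downstream.

   Training uses Adam with L2 weight decay and mean-squared error, with
   50% of input genes dropped at random each batch (inverted scaling by
   default, so evaluation-time inputs match the training expectation —
   plain zeroing is available but biases the train/eval input scale).
   The biophysical schedule freezes a pre-trained decay module for 100
   epochs while the transcription module learns total velocity, then
   unfreezes it and adds the decay module's MSE to its bounded target.
   The two joint losses are weighted 1:1 by default; a variance-balanced
   option down-weights the auxiliary term by the ratio of target
   variances when the decay targets are much larger than the velocities.

7. **Evaluation** (`evaluation`). A trained model is read out as a GRN by
   explained relative variance: for each TF the model is re-run with that
   TF's hidden node zeroed (no retraining) and each gene scores
   1 − RSS_full/RSS_reduced. Edges of genes whose prior rows were held
   out of the mask are ranked by ERV and scored by area under the
   precision–recall curve. Model fit is the coefficient of determination;
   per-TF marginal error is the gradient–activity product at the TFA
   layer, summed over trajectory time and averaged over trajectories;
   half-life is ln 2 / lambda.

## Numerical and design choices

* **No deep-learning framework.** The models run on a small reverse-mode
  autodiff engine over numpy (`_autograd`) with a matching Adam; the
  networks here are hundreds to a few thousand parameters, where numpy
  matmuls are faster than framework overhead and the engine is ~200 lines
  that are themselves finite-difference tested.
* **Output unit scales.** A Softplus output head can only produce values
  near zero with strongly negative pre-activations, where its gradient
  vanishes; fitting velocity targets of magnitude ~0.03 this way stalls
  and the optimizer instead destroys the encoder (dead TFA nodes). The
  transcription and decay heads therefore decode in fixed data-derived
  units (`output_scale`, `rate_scale`: the mean absolute velocity target
  and the 0.9 quantile of the decay bounds), keeping the nonlinearity in
  its responsive range. These are constants fixed before training, not
  trained parameters — a choice of units, not extra capacity.
* **Encoder initialization.** Inputs are nonnegative, so signed random
  init can start a TF node with all-negative pre-activations that the
  ReLU then silences permanently; encoder weights start nonnegative. The
  hidden mixing matrices start near identity (recurrence small), keeping
  hidden channel j aligned with TF j, which the knockout readout relies
  on.
* **StARS selection.** Edge divergence is the fraction of edges present
  in some but not all of twenty half-subsample supports, among edges
  present in any. Taken literally, "the smallest penalty with divergence
  below 5%" lands in the saturated dense end of the path, where all
  subsamples trivially agree; the implementation instead walks the path
  toward density through the first stable stretch after support appears
  and stops where subnetworks start disagreeing. The path starts at the
  largest subsample-wise penalty with empty support.
* **Validation losses** for recurrent models are computed on trajectories
  drawn from validation cells, falling back to a single-step pass when
  those cells are too sparse to fill consecutive bins.
* **Average precision under a random ranking** is not exactly the
  positive prevalence: it carries a known positive O(log N / N)
  finite-sample bias. The calibration test compares the Monte-Carlo mean
  to the exact negative-hypergeometric null expectation, which converges
  to prevalence as the universe grows.

## The synthetic generator

`synthetic` simulates what the pooled-interval experiment measures: a
sparse nonnegative TF-to-gene weight matrix (every gene at least one
regulator), piecewise-linear TF activities in three staged shapes —
repression completing early, a mid-course pulse, late induction — with
activity essentially zero outside the active phase (a strong perturbation
response; the decay-dominated phases this creates are what make decay
rates observable at all), per-gene decay rates log-uniform on
[0.01, 0.2] min⁻¹ (half-lives of ~3.5–70 min) with an optional single
step change, deterministic ODE integration from the t = 0 steady state,
uniform cell sampling over an 80-minute course split into eight 10-minute
pools, and Poisson counts at a depth of ~50 expected counts per gene per
cell (a panel of well-expressed genes). Presets: tiny (3 TFs, 20 genes,
500 cells), small (10/100/2000), medium (25/500/10000). The benchmark
prior is the true support plus 20% false edges; a quarter of edge-bearing
genes' rows are withheld from the training mask and form the evaluation
universe.

What the generator does **not** emulate: overdispersed (negative
binomial) counts beyond an optional parameter, ambient RNA, doublets,
batch effects, cell-to-cell kinetic heterogeneity (all cells share one
deterministic trajectory per program), or post-transcriptional regulation
of decay. Passing tests on it therefore demonstrate correctness of the
estimators under the stated model, not robustness to those artifacts.

One consequence of depth normalization is worth noting: when total mRNA
falls over the course (as it does under strong repression), the velocity
of depth-normalized expression contains a shared −X·dlog S/dt term that
is not separable into per-gene production and decay; it is absorbed by
the fitted modules and slightly biases absolute rate estimates while
leaving rankings intact.

## Problem sizes and runtimes

The shipped benchmark pipeline (`workflows.kinetics_benchmark`) uses the
tiny preset with 500 biophysical epochs, 300 decay-pretraining epochs,
learning rate 2×10⁻³ (5×10⁻³ for pretraining), weight decay 10⁻⁷,
trajectory length 10 bins of 1 minute, five trajectories per start offset
per epoch, and an ensemble of three independently initialized biophysical
models whose ERV and decay readouts are averaged (knockout attribution at
a three-TF scale is sensitive to the optimization path; averaging
independent fits stabilizes it, as subsample ensembles do for the linear
baseline); one seed takes one to two minutes on one CPU. The default
TrainingConfig mirrors the full-scale choices (learning rate 5×10⁻⁵,
weight decay 10⁻⁷, dropout 0.5, batches of 250 cells / 20 trajectories),
which suit much larger data than the desk-scale benchmarks.

## Known limitations

* With only three TFs, temporally correlated activity curves make edge
  attribution by knockout intrinsically noisy; the recurrent model can
  partially reconstruct a knocked-out channel from the others, so ERV is
  conservative. Larger TF panels (as in real priors) separate better.
* The decay bound is an inequality, not an estimator of lambda; absolute
  recovered rates inherit its bias and the normalization term above.
  Rank-based summaries are the supported readout.
* Iterative forward prediction uses explicit Euler with dt = 1 min and a
  nonnegativity clamp; stiff regimes (half-life below ~2 min) would need
  a smaller step.
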