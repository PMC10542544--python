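"""Linear network inference baseline: prior-based TFA plus StARS LASSO.

Estimates TF activity by the minimum-norm solution of A P^T ~ X, fits
gene-wise LASSO models along a stability-selected penalty path, and scores
the recovered support against the simulated network.
"""

import numpy as np

from velogrn.data import standardize_counts
from velogrn.grn_linear import estimate_tfa, lasso_stars
from velogrn.synthetic import make_benchmark

exp, prior = make_benchmark("tiny", seed=0, contamination=0.0)
X = standardize_counts(exp.counts)

tfa = estimate_tfa(X, prior)
grn = lasso_stars(tfa, X, seed=0, n_alphas=25)

support = np.abs(grn.beta) > 1e-8
gold = exp.truth.W_true > 0
tp = int((support & gold).sum())
fp = int((support & ~gold).sum())
fn = int((~support & gold).sum())

print(f"TF activity matrix: {tfa.A_hat.shape[0]} cells x {tfa.A_hat.shape[1]} TFs")
print(f"selected penalty: {grn.lambda_selected:.4g}")
print(f"edges recovered: {tp} true positives, {fp} false positives, {fn} missed")
print(
    "\nThe stability-selected LASSO keeps edges whose support agrees across"
    "\ntwenty half-subsamples; with an uncontaminated prior most true edges"
    "\nsurvive selection."
)
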