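"""Train the biophysical model end to end and score it as a GRN.

Runs the full pipeline on the tiny benchmark (3 TFs, 20 genes, 500 cells):
time assignment, velocity, decay bounds, decay-module pretraining, the
freeze/unfreeze biophysical schedule, then decay-rate recovery and held-out
edge recovery by explained relative variance. Takes a couple of minutes.
"""

from velogrn.workflows import kinetics_benchmark

result = kinetics_benchmark("tiny", seed=0)

print(f"ordering of assigned times vs pools:     {result.ordering_rho:.3f}")
print(f"velocity fit R^2 (estimated target):     {result.velocity_r2:.3f}")
print(f"decay-rate recovery (Spearman rho):      {result.lambda_spearman:.3f}")
print(f"held-out edge AUPR:                      {result.network_aupr:.3f}")
print(f"  (edge prevalence in the universe:      {result.edge_prevalence:.3f})")
print(
    "\nAUPR well above prevalence means TF-knockout variance attribution"
    "\nrecovers regulatory edges the model never saw in its prior mask;"
    "\nthe Spearman rho compares the decay module's per-gene mean rates"
    "\nwith the simulation's true rates."
)
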