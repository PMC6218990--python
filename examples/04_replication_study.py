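"""A miniature replication study.

Runs the full pipeline (generate -> tune over the grid -> score) on a
scaled-down exponential scenario (n = 250, p = 100, 3 replications) and
prints the per-tau averages of the selection and prediction metrics.
A full-size study is run the same way via `run_study(1, 50, seed)` or
`survemvs study --scenario 1 --reps 50`.
"""

import survemvs as sv
from survemvs.simulate import SimScenario

small = SimScenario(family="exponential", shape=1.0, n=250, p=100)
report = sv.run_study(1, n_replications=3, seed=5, scenario=small)

print("per-replication rows:")
print(report.per_rep[["rep", "tau", "tpr", "fdr", "mse", "cindex", "v0", "v1"]]
      .to_string(index=False))
print("\naverages by EBIC flavour (tau):")
print(report.summary.to_string(index=False))
# tau indexes the EBIC penalty strength: tau=0 is the plain BIC, larger tau
# penalizes the size of the model space and yields sparser selections.
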