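"""Demonstrate double robustness of the augmented estimator on a small
replication study.

The monotone benchmark generates missingness from a model in U = |X|^1.5;
feeding the analysis X instead of U misspecifies the missingness models.
IPW inherits that bias; AIPW stays nearly unbiased because its outcome
regressions are still correct.  (A scaled-down study — 150 replicates of
n = 500 — so the printed biases carry Monte-Carlo error of roughly
plus/minus 1 on the x100 scale.)
"""

import mortalcohort as mc

design = mc.SimulationDesign(study="monotone", n=500, scenario="missingness")
summary = mc.run_replication_study(design, methods=("ipw", "aipw"),
                                   n_reps=150, seed=3, n_truth=1_000_000)

print("monotone study, missingness models misspecified (U -> X), "
      f"{summary.n_reps} replicates\n")
print("method   bias x100 (beta5)   empirical SE x100")
for m in ("ipw", "aipw"):
    print(f"{m:6s} {summary.value(m, 5, 'bias100'):12.2f}"
          f" {summary.value(m, 5, 'se100'):19.2f}")
print("\nIPW is biased because its weights come from the wrong model;")
print("AIPW's augmentation by the (correct) outcome regressions removes")
print("essentially all of that bias — the double-robustness property.")
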