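"""Sweep the sensitivity parameter gamma over a grid and watch the
estimates move.

gamma is the residual log-odds effect of the current outcome on being
missing, fixed a priori rather than estimated; exp(gamma) is the odds
ratio of missingness per unit outcome.  Here the data were generated with
gamma = -0.2, so the sweep from 0 to -0.4 brackets the truth: the
estimates drift steadily downward as the assumed non-ignorability grows,
and the drift per 0.1 of gamma (about 0.05 here) is what a sensitivity
report communicates — how much the conclusion moves per unit of an
assumption the data cannot check.
"""

import numpy as np

import mortalcohort as mc

truth = mc.true_beta("nonmonotone", "montecarlo", n_oracle=1_000_000, seed=99)
data = mc.simulate_nonmonotone(
    mc.SimulationDesign(study="nonmonotone", n=20_000, seed=21))
miss_designs, reg_builder = mc.analysis_designs("nonmonotone", "none")

grid = mc.gamma_grid("linear", stop=-0.4, step=0.1)
table = mc.sensitivity_grid(data, grid, methods=("ipw",), pattern="nonmonotone",
                            miss_designs=miss_designs, reg_builder=reg_builder)

b5 = table[table["parameter"] == 5]
print(f"true beta5 (visit-5 contrast): {truth[4]:.3f}\n")
print("assumed gamma   IPW beta5   error")
for _, row in b5.iterrows():
    err = row["estimate"] - truth[4]
    print(f"{row['gamma_value']:13.2f}   {row['estimate']:9.3f}   {err:+.3f}")
print("\nAt this sample size the smallest error sits at the generating")
print("gamma; in a real analysis gamma is unknowable, so the report shows")
print("all rows and lets the reader judge how much non-ignorability it")
print("would take to change the conclusion.")
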