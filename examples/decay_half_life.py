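"""Fit protein decay kinetics and compare two conditions.

Simulates Western-blot-style intensity time courses for a fast-degrading
wild-type protein (k = 0.49/h) and a stabilised mutant (k = 0.17/h), fits
y(t) = (1-b) exp(-kt) + b to each, and reports half-lives with propagated
errors plus per-timepoint Welch tests on log2 intensities.
"""

import pandas as pd

from somitoclock.pipeline import run_decay_pipeline
from somitoclock.synth import DecaySimSpec, generate_decay_series

wt = generate_decay_series(
    DecaySimSpec(k=0.49, b=0.14, noise_cv=0.1, n_replicates=3, seed=1), "wt")
mut = generate_decay_series(
    DecaySimSpec(k=0.17, b=0.048, noise_cv=0.1, n_replicates=3, seed=2), "mut")

result = run_decay_pipeline(pd.concat([wt, mut], ignore_index=True))
for cond, fit in result["fits"].items():
    print(f"{cond}: k = {fit['k']:.2f} ± {fit['se_k']:.2f} /h, "
          f"b = {fit['b']:.2f}, t1/2 = {fit['t_half']:.1f} ± {fit['se_t_half']:.1f} h")
print(result["comparison"].round(4).to_string(index=False))

# The half-life is ln(2)/k: ~1.4 h for the wild type and ~4 h for the
# stabilised mutant.  The BH-adjusted p-values show the remaining protein
# differs between conditions at the late timepoints.
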