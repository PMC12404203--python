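"""Classify nuclei by a bimodal marker-intensity histogram.

Simulates a per-nucleus marker table (two lognormal populations), removes
cells near the image border, finds the histogram-valley threshold on the
log-total metric, and quantifies the group difference with the rank-based
effect size r = |Z|/sqrt(N).
"""

import pandas as pd

from somitoclock.nuclei import (
    bimodal_threshold,
    classify_cells,
    filter_boundary_cells,
    marker_metric,
    rank_effect_size,
)
from somitoclock.synth import NucleiSimSpec, generate_nuclei_table

low = generate_nuclei_table(
    NucleiSimSpec(n_cells=1500, pos_fraction=0.3, seed=1), group="wt")
high = generate_nuclei_table(
    NucleiSimSpec(n_cells=1500, pos_fraction=0.6, seed=2), group="mutant")
table = filter_boundary_cells(
    pd.concat([low, high], ignore_index=True), (1024, 1024))

values = marker_metric(table, metric="log_total")
threshold = bimodal_threshold(values)
result = classify_cells(values, threshold, table["group"].to_numpy(),
                        metric_name="log_total")
print(f"threshold on log-total signal: {threshold:.2f}")
print(result.proportions.round(3))

es = rank_effect_size(values[table["group"] == "wt"],
                      values[table["group"] == "mutant"])
print(f"W = {es.W:.0f}, Z = {es.Z:.2f}, r = {es.r:.3f} ({es.magnitude})")

# The valley of the bimodal histogram separates marker-negative from
# marker-positive nuclei; the positive fraction per group recovers the
# simulated 30% vs 60%, and r grades how strongly the groups differ.
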