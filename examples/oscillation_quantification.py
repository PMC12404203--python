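"""Quantify segmentation-clock oscillations in two synthetic somitoid cohorts.

Generates six wild-type-like movies (posterior-origin travelling wave,
258-min period) and six mutant-like movies (centre-origin wave, 278-min
period, elevated troughs), runs the full pipeline — segmentation, A-P axis,
kymograph, peak detection — and compares the recovered features.
"""

import numpy as np

from somitoclock.kymo import compare_cohorts
from somitoclock.pipeline import PipelineConfig, analyze_movie
from somitoclock.synth import PRESETS, generate_cohort


def run_cohort(preset_name, base_seed, config):
    summaries = []
    for movie, _truth in generate_cohort(PRESETS[preset_name], 6, base_seed):
        summary, _ = analyze_movie(movie, config)
        summaries.append(summary)
    return summaries


config = PipelineConfig()
wt = run_cohort("wt_embedded", 1, config)
mut = run_cohort("s2513a_embedded", 101, config)

print("wild type:  period %.0f min, trough %.0f a.u., amplitude %.0f a.u., "
      "directionality scores %s" % (
          np.mean([s.mean_period for s in wt]),
          np.mean([s.trough_intensity for s in wt]),
          np.mean([s.amplitude for s in wt]),
          [s.directionality_score for s in wt]))
print("mutant:     period %.0f min, trough %.0f a.u., amplitude %.0f a.u., "
      "directionality scores %s" % (
          np.mean([s.mean_period for s in mut]),
          np.mean([s.trough_intensity for s in mut]),
          np.mean([s.amplitude for s in mut]),
          [s.directionality_score for s in mut]))

for feature in ("mean_period", "trough_intensity", "amplitude"):
    comp = compare_cohorts(wt, mut, feature, seed=1)
    print(f"{feature}: mutant/wt ratio {comp.ratio_percent:.0f}%, "
          f"difference {comp.difference:+.1f} "
          f"(bootstrap 95% CI {comp.ci_low:+.1f} .. {comp.ci_high:+.1f})")

# The period lengthens by ~20 min in the mutant, troughs sit near 185% of
# wild type, and the amplitude collapses to ~51% — the mutant oscillates
# around an elevated floor.  Score 3 = clear posterior-to-anterior wave;
# score 1 = oscillating but without directional progression.
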