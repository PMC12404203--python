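# somitoclock

Quantification of segmentation-clock dynamics in human somitoids — iPSC-derived
organoids of the presomitic mesoderm (PSM) that oscillate a HES7 fluorescent
reporter with a ~4–5 h period and bud off somites. The package is written for
researchers analysing such time-lapse recordings and the accompanying
biochemistry: it measures how perturbing NICD (NOTCH1 intracellular domain)
turnover changes the clock's period, trough level, amplitude and wave
directionality, how fast NICD itself decays, and how nuclear marker levels
shift between genotypes.

Three analysis tracks:

1. **Oscillation pipeline** — from a time-lapse movie `(t[,z], y, x)`:
   z-projection, robust percentile normalisation, classical mask segmentation
   (external masks pluggable), anteroposterior axis construction
   (principal axis → K-means (k=5) on foreground pixels → exact
   travelling-salesman ordering of the cluster centres → piecewise-linear
   midline, posterior end identified by reporter intensity), then a kymograph
   by averaging the median+Gaussian-filtered signal along local perpendiculars
   to the axis. Peaks and troughs of the anterior trace are detected under a
   3 h minimum-period constraint; the period is the mean time between
   successive peaks (first three intervals), the per-cycle amplitude is
   peak − mean of flanking troughs, and an ordinal 0–3 score grades
   posterior-to-anterior wave progression.
2. **Decay kinetics** — fits `y(t) = (1 − b)·e^(−kt) + b` to replicate decay
   time courses normalised to t = 0; the half-life is `t½ = ln(2)/k` with the
   delta-method error `se(t½) = ln(2)·se(k)/k²`; conditions are compared per
   timepoint by Welch t-tests on log₂ intensities with Benjamini–Hochberg
   adjustment.
3. **Nuclear quantification** — per-ROI mean intensities, removal of cells
   within 10% of the image border, bimodal-histogram valley thresholds
   (Freedman–Diaconis bins, 3-bin smoothing) to split marker-negative from
   marker-positive nuclei, and the rank-based effect size
   `r = |Z|/√N`, `Z = |W − n₁n₂/2| / √(n₁n₂(n₁+n₂+1)/12)`
   (small < 0.3 ≤ moderate < 0.5 ≤ large).

A synthetic-data module generates somitoid movies carrying travelling or
centre-originating intensity waves with known period/baseline/amplitude,
replicate decay series, and bimodal nuclear tables — with recorded ground
truth, so every pipeline stage can be checked against what was simulated.

## Worked example

`examples/oscillation_quantification.py` generates six wild-type-like movies
(posterior-origin wave, 258 min period) and six mutant-like movies
(centre-origin wave, 278 min period, elevated baseline), runs the full
pipeline on each, and compares cohorts:

```
wild type:  period 257 min, trough 102 a.u., amplitude 189 a.u., directionality scores [3, 3, 3, 3, 3, 3]
mutant:     period 280 min, trough 186 a.u., amplitude 97 a.u., directionality scores [1, 1, 1, 1, 1, 1]
mean_period: mutant/wt ratio 109%, difference +23.3 (bootstrap 95% CI +23.3 .. +23.3)
trough_intensity: mutant/wt ratio 183%, difference +84.4 (bootstrap 95% CI +84.3 .. +84.5)
amplitude: mutant/wt ratio 51%, difference -92.3 (bootstrap 95% CI -92.4 .. -92.1)
```

The mutant's clock runs ~23 min slower, oscillates around a floor near 185%
of the wild-type trough with roughly half the amplitude, and its waves lack
posterior-to-anterior directionality (score 1 vs 3). See also
`examples/decay_half_life.py` (half-life fitting and per-timepoint
comparison) and `examples/nuclear_classification.py` (bimodal threshold and
effect size).

The same machinery is scriptable from a shell:

```bash
somitoclock simulate --preset wt_embedded --n 6 --seed 1 --out movies/
somitoclock oscillate movies/*.tif --out results/
somitoclock decay-fit decay.csv --out results/
somitoclock nuclei cells.csv --out report.json
```

## Layout

- `src/somitoclock/synth.py` — synthetic movies, decay series, nuclei tables
- `src/somitoclock/preprocess.py` — projection, normalisation, segmentation
- `src/somitoclock/axis.py` — A-P axis and morphometrics
- `src/somitoclock/kymo.py` — kymographs and oscillation features
- `src/somitoclock/decay.py` — decay fits and half-lives
- `src/somitoclock/nuclei.py` — nuclear quantification and effect sizes
- `src/somitoclock/pipeline.py`, `cli.py`, `io.py` — orchestration, CLI, I/O
- `docs/methods.md` — models, parameters, numerical choices, limitations
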