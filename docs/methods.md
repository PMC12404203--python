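# Methods

## The measurement problem

Somitoids — iPSC-derived organoids of the presomitic mesoderm — express a
fast-maturing HES7 fluorescent reporter whose intensity oscillates with the
segmentation clock and travels as a kinematic wave from the posterior toward
the anterior of the tissue. Quantifying these recordings requires reducing a
`(t, y, x)` movie to a 1D tissue coordinate over time (a kymograph) and then
to scalar features: period, trough and peak levels, amplitude, number of
sustained cycles, and whether the waves progress posterior→anterior. Two
companion assays — protein decay time courses and fixed-cell nuclear
immunofluorescence — have their own estimators (half-life with error, and
bimodal-threshold classification with rank effect sizes).

## Oscillation pipeline

**Filtering.** Each frame is despeckled with a 3×3 median filter and smoothed
with a Gaussian of σ = 1 px; the kymograph itself is Gaussian-smoothed with
σ = 1 (rows and columns). These neighbourhood sizes suit shot-noise-limited
10× confocal data where the tissue is hundreds of pixels long; they are all
configurable.

**Segmentation.** The built-in segmenter is deliberately classical: Otsu
threshold on the percentile-normalised time-mean reporter frame, binary
opening (radius 2 px), largest connected component, hole filling. It is a
stand-in adequate for bright, well-separated tissue; masks from any external
tool can be passed in and override it. One mask is computed per movie (from
the time mean) because one axis is derived per somitoid; per-frame masking is
not attempted.

**Axis construction.** Foreground pixel coordinates are clustered by K-means
(k = 5) seeded at equally spaced points along the mask's principal axis, the
cluster centres are ordered by an exact exhaustive travelling-salesman search
over open paths (k = 5 gives 60 distinct paths; k ≤ 10 enforced), and the
ordered centres are joined by piecewise-linear interpolation resampled at
1-px arc steps. k = 5 centres give the midline enough flexibility to follow
the gentle C-shaped bend of an elongated somitoid without oscillating.

**Orientation.** Which end is posterior is decided by signal: the posterior
PSM expresses the reporter at a higher mean level, so s = 0 is assigned to
the endpoint whose surrounding disc (radius = half the mean tissue width) is
brighter in the time-averaged movie. The rule can be overridden
(`orientation: keep|reverse`); `reverse` flips the automatic assignment. For
a pure cosine wave spanning exactly one wavelength the two endpoint phases
coincide and time-averaged intensity alone cannot discriminate — in real
tissue (and in the synthetic movies, whose band is widest at the posterior)
the posterior is brighter for geometric and expression reasons.

**Kymograph.** At each of the ~N axis samples the signal is sampled at 1-px
steps along the local perpendicular (central-difference normals), restricted
to the mask, and averaged; rows whose perpendicular misses the mask entirely
are filled from the nearest valid row with a warning. Row 0 is posterior.

**Feature extraction.** The anterior trace is the mean of a 5-row window
centred at arc fraction 0.8 — far enough anterior to report the arriving
wave, far enough from the tissue edge to stay well-sampled; the offset is
configurable because different recordings place the oscillatory domain
differently. Peaks and troughs come from local-extremum detection with a
minimum separation of 3 h (the minimum credible clock period in human PSM;
18 frames at 10-min sampling) and a prominence of at least 10% of the trace
range, with same-type neighbours resolved by keeping the stronger so that
peaks and troughs interleave. The period is the mean of at most the first
three inter-peak intervals (later cycles can damp or drift; a flag enables
the full-series mean); per-cycle amplitude is the peak minus the mean of its
flanking troughs; the damping ratio is last-cycle over first-cycle amplitude.

**Directionality score (0–3).** An automated surrogate for manual grading of
wave progression. The anterior trace defines the cycles; score 0 when it has
fewer than two detected peaks *or* its peak-to-trough span is below 5% of
its mean level (prominence is scale-free, so a flat noisy trace needs this
floor to register as "no/poor oscillations"). For each cycle the wave ridge
is tracked across rows — each row's peak is matched to the one nearest the
previous row's matched time, which follows a travelling wave without phase
wrapping — and the matched peak times are regressed on row index. A cycle is
directional when the slope is positive with p < 0.05. Score 3 when ≥ 75% of
cycles are directional, 2 at 50–75%, 1 otherwise. The class boundaries are
design choices validated on synthetic ground truth only. A naive
nearest-to-a-fixed-anchor assignment was rejected: when one wavelength spans
the axis it wraps phase mid-tissue and biases the fitted slope negative even
for a clean posterior→anterior wave.

**Cohort comparison.** Features are compared as group means with the
mutant/wild-type ratio in percent and a seeded bootstrap 95% percentile CI
(2000 resamples) for both ratio and difference. This deliberately replaces
mixed-effects modelling of per-cycle data — adequate for cohorts of
independent somitoids, but it ignores within-somitoid correlation structure
that a mixed model would capture.

## Decay kinetics

The model `y(t) = (1 − b)e^(−kt) + b` (k: decay rate /h; b: non-degrading
background fraction) is fitted by least squares to all replicates pooled,
after normalising each replicate to its own t = 0 value. `b` is constrained
to [0, 1): unconstrained fits can wander when the data barely reach the
plateau, producing background errors larger than the estimate. Initial
values: b₀ = mean intensity at the latest timepoint (reset to 0 if not below
the maximum), k₀ from the early-time slope of the linearised model (fallback
0.5/h). Standard errors come from the Jacobian-based covariance
`s²(JᵀJ)⁻¹`. Half-life: `t½ = ln(2)/k`, `se(t½) = ln(2)·se(k)/k²` (delta
method); summaries round to one decimal, full precision is retained in the
outputs. A constant series is flagged `converged = false` (k unidentifiable)
rather than returning an arbitrary rate. Condition comparisons use Welch
t-tests (unequal variances is the safer default for densitometry) on log₂
intensities at each shared timepoint after t = 0, Benjamini–Hochberg-adjusted
across timepoints.

## Nuclear quantification

Mean intensity per labelled ROI; cells with centroids within 10% of any
image border are discarded (partial nuclei and edge shading). Classification
metrics: natural log of (mean × area + 1) for diffuse markers (total signal,
log-compressed; +1 avoids log 0), or the mean absolute deviation of
within-ROI pixels for punctate markers. The negative/positive threshold is
the centre of the deepest local minimum strictly between the two highest
local maxima of the metric histogram (Freedman–Diaconis bin width, 3-bin
moving-average smoothing — raw finite-sample histograms have spurious
minima); a histogram without an interior minimum raises "not bimodal" rather
than guessing. Group differences: `Z = |W − n₁n₂/2| / √(n₁n₂(n₁+n₂+1)/12)`
from the Mann–Whitney W with midranks for ties but no tie correction of the
variance (with the published statistics this convention reproduces the
published effect sizes to within 0.002), `r = Z/√N` with small/moderate/large
bands at 0.3 and 0.5. |Z| is reported, so r is non-negative regardless of
direction.

## Synthetic data: what it emulates, and what it does not

**Movies.** An elongated band (default 180×60 px in a 256×256 frame) bent
along a quadratic curve, tapering 35% toward the anterior — mimicking the
wider posterior of a real somitoid and giving the intensity-based
orientation rule a realistic cue. Inside the band,
`I(s,t) = B + A·D(t)·(1 + cos(2πt/T − φ(s)))/2` with `φ(s) = 2πs/λ`
(posterior origin) or `2π|s − 0.5|/λ` (centre origin), wavelength fraction
λ = 1 (one wave per axis, as seen in kymographs), and optional exponential
damping `D(t) = e^(−t/τ)`. Background is 5% of baseline, so segmentation is
non-trivial but reliable. Noise is additive Gaussian (camera character;
σ = 8 a.u. against baselines of 100–190 — the true imaging noise and
reporter dynamic range are not knowable from published figures, so this is a
design choice, not a measured value). Movies are single-plane; the
z-projection step is exercised by separate multi-plane fixtures. Frames are
10 min apart over 26 h (157 frames) or 18 h for the pre-embedding presets.

Preset ground truth encodes the study conditions: wild-type period 258 min
(4.3 h) with posterior origin; mutant 278 min with centre origin, trough
188 and amplitude 102 against wild-type 100/200 — so the designed
trough ratio is 188% and amplitude ratio 51%, and recovery of those numbers
by the full pipeline is a meaningful end-to-end check. The damped-mutant
preset uses τ = 300 min, chosen from the preset's own geometry so that the
fourth peak's prominence falls below the 10% detection threshold while the
third survives (amplitude ratios at the anterior window's peaks 1–4 are
0.76/0.30/0.12/0.05 of nominal).

Not simulated: photobleaching, focus drift, 3D tissue optics, somite
boundary formation, or the HES7 regulatory network itself. Passing recovery
tests therefore shows the pipeline measures what it claims on data matching
its geometric assumptions — not that segmentation or axis-finding are robust
to arbitrary real-world artefacts.

**Decay series** draw multiplicative lognormal noise (densitometry error
character) around the exact model; **nuclei tables** draw log-intensities
from a two-component Gaussian mixture with uniform centroids and recorded
true labels.

## Numerical choices and degenerate inputs

- Percentile (1st/99th) min-max normalisation, clipped to [0, 1]: hot pixels
  otherwise set the scale. Constant frames normalise to zeros with a warning.
- Near-isotropic masks (principal-moment ratio < 1.05) warn that the major
  axis is ill-defined but still return a deterministic eigenvector.
- K-means uses deterministic seeds (equally spaced along the in-mask chord),
  one initialisation, ≤ 100 iterations.
- TSP ties are broken toward the lexicographically smallest index sequence;
  a path and its reverse are the same open path.
- Duplicate consecutive cluster centres are collapsed with a warning.
- The noiseless movie's in-band extrema equal baseline and baseline+amplitude
  only up to phase discretisation of the frame/pixel grid (≲ 0.05 a.u. at
  amplitude 200).
- Bootstrap, K-means and all generators take explicit seeds; reports embed
  the resolved configuration.

## Problem sizes

Tests and the acceptance script analyse cohorts of six 256×256, 157-frame
movies per genotype and 100–200-replicate simulation batches for the decay
estimators — sizes at which every estimate above is stable (the cohort
features vary by ≪ 1% across seeds) while a full run stays fast on a single
CPU.

## Known limitations

- The elongation threshold (length:width ≥ 1.5) and the anterior offset
  (0.8) are conventions; published figures do not pin them down.
- The directionality score is validated only against synthetic ground truth;
  against human scoring it is an unvalidated surrogate.
- Cohort statistics are mean/bootstrap, not mixed-effects models.
- The built-in segmenter assumes one bright connected tissue per frame;
  touching somitoids or strong debris require external masks.
- Reported intensities are raw filtered trace units; no attempt is made to
  convert to absolute reporter concentrations.
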