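# Methods

`vhmea` reimplements, as a tested pipeline, the analysis used to quantify
spontaneous motor-neuron activity in multi-electrode array (MEA) recordings
from neonatal mouse spinal cord slices — a spinal muscular atrophy (SMA)
model versus littermate controls — together with a synthetic-recording
generator that plants ground-truth activity at the reported condition
levels so every stage can be scored without animal data.

## Recording model

A MED64-style probe is modeled as an 8×8 grid of extracellular electrodes
at 75 µm pitch sampled at 20 kHz, recording in 50-s segments. Slices are
positioned so only the ventral horn covers part of the grid; the default
`ArrayGeometry` marks a 6×6 corner sub-grid (36 electrodes, just over half
the probe) as tissue-covered. Electrodes outside this mask record noise
only.

### Condition presets

Activity is planted per condition (genotype × drug) at the reported group
means: the number of active electrodes per slice, the number of distinct
units on each active electrode, and the aggregate firing rate per active
electrode (all units on an electrode sum to this rate — the per-electrode
"spike frequency" is treated as a pooled, pre-sorting quantity):

| genotype | drug          | active electrodes | units/electrode | rate (Hz) |
|----------|---------------|------------------:|----------------:|----------:|
| control  | basal         | 15 | 5 | 6.08 |
| SMA      | basal         |  6 | 4 | 5.48 |
| control  | serotonin     | 25 | 7 | 10.20 |
| SMA      | serotonin     | 11 | 5 | 6.98 |
| control  | acetylcholine | 14 | 5 | 5.88 |
| SMA      | acetylcholine |  6 | 4 | 5.39 |
| control  | bicuculline   | 16 | 5 | 5.96 |
| SMA      | bicuculline   |  7 | 4 | 6.18 |
| control  | GABA          | 14 | 5 | 5.74 |
| SMA      | GABA          |  6 | 4 | 5.14 |

Units-per-electrode for the three pharmacology rows are not reported and
default to the genotype's basal count. Non-active in-mask electrodes carry
a single sub-criterion background unit at 0.2 Hz, so the ≥ 1 Hz activity
criterion is consequential rather than vacuous. Drug effects are modeled
purely as preset changes in planted activity; no receptor kinetics.

### Spike trains

Each unit fires as a dead-time (refractory) Poisson process: inter-spike
intervals are `refractory + Exponential(1/λ)` with λ inflated so the mean
ISI equals exactly 1/rate — the *realized* rate equals the requested rate,
with a hard 2 ms refractory floor. Trains that would land an electrode on
the wrong side of the activity criterion (a vanishing-probability event at
the planted rates) are redrawn deterministically so planted truth is
always well-posed.

### Waveform templates

Extracellular waveform shapes are unreported, so the generator uses a
deterministic per-electrode catalog of biphasic, negative-going templates
(the dominant polarity of extracellular somatic spikes): a main Gaussian
lobe with an opposing lobe before or after it, tapered to zero at the
64-sample (3.2 ms) window edges. Units on an electrode differ jointly in

- peak amplitude: tiers spanning 8–15× the noise SD (40–75 µV at the
  default 5 µV noise), guaranteeing detectability above the ±4.5δ
  threshold;
- main-lobe width: 0.4 or 1.0 ms;
- second-lobe depth: 0.30 or 0.55 of the peak;
- second-lobe side: before or after the peak.

The three binary shape attributes are assigned as near-balanced codes
across a unit set, and amplitude tiers are permuted so any two units whose
codes differ in a single attribute sit on distant tiers. Two deliberate
constraints matter here: balanced attribute splits make the corresponding
wavelet coefficients strongly bimodal — which is what the sorter's
deviation-from-normality feature selection responds to — and the
second-lobe depth is capped at 0.55 because a deeper lobe rivals the
band-passed main lobe and makes the detector's extremum alignment flip
between lobes. Spike-to-spike variability is a multiplicative amplitude
jitter (SD 3 %).

### Noise and drift

Per-electrode noise is stationary Gaussian (default SD 5 µV) plus slow
drift: a 0.5 Hz sinusoid with random phase and a linear ramp, both of
amplitude 20 µV. The drift sits entirely below the 85 Hz high-pass cutoff;
it exists to make the filtering and least-squares detrending stages
consequential, not decorative.

What the generator does **not** emulate: electrode-distance-dependent
amplitude decay or cross-electrode correlation (each electrode is
independent), bursting or rate non-stationarity, electrode artifacts, and
biophysical waveform diversity beyond the parametric catalog. Passing
recovery tests therefore demonstrate the pipeline's correctness under
these idealized conditions, not its performance on every pathology of real
tissue recordings.

## Preprocessing

Traces are band-passed 85 Hz – 2.5 kHz with a 4th-order Butterworth filter
applied forward–backward (zero phase, odd-reflection padding), then
linearly detrended per electrode — filter order, cutoffs, and the
filter-then-detrend order are configurable. Detrending uses the
closed-form simple-regression fit on a centered time axis (identical to
generic least squares, O(n)). Filtering runs in the trace's own floating
dtype; float32 segments stay float32, which is ample precision for
microvolt data.

## Spike detection

δ is the plain sample standard deviation of the full preprocessed 50-s
trace (a robust median-based estimate is deliberately not the default);
the detection threshold is ±4.5δ, pooling both polarities into one event
stream. Each excursion beyond threshold yields one event, timestamped at
its extremum sample (0-based, seconds from segment start); events closer
than 1 ms are merged keeping the larger extremum; a 64-sample snippet
centered on the extremum is cut for sorting. Events whose window would run
off the segment are dropped to keep the waveform matrix aligned with the
event table.

Active electrodes are those with ≥ 50 detected spikes per 50-s segment
(equivalently ≥ 1 Hz); classification is per segment. Firing frequency is
reported per 25-s window (two observations per segment) on active
electrodes; scaled-down segments in tests fall back to two windows of half
the segment length.

## Spike sorting

Sorting is per electrode: a 4-level Haar discrete wavelet transform of
each snippet, selection of the 10 coefficients whose distributions deviate
most from normality (Lilliefors statistic: max |ECDF − fitted normal
CDF|), then superparamagnetic clustering (SPC) of the 10-D feature
vectors. Before the transform, snippets are realigned to sub-sample
precision (parabolic fit through the three samples around the peak, cubic
interpolating shift); without this, ±1-sample alignment jitter dominates
the within-unit feature variance.

SPC maps spikes to q = 20-state Potts spins coupled to their k = 11
nearest neighbours with strength `exp(−d²/2a²)/K̂` (a = mean
neighbour distance, K̂ = mean degree), runs Swendsen–Wang dynamics (100
sweeps, 25 discarded as burn-in) at each temperature of a 0–0.20 grid
(step 0.01), and links points whose spin–spin correlation exceeds 0.5.
Clusters with ≥ 15 members count as units; smaller groups are unassigned
(label 0) and excluded from unit counts but retained in electrode-level
frequencies.

**Working-temperature rule.** The number of valid clusters is tracked
along the temperature scan; the multi-cluster count that persists over the
most temperatures is taken as the superparamagnetic-phase structure
(persistence ties resolve toward the count appearing at lower, more
ordered temperatures), and the working temperature is the one showing that
count with the most spikes inside valid clusters. The obvious alternative
— the highest temperature at which large clusters survive — systematically
lands in the fragmentation regime and undercounts; the stability rule is
pinned by tests.

Determinism and equivariance: clustering is seeded, and points are
processed in a canonical (lexicographic) feature order internally, so
permuting the spike order permutes the labels identically.

Known limitation: with 7 planted units per electrode (the control +
serotonin preset) the 10-coefficient feature space under-resolves the
catalog and the sorter recovers ≈ 4–5 units per electrode; 3–5-unit
configurations are recovered reliably. Amplitude-only contrasts at 4× the
within-class jitter SD (≈ 2 % class overlap) are below SPC's resolution at
these published defaults and merge.

## Statistics

Per slice: active-electrode count; mean of the active electrodes' 25-s
frequency observations; total spikes/minute summed over active electrodes.
Condition tables report mean ± SEM (the "±" convention chosen here and
labeled in output).

Frequency histograms use 0.5 Hz bins, left-closed, starting at 0; each
slice's observations are weighted by 1/(its observation count) so every
slice contributes unit mass and pooled mass equals the slice count.

Gaussian-mixture fits use a hand-rolled univariate EM (K = 3 by default,
matching the three-peak description of the frequency distributions):
k-means++-style seeded starts (10 restarts), log-space E-step,
convergence when the log-likelihood gain drops below 1e−8 per observation
(500-iteration cap), variances floored at 1e−6× the data variance, best
start by final log-likelihood. The per-iteration log-likelihood trace is
retained and is non-decreasing by construction; a BIC-based model-selection
mode is available but off by default. EM is implemented in-package because
the contract exposes the trace and the stated convergence rule;
scikit-learn's mixture model serves as an independent cross-check in the
test suite only.

Group comparisons: Kruskal–Wallis (tie-corrected, χ² p-value, α = 0.01) on
the pooled raw 25-s frequency observations of each condition — per-slice
normalization is a histogram display choice and is not applied to test
samples — and one-way ANOVA (α = 0.05) on slice-level summaries across
drug states within a genotype. Degenerate inputs are defined rather than
fatal: all-identical observations give H = 0 (p = 1); zero within-group
variance gives F = ∞ (p = 0) when means differ and F = 0 (p = 1) when they
do not.

## Numerical and design notes

- All randomness flows through `numpy` SeedSequences; identical inputs and
  seeds give bit-identical recordings, reports, and cluster labels.
- Voltages are stored as float32 µV in a versioned HDF5 container
  (`/voltages`, geometry group, optional `/truth` answer key); tables are
  CSV with headers; configuration round-trips through YAML.
- Problem sizes in the shipped acceptance script: 12 slices for the
  control-basal and control-serotonin recoveries, 11 for SMA-basal
  (matching the reported group sizes), and 4 sorted slices (≈ 60 active
  electrodes) for the units-per-electrode recovery — the sorting stage
  dominates runtime and 60 electrodes give a stable mean.
- The detector's dead time (1 ms) and snippet window (64 samples) follow
  common practice for the sorting method and are exposed in configuration;
  whether δ is computed per 50-s segment (implemented) or per 25-s half is
  not specified by the source procedure, and the ≥ 50-spike criterion is
  applied per segment with slice-level reporting by mean.
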