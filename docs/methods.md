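# Methods

This note documents the models, the parameters that matter, the
numerical choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish.

## Session model and preprocessing

A session is a set of plain-text tables: spike times per unit, unit
metadata (region, spike width, mean rate, optional quality metrics),
head positions at 39.0625 Hz (25.6-ms frames), trial records for the
T-maze, and optionally a float32 LFP trace with a sampling-rate sidecar.

Putative principal neurons are selected by spike width > 0.4 ms; CA1
units must additionally fire below 10 Hz on average, while no rate
ceiling is applied in SUB, where principal cells sustain high rates.
When quality metrics are present, units must pass isolation distance
> 20, ISI index < 0.2, amplitude > 50 µV and mean rate > 0.1 Hz.  A
session qualifies for a region when at least 10 principal units above
0.1 Hz were recorded simultaneously.

Instantaneous firing rates use 512-ms bins, half-open `[t, t + Δ)` and
anchored at the interval start (spikes exactly on the right edge fall
into the next bin; the convention is arbitrary but fixed for
reproducibility).  Manifold construction uses the square root of the
rate to stabilize Poisson-like variance.  The transform ledger — rate →
sqrt → Gaussian smoothing → per-unit z-score — is recorded on every
binned matrix so that downstream stages can assert what they receive:
geometry analyses (visualization, topology, shape) use σ = 2-bin
smoothing, decoding uses unsmoothed rates, and z-scoring is optional
everywhere.  Gaussian smoothing uses reflective boundaries to avoid edge
droop.  Per-unit z-scores are computed over the analysis interval; a
zero-variance unit's row is set to 0 with a warning.

Per-bin behavior takes every 20th tracking sample, smooths X and Y
separately (σ = 1 bin), computes speed from adjacent smoothed positions
divided by the bin width (then smoothed again), and linearizes T-maze
positions by arc-length projection onto the turn-specific loop.  The
arc-length → u mapping is piecewise linear and anchored at behavioral
landmarks so that the start box occupies u ∈ [0.02, 0.08], the junction
[0.55, 0.62], the arm [0.62, 0.86] and the reward zone [0.86, 0.90];
the return leg fills the remainder.  These anchors also define the
landmark labels used in the ripple segment analysis; the junction and
arm windows are configurable because no exact mapping of path segments
to salient areas is canonical.

## Synthetic generator

The generator is the benchmark's ground truth, so its defaults encode
the study conditions rather than convenient test cases.

**Behavior.**  T-maze trials consist of a start-box hold (8 ± 2 s,
experimenter-controlled enclosure), a run through stem → junction → arm
→ reward → outer-wall return (mean running speed 22 cm/s with
Ornstein–Uhlenbeck fluctuations), a drinking pause at the water port
(1.8 ± 0.8 s), occasional mid-run hesitations (~0.25 s⁻¹, ~1 s each)
and a linger near the box entrance before re-entry.  The resulting box
occupancy is ~30 % and trial durations are 25 ± 3–4 s.  The variability
matters: near-constant trial durations would leave every unit's shifted
spike train periodic on a common period, and the circular-shift null
for topology would itself contain large rings.  Turns alternate except
for injected error trials (probability 0.05); only correct trials feed
path decoding.  Open-field foraging is an OU velocity process with
reflective walls that covers ≥ 95 % of 10-cm cells in 20 minutes.

**Tuning.**  CA1-like units carry 1–3 narrow place fields (σ_u
0.025–0.06, high peak gain) with negligible conjunctive modulation;
SUB-like units carry 3–6 broad fields (σ_u 0.08–0.2) plus axis, reward,
choice and speed gains.  Two structural choices drive the manifold
geometry and reflect the physical task: fields centered on the shared
box/stem ground fire on both loops (the stem is literally the same
place on either trial type), and SUB congruence is conjunctive — each
unit has a per-unit propensity (uniform on 0.15–0.85) for its arm and
reward fields to be congruent across loops, while return-leg fields are
always turn-specific because the two return corridors are different
places traversed with mirrored headings.  Field centers are drawn
uniformly per unit of arc length (physical ground), not per unit of u.
Reward gains (6–14 Hz on ~45 % of SUB units) peak at consumption, which
is what defines reward cells.  Choice gains (±0.15–0.4, multiplicative
during the hold) are anchored so that path decoding with ~30 units
lands in the 0.9–1.0 range.  During the hold, a shared slow gain
fluctuation (OU, τ = 1 s) loads onto units with choice-dependent
weights so that pairwise coactivity — not just mean rates — carries the
upcoming turn.  Per-unit mean rates are log-normally dispersed around
the regional targets (1.43 Hz CA1-like, 5.80 Hz SUB-like) and
calibrated against an internally simulated reference behavior, so the
population mean lands within a few percent of target.

**Spiking** is inhomogeneous Poisson per 25.6-ms frame with uniform
jitter inside the frame — adequate for 512-ms analysis bins, no
refractoriness or burstiness is modeled.

**Sleep.**  The LFP is 1/f background noise plus Gaussian-enveloped
(σ = 25 ms) 170-Hz bursts at Poisson times (0.3 Hz, 350-ms refractory
gap), with burst amplitude set to 8× the background ripple-band SD.
Spiking is background Poisson at 20 % of each unit's awake mean plus
event spiking inside the 76.8-ms window around each burst.  CA1-like
events reactivate the awake pattern at a random track location with a
6× gain (ripple bursting is strong in CA1 pyramidal cells).  SUB-like
events re-express the consumption-state reward-port pattern through a
fixed multiplicative distortion (log-normal σ = 0.35, reward units
up-weighted ×1.4) at a more modest 2.5× gain, with small per-event
jitter: the fixed distortion pushes the events off the awake manifold
as one tight cluster while the reward pattern keeps their nearest awake
segment at the reward area.

## Dimensionality

Radii are 50 log-spaced values between the smallest nonzero and largest
pairwise distance (the count and spacing of evaluation radii are free
choices; both are configurable).  The Heaviside convention is H(0) = 1 (boundary pairs
count).  The percentile band is taken on the C values, not the radii.
Estimation uses sqrt rates without smoothing; z-scored rates are an
option and preserve the CA1-vs-SUB ordering.

## Embedding

Isomap uses a symmetrized k-NN graph (k = 20), Dijkstra geodesics and
classical scaling; if the graph is disconnected, k doubles (with a
warning) until it connects.  Zero-length edges from duplicate rows are
kept explicit at 1e-12.  The eigen-sign ambiguity is fixed by orienting
each axis so its largest-magnitude coordinate is positive, and the
eigensolver is given a fixed start vector, so embeddings are
bit-reproducible; all downstream geometry metrics are additionally
rotation-invariant.  Joint awake+ripple embeddings concatenate rows
(unweighted) and z-score the coordinates per axis.

## Topology

Vietoris–Rips persistence is computed in-package: Z/2 boundary-matrix
reduction with columns as integer bitsets, the twist (clearing)
optimization, H0 via union-find, and the enclosing radius
`min_i max_j d(i, j)` as the default filtration threshold — beyond it
the complex is a cone, so truncating there loses no finite bar;
essential bars are capped at the threshold, and the single essential
component always counts as robust.  Clouds are reduced to maxmin
landmarks first (96 for session pipelines, fewer for maxdim-2 model
clouds); this keeps the simplex enumeration tractable and, on
trajectory data, also stabilizes the filtration.  An independent naive
full-reduction oracle in the test suite verifies the barcodes on small
clouds.

The robustness null circularly shifts each unit's spike train by an
independent uniform offset and re-runs the entire bin → sqrt → smooth →
embed → filter → persistence pipeline; null lifetimes are pooled per
dimension across 50 shuffles (a warning fires if fewer than 100 holes
per dimension were pooled) and the robustness threshold is the pooled
lifetimes' 99.9th percentile, taken separately for each dimension.

## Shape

The D2 signature density-filters the cloud, min-max normalizes all
pairwise distances, histograms them into 1200 bins, smooths with
σ = 10 bins and renormalizes; it is invariant to rigid motions and
global scaling by construction.  The bimodality coefficient is computed
on the raw normalized-distance sample with bias-corrected skewness and
excess kurtosis; it tends to 5/9 for uniform and 1/3 for normal
samples.  Dissimilarity is the L1 distance between signatures (a
pseudometric, range [0, 2]).  The figure-8 models use tori with a
tube-to-ring radius ratio of 0.3 (configurable; the qualitative
orderings hold over 0.2–0.4), tangent at one point, with the second
ring plane rotated 90° for the bent variant.  Per-neuron arm-tuning
correlations are restricted to u ∈ [0.60, 0.90] (arm + reward), a
choice derived from the maze geometry.

## Decoding

The GP kernel is ConstantKernel × RBF + WhiteKernel with
marginal-likelihood optimization from a single start (seed-pinned);
targets are standardized internally.  Folds are refit independently.
Twofold cross-validation either permutes bins randomly (seeded) or
splits the session into halves.  Note that random-split CV on
autocorrelated data leaks temporally adjacent bins across folds, which
inflates the circular-shift chance level (shuffle R² well above zero);
the observed accuracies clear it regardless, and the same scheme is
applied to observed and shuffled data.  Path decoding averages per-bin
P(left) within each held-out trial; a tie at exactly 0.5 is broken by a
seeded coin flip.  Coactivity decoding uses per-trial covariance of
sqrt rates over box bins (N(N−1)/2 features; zero-variance columns
dropped; trials with ≤ 1 box bin dropped).  Head-direction equalization
removes bins from the better-sampled choice per 20° HD bin (width
configurable) until counts match.

## Transfer and peer-neuron decoding

The SO(3) search evaluates a zyz Euler grid at 15° steps followed by a
local 3° refinement around the best cell, maximizing decoding accuracy
on a random half of the target bins; accuracy is reported on the other
half, and the result records a coarse objective trace for audit.
Rotations are verified proper (det +1) to 1e-6.  Sessions must
self-decode position at R² ≥ 0.2 to be eligible.  Peer-neuron decoding
excludes silent targets (< 0.001 Hz), embeds the remaining N−1 units in
3-D and GPR-decodes the held-out unit's σ = 1-bin-smoothed rate.

## Ripples

The band-pass is a 3rd-order Butterworth applied forward-backward; the 11-sample moving
average is interpreted at the native LFP rate.  Candidate boundaries
are the z > 3 crossings; merging (< 30 ms gaps), the peak-power floor
(z ≥ 7) and duration bounds (15–300 ms, applied after merging) then
define events, whose peak time is the negative peak of the filtered
trace.  Detection is amplitude-scale invariant because of the
z-scoring.  Because the moving average and filter ringing widen any
supra-threshold excursion past 15 ms at 1250 Hz, the merge/duration
rules are exercised exactly on constructed power series
(`events_from_normalized_power`), while end-to-end fidelity is measured
as recall/precision against injected ground truth.  The scatter null
for segment association draws uniform points in the awake cloud's
axis-aligned bounding box.  Peri-ripple analysis samples 30 events per
repetition (selections returned to the pool between the 10
repetitions), bins at peak − 200 ms / peak / peak + 200 ms, joint-embeds
with the awake bins and reports Euclidean step sizes and
nearest-segment changes (expressed in segment-index units along the
linearized path).

## Problem sizes

The test suite and the acceptance script run on scaled-down study
conditions chosen to exercise every stage end-to-end: 30-unit
populations, 8-minute task sessions (≈ 940 bins, 19–24 trials),
10-minute sleep (≈ 160–180 ripples), 10-seed sweeps for
direction-of-effect checks, 20 shuffles for nulls and 96 landmarks for
session persistence.  Under these conditions the recovered
dimensionalities (CA1-like ≈ 3–5, SUB-like ≈ 5–7), ring counts (2),
shape-model orderings and ripple-geometry orderings reproduce the
regional contrasts the pipeline is designed to measure.

## Limitations

The generator is a rate-model benchmark, not a biophysical simulation:
no theta rhythm or phase coding, no bursting or refractoriness, no
spike-sorting noise, and the LFP carries nothing but ripple-band
content over 1/f noise.  Sleep reactivation compresses to a single
pattern per event rather than a replayed sequence, so replay-order
analyses are out of scope.  Passing the synthetic benchmark shows the
pipeline recovers known structure under realistic rates, trial
statistics and noise; it cannot certify behavior on pathologies the
generator does not model (electrode drift, cell-type misclassification,
non-stationary tuning).  The bent-vs-planar figure-8 dissimilarity
difference is small (≈ 0.01–0.02) though consistently signed — on real
data that comparison should be read across many sessions, as a
population-level statement.
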