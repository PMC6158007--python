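# Methods

This note documents the models, numerical choices, and open design
decisions behind `synphys`, and what its synthetic benchmarks do and do not
demonstrate about real recordings.

## Scope and data model

The package analyses paired-recording experiments: a presynaptic neuron is
driven to fire a train of action potentials while the membrane potential of
a putative postsynaptic partner is recorded. The canonical stimulus is 12
pulses — 8 induction pulses at 10/20/50/100 Hz that drive short-term
plasticity toward steady state, then a recovery delay (250–4000 ms), then 4
more pulses at the same rate — repeated over trials at a 15 s inter-trial
interval. The interval between the 8th and 9th pulses *is* the recovery
delay. Units are mV, ms, and pA throughout; traces carry an explicit start
time so spike-aligned windows are exact.

No public dataset accompanies the experimental design this package targets,
so the synthetic generator (`synthgen`) is first-class: every downstream
stage is validated against known ground truth.

## Synthetic experiments

**EPSP kernel.** Events use the double-exponential shape
`(1 − e^{−u/τ_r})² e^{−u/τ_d}`. Experimenters specify kinetics as
foot-to-peak rise time rather than τ_r, so τ_r is calibrated by root
finding on the closed-form peak location `u* = τ_r ln(1 + 2τ_d/τ_r)`
(monotone in τ_r; Brent's method, tolerance 1e-12). The kernel is
peak-normalized so its maximum equals the drawn amplitude exactly.
Defaults: 2 ms rise, 15 ms decay, onset latency Normal(2 ms, 0.2 ms).

**Stochastic amplitudes.** Per-event amplitude is the product of a
Binomial(n = 24, p = 0.2) vesicle-release count and a Normal(1, 0.3) gain,
scaled by `target_mean / (n·p·gain_mean)` so the distribution mean hits the
target. The analytic coefficient of variation from product moments is
0.521; negative products (gain < 0) occur in ~0.04% of draws and are kept —
truncation would bias the mean and is not part of the product model.

**Short-term plasticity coupling.** When STP parameters are supplied, the
*mean* of the amplitude draw for pulse k is multiplied by the simulated
normalized response w_k/w_1, preserving the binomial × normal shape. Each
trial starts from rest: the 15 s inter-trial interval exceeds all plausible
recovery constants by an order of magnitude.

**Noise.** Recordings are characterized here by background RMS *after*
exponential deconvolution (τ = 15 ms) and 1 kHz low-pass — the units in
which noise competes with signal during detection — with ~0.6 mV as the
typical scale. The raw spectrum of recording noise is not otherwise
constrained, so two seeded Gaussian models are provided. `white`
(low-passed at 2 kHz) is amplified ~37× by deconvolution at these sampling
rates. The default `pink-mixed` is more faithful to recordings: a dominant
low-frequency (1/f, <100 Hz) component that sets the raw RMS (default
0.15 mV) plus a small wide-band component (1% of variance) that dominates
after deconvolution, yielding ~0.6 mV deconvolved. Both the mixture
fraction and the RMS are configuration knobs;
`raw_rms_for_deconvolved` calibrates raw RMS for any deconvolved target
empirically on a long reference realization. Heterogeneity across pairs in
the background pool is log-normal (0.15 ± 0.10 mV raw, i.e. roughly
0.6 ± 0.4 mV deconvolved).

**Reproducibility.** All randomness flows from one integer seed through
counter-based substreams (`SeedSequence(entropy=seed, spawn_key=...)`),
keyed by pair and trial, so enlarging a cohort never perturbs
previously generated sweeps.

What the generator does *not* emulate: active membrane dynamics and
postsynaptic spiking, spontaneous synaptic events, electrode drift,
crosstalk beyond an optional rectangular artifact, polysynaptic responses,
and synapse-to-synapse variability in release statistics (the binomial
parameters are fixed). Detection-limit results on synthetic cohorts
therefore show that the machinery is correct and calibrated, not that real
recordings reach any particular microvolt threshold — real noise is less
stationary and less Gaussian than this model.

## Quality control

Sweep-level checks (all failures reported, not just the first): |auto-bias
current| < 800 pA; 10 ms pre-stimulus baseline within ±5 mV of the target
holding potential (−70 mV); baseline mean within 3 SD of the across-sweep
baseline mean; no postsynaptic threshold crossing of −20 mV. Connections
require ≥5 surviving sweeps. Sweeps held at −55 ± 5 mV can be re-admitted
for STP analysis via a flag. The stimulus-artifact check (<30 µV) and
positive-polarity check run at connection level on the spike-aligned
average — a 30 µV criterion is meaningless against single-sweep noise of
hundreds of µV; the averaged artifact estimate compares the stimulus window
against the adjacent 1 ms, which also cancels low-frequency noise.

## PSP fitting

Weighted multi-start least squares (scipy `least_squares`, trust-region
reflective). Starts: onset 1–4 ms post-spike × decay 5/15/50 ms; bounds
t0 ∈ [spike, spike + 10] ms, τ_r ∈ [0.05, 20] ms, τ_d ∈ [1, 300] ms,
A ≥ 0. Region weights (the weighting scheme itself is a free choice —
only the ordering rise > baseline/decay > masked is principled): 30 on
[t0 − 0.5, t0 + 4] ms, 3 elsewhere, 0 on the ±0.5 ms stimulus/crosstalk
mask. The reported WRMSE is the weighted RMS residual divided by the
pre-stimulus baseline RMS, making the conventional "< 8" kinetics gate
scale-free; an absolute 8 mV error bound would be vacuous for sub-mV
events. The normalization convention and the weight constants are the two
deliberately open choices in this module; both are exposed as arguments.
Degenerate inputs: an all-zero trace yields amplitude ≈ 0 flagged
`degenerate` (or a `FitError` carrying per-start diagnostics if no start
converges).

## Deconvolution and train amplitudes

`D = V + τ dV/dt` with centered differences (one-sided at edges);
`reconvolve` inverts it either exactly (banded linear solve of the discrete
operator, machine precision) or as a plain first-order low-pass
(exponential integrator, exact up to discretization and an initial
transient). Train amplitudes: sweeps averaged, deconvolved at τ = 15 ms,
4th-order zero-phase Butterworth low-pass at 1 kHz (the filter family and
cutoff are package choices), then per-pulse peaks in windows from 1 ms
post-spike to min(15 ms, IPI/2). The mean of the deconvolved trace over the
1 ms between spike and window start is subtracted as a local baseline:
without it, residual tails under τ mismatch accumulate across 100 Hz trains
(~7% normalized error); with it the error drops below 0.5%, consistent with
the few-percent insensitivity that justifies a fixed τ.

## STP model

Event-driven and exact between spikes: τ_r relaxes exponentially toward
τ_r0 with time constant τ_FDR, and the depleted fraction decays by
`exp(−I(T))` with the integral of dt/τ_r(t) in closed form (written
overflow-safe for long delays). At each spike the response w = A·n·P0 is
read out *before* the update n ← n(1 − P0), τ_r ← τ_r(1 − a_FDR) — the PSP
is proportional to the vesicles available to that spike. A forward-Euler
integrator at 1 µs steps is kept in the test suite as an independent
oracle; the a_FDR → 0 limit reproduces the classical fixed-τ depletion
model and its periodic-train fixed point
`n_ss = (1 − e^{−Δ/τ})/(1 − (1 − P0)e^{−Δ/τ})`.

Fitting (lmfit least-squares) minimizes unweighted squared residuals of
normalized amplitudes jointly across all supplied (frequency, delay)
curves; normalization removes the scale A. Identifiability requires ≥2
frequencies or ≥2 delays. Bounds: P0, a_FDR ∈ [0.01, 0.99], τ_r0 ∈
[0.05, 20] s, τ_FDR ∈ [10, 5000] ms; multi-start over a 3×3 (P0, τ_r0)
grid. Standard errors come from the covariance matrix; a missing/singular
covariance raises a warning and is flagged, and parameters within 2% of a
bound are reported in `at_bounds` (a flat all-ones curve lands there rather
than returning silently). Replicate simulation studies in the tests use a
single default start per replicate — with 104 data points per battery the
loss surface is benign and this keeps 100-replicate studies fast; the
noiseless recovery checks use the full multi-start.

## Detection

Features per probed pair: fitted amplitude/latency/rise/τ_d and normalized
fit error of the averaged response (single-start fit — features need
determinism and speed, not the last percent of fit quality), plus KS
p-values comparing per-trial deconvolved peak amplitudes and peak times in
a 3 ms window starting 1 ms post-spike against peaks measured in matched
3 ms chunks of the 10 ms pre-stimulus window, plus deconvolved background
RMS. p-values enter the classifier as log10, clipped at 1e-300; non-finite
components from failed fits are mapped to large finite sentinels.

The default classifier is a standardized logistic regression: margin-based,
probabilistically calibrated by construction, deterministic, and monotone
along each evidence direction — properties the detection-limit machinery
relies on. The backend is pluggable (any `fit`/`predict_proba` estimator,
e.g. a calibrated SVM). Training data is synthetic by construction here;
on real data the same contract holds with annotated pairs.

Detection limits: simulated EPSPs (one per presynaptic spike, stochastic
amplitudes scaled to a grid mean, Normal(2 ms, 0.2 ms) latencies) are
injected into the pair's own background sweeps; classification probability
is averaged over 8 independent injection repeats, with common random
numbers across the amplitude grid so profiles are monotone under paired
comparison. The default grid is 14 log-spaced points over 10 µV–2 mV; the
50% crossing is interpolated linearly in log amplitude; profiles that never
reach 0.5 are censored at the grid maximum and flagged. The corrected
amplitude distribution divides the Gaussian-smoothed (σ = 1 bin) measured
histogram by the cohort-mean detection probability per bin, masking bins
below a detection floor of 0.1 where the correction diverges; the reported
inflation is corrected/measured − 1 over unmasked bins.

The optogenetic SNR scorer implements the photostimulation pipeline:
1 kHz low-pass, baseline subtraction, deconvolution (τ ∈ [10, 40] ms),
30 Hz high-pass; events are peaks >3 SD above the pre-stimulus baseline;
signal region 5–105 ms post-onset, noise region 145–45 ms pre-onset; within
each region the 10 ms sub-window (scanned at 0.5 ms resolution) containing
events in the most unique trials is selected, per-trial peak medians taken,
and the mean of the 25 ms window preceding each region subtracted. Calls
use ratio > 1.5. Traces must span [onset − 170, onset + 105] ms so the
noise region has its own preceding baseline.

## Connectivity statistics

Jeffreys 95% intervals are Beta(k + ½, n − k + ½) quantiles with lo = 0 at
k = 0 and hi = 1 at k = n. Distance profiles use half-open 40 µm bins from
zero on 3D intersomatic distance; "within 100 µm" summaries are inclusive.
Fisher tests use the probability-mass two-sided definition on
(connected, unconnected) tables; pairwise comparisons offer Bonferroni
adjustment. The optogenetic false-negative rate is
(1 − photosensitivity) × prior connection probability, valid under
independence of connectivity and photosensitivity.

## Pipeline and problem sizes

`pipeline.run_end_to_end` drives simulate → QC → detect → fit → deconvolve
→ STP-fit → connectivity from one YAML-serializable config and one seed;
reruns are bit-identical. Stage outputs go to per-class JSON pair tables, a
pickled classifier, and a summary with the QC funnel (probed ≥ detected ≥
strength ≥ kinetics). Default demo sizes — 20 pairs/class at 20 kHz, 30
training positives + 60 backgrounds, 6-point detection grids with 4
repeats — are chosen so a full run completes in well under a minute on one
core while still exercising every stage; all sizes scale up from the
config. Persistence is HDF5 (one group per pair, traces plus acquisition
attributes) with ground truth in a JSON sidecar.

## Known limitations

- The WRMSE normalization and region weights are conventions, not
  measurements; comparisons of the "< 8" gate across datasets require the
  same convention.
- The noise model is stationary and Gaussian; detection thresholds on real
  recordings with spontaneous events will be worse than synthetic ones.
- The STP model covers depression with use-dependent replenishment only;
  strongly facilitating synapses fit poorly by design (flagged through
  `at_bounds`/r², not modelled).
- Classifier accuracy figures quoted by the tests are synthetic-benchmark
  numbers; they transfer to real data only to the extent the generator's
  assumptions hold.
- The exact-inverse `reconvolve` assumes the trace was deconvolved with the
  same centered-difference operator; traces deconvolved elsewhere should
  use the filter method.
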