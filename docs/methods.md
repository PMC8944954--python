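# Methods

## The model

Fast interictal events are modelled as a renewal point process whose
inter-event intervals (IEI) are lognormal: `ln IEI ~ N(m, s)`. The process
is summarized by the geometric mean `μ = exp(m)` (seconds) and the
geometric SD `σ = exp(s)`. A geometric SD is a dimensionless multiplicative
factor; slice-electrophysiology reports conventionally print it with second
units next to μ, and the package does the same in its reports while
storing it dimensionless.

Key identities used throughout:

* arithmetic mean interval `E[IEI] = μ·e^{s²/2}` (Jensen: > μ for s > 0);
* expected event count over time `t` (renewal theorem): `t / E[IEI]`;
* expected excess of matched periodic (period μ) over lognormal pacing:
  `t·(1/μ − 1/(μ·e^{s²/2}))`.

All timestamps are seconds, zero-based from trace start; ictal windows are
half-open `[onset, offset)`. Pulse/event trains place their first element
at the first drawn interval (not at t = 0) and keep an element landing
exactly on the duration boundary, so a 20-min 1 Hz train has exactly 1200
pulses and a 60-s period-2 train has 30 — the counting convention every
pulse-budget comparison relies on.

## Synthetic recordings

`lognstim.synth` renders ground-truthed two-channel (CA3, CTX) traces at
2 kHz emulating the 4AP hippocampus–cortex slice preparation:

* **fast interictal events** — lognormal renewal times (defaults μ = 2 s,
  σ = 1.3, the regime observed in slice recordings), rendered as smooth
  biphasic transients (raised-cosine positive lobe, 0.6× negative
  after-lobe; 500 μV peak, 50 ms span). The waveform shape is a modelling
  choice — field-potential spikes are sharp and asymmetric — and the
  asymmetry keeps the rectified peak unambiguous for timing;
* **slow interictal discharges** — Poisson (2/min), wider (0.4 s) and
  smaller (250 μV) bumps on the CTX channel;
* **ictal bursts** — windows from a shifted-exponential renewal model
  (durations and gaps: shift = half the mean plus an exponential tail with
  the other half; defaults 180 s mean interval, 40 s mean duration).
  Rendered as 10–40 Hz oscillations, frequency gliding from the top to the
  bottom of the band (tonic→clonic), trapezoidal envelope with a fast
  (≤ 0.5 s) rise/fall, 400 μV amplitude — an order of magnitude above the
  in-band noise floor;
* **propagation** — the CTX copy of each fast event lags CA3 by 10 ms;
  a `fast_to_ctx=False` switch emulates Schaffer-collateral disruption
  (fast events confined to CA3, as in the disconnected slices that
  generate ictal activity);
* **noise** — additive white Gaussian (20 μV SD).

One master seed governs a synthesis; each component draws a named
sub-stream (SeedSequence-derived), so regenerating one component never
perturbs another. What the generator does *not* emulate: 1/f background,
electrode drift and stimulation artifacts, state-dependent coupling
between interictal and ictal dynamics, biophysical waveform diversity.
Passing tests therefore demonstrate correctness of the pipeline's
statistics and detectors under the assumed signal model, not robustness to
every pathology of real MEA data.

## Event detection and IEI statistics

Traces are low-pass filtered at 200 Hz (3rd-order Butterworth) to exclude
multi-unit components. The filter is applied forward–backward
(`sosfiltfilt`), i.e. zero-phase, because the timestamps feed distribution
fits and a causal filter would shift them by a frequency-dependent lag.
Events are peaks of the rectified trace above `threshold_fraction` (0.5)
of a reference amplitude; "half the amplitude of the signal" is
operationalized as the 99th percentile of the rectified filtered trace —
robust to isolated artifacts, unlike the maximum — computed per channel
and per analyzed segment, with `max` and an explicit user value as
alternatives. Peaks closer than the 0.1 s refractory period merge to the
larger; 0.1 s sits well below the smallest IEI observed in slice data
(~0.26 s) while spanning the biphasic waveform. IEIs are first differences
within an analysis segment, never across segment boundaries, and segments
should total ≥ 10 min (warned, not enforced).

Histograms use Freedman–Diaconis binning, `h = 2·IQR·n^{-1/3}`, which is
robust for heavy tails. The lognormal fit is the closed-form MLE on the
log scale with divisor-n SD (the true MLE; the divisor is a documented
convention, not configurable silently). Goodness of fit compares observed
bin counts with counts *integrated* from the fitted pdf over each bin —
point evaluation at bin centres biases heavy tails — via adjusted R²
(p = 2 parameters) and SSE.

Lognormality validation follows the surrogate scheme: draw a normal sample
of the same size with the fitted (m, s) and run a two-sided Welch t-test
on the log values; pass = p > 0.05. Because the surrogate mean is anchored
to the sample mean, the variance of the mean difference is half what the
Welch test assumes, making the screen conservative: its null pass rate is
≈ 99%, not the nominal 95%. The test suite therefore calibrates the Welch
test itself with surrogates drawn from the *population* parameters (pass
rate ≈ 95%) and separately asserts the fitted-surrogate screen is
conservative. The cumulative comparison reports the two-sample KS distance
between data and surrogate on the decimal scale.

The CV/μ power law is fitted by least squares on log–log pairs. The CV
convention is configurable (`geometric`: σ_geom/μ_geom as printed in
slice reports; `arithmetic`: `sqrt(e^{s²}−1)`) because per-slice CV
averaging is not uniquely recoverable from pooled population moments; no
convention is asserted as canonical.

## Wavelet ictal detection

Analysis runs at 512 Hz (rational-ratio polyphase resampling with built-in
anti-aliasing). At 512 Hz the dyadic detail bands line up usably with the
target ranges: level ℓ nominally spans `(fs/2^{ℓ+1}, fs/2^ℓ)`, so levels
7–8 cover 1–4 Hz (baseline) and levels 4–5 cover 10–40 Hz (ictal; level 5's
8–16 Hz band overlaps the target by 75%). A band maps to every level with
≥ 50% of its span inside the range, with a maximum-overlap fallback so the
mapping is never empty. At the recording rate of 2 kHz no single level
covers 1–4 Hz, which is why the fixed analysis rate exists.

The multiresolution analysis uses the **stationary (undecimated)** db4
transform: components are reconstructed per level, time-aligned
sample-for-sample with the input, and sum to it exactly (asserted to
≤ 10⁻⁶ relative error in tests). The decimated transform would leave a
dyadic-phase-dependent component variance (measured SD spread ≈ 0.21–0.38
on unit-variance white noise) that produces spurious 5σ exceedances; the
stationary variant restores a stationary Gaussian baseline, under which
the 5σ per-sample exceedance probability is ≈ 5.7×10⁻⁷ and ten minutes of
clean baseline yields zero false labels. Inputs are symmetric-padded to a
multiple of 2^level and components truncated back.

Baseline statistics (mean, SD) come from a user-selected event-free window
of ≥ 10 s of the ictal-band component — moments, not a histogram fit,
since for a Gaussian they are the ML estimates. Detection thresholds the
component two-sidedly at μ_b ± 5σ_b; suprathreshold samples separated by
less than the 2 s cluster gap form one event spanning first to last
crossing. No minimum-duration cut-off is applied: brief pathological
discharges count, which deliberately biases *against* overestimating
stimulation efficacy. The detector is offset-invariant (the baseline mean
absorbs constant shifts). Manual labels remain first-class: label sets are
plain JSON, so the visual-inspection workflow (and labelling of
stimulation phases, where artifacts defeat automated detection) can edit
or replace detector output.

`P_ictal = 100·Σ D(i) / t_TOT` with the mode-dependent observation window:
protocol duration for stimulation phases; first onset to last offset for
control phases (undefined, hence an error, without labels). Ictal
amplitude is the maximum peak-to-peak value over a fixed channel subset
within labelled windows.

## Stimulus trains

Lognormal surrogate trains reuse the synthesis renewal generator with a
fit's (m, s); matched periodic trains share μ with σ = 0 (count
`⌊duration/μ⌋`); 1 Hz pacing is the positive control; minimum protocol
duration defaults to 20 min. Counts are computed from unrounded fitted
values — tables that print rounded μ can disagree by a few pulses.
Sparseness sweeps scale the log-SD as `s = f·ln(μ)` for fractions
f ∈ {0, 0.5, 1} and reuse the same per-trial sub-seeds across σ values so
trials are comparable, as in the original surrogate-validation design.
Exports use a two-column ASCII dialect (`time_ms value_uA`, 1 μs
resolution) with each pulse expanded to a charge-balanced biphasic step
(+A, −A, return to zero; 100 μs/phase, positive phase first by default);
export is byte-deterministic given (fit, duration, seed), and import
restores the train exactly at the printed resolution.

## Efficiency comparison

Pulse delivery is compared on a uniform grid (10-min steps). The
z-standardization `z_i = (x_i − mean)/SD` uses sample SD (divisor n−1).
The divergence search runs a two-sample KS test and, while significant
(α = 0.05 two-sided), truncates the final time point and repeats; the
divergence time is the earliest end time at which the truncated comparison
remains significant.

The KS sample convention matters and is explicit (`method`):

* `step_counts` (default) — samples are pulses delivered per step. A
  constant-rate and a renewal train differ in both location and spread of
  their per-step deliveries, so power accumulates with steps: 20-min
  trains (2 points per series) can never reach significance, while 24-h
  trains separate decisively — reproducing the qualitative dichotomy the
  slice experiments show. Standardizing both samples with pooled moments
  is a common monotone transform and cannot change a KS decision, so the
  z-step is a no-op here and is kept for the normalized cumulative plots.
* `standardized_cumulative` — samples are the per-series z-standardized
  cumulative counts. Two near-linear cumulative ramps become almost
  identical uniform grids after per-series standardization, so this
  variant has essentially no power at any horizon (verified numerically:
  p ≈ 1.0 at 24 h for every experimental parameter pair). Retained for
  methodological comparison, not as the default.
* `intervals` — conventional KS on raw inter-pulse intervals; a constant
  and a spread interval distribution differ from the first step, so this
  flags divergence immediately and carries no time information.

With the default method the six experimental (μ, σ) pairs diverge at
~40–60 min and show 24-h excesses of ~1000–2900 pulses, matching the
closed-form drift; exact-KS granularity sets a floor of four grid points
(40 min) on the earliest detectable divergence, so divergence times are
meaningful only at order-of-magnitude level. Long-horizon projections
regenerate each train from a deterministic per-pair sub-seed (whether a
short-protocol realization should be extended or regenerated is
underdetermined; regeneration with fixed seeds is the reproducible
choice).

## Problem sizes and numerical conventions

Monte-Carlo checks use 200–1000 seeds for 20-min train counts, 10–200
trials for sweep frequencies, and single seeded realizations per pair for
24-h projections — sizes at which sampling error is well below the
effects asserted. Boundary tolerances: events/pulses within 1 ns of the
duration boundary are kept; histogram final edges are nudged to close the
last bin; degenerate inputs (zero IQR, zero baseline SD, constant count
series, control phases without labels) raise errors rather than produce
silent values.

## Known limitations

* The surrogate recordings are statistical, not biophysical; detector
  performance on real MEA data (artifacts, drift, non-Gaussian noise) is
  not established by these tests.
* The step-counts KS comparison treats autocorrelated per-step deliveries
  as exchangeable samples; it reproduces the intended cumulative-trend
  logic but is not a calibrated hypothesis test, and its divergence times
  are descriptive.
* The Welch lognormality screen is conservative by construction (see
  above); it cannot reject mild tail departures at small n.
* Biological efficacy (ictal-state reduction under actual stimulation)
  requires recorded slice data and is outside the synthetic test path;
  the pipeline quantifies it only through P_ictal on supplied or detected
  labels.
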