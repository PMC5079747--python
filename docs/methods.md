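# Methods

This note documents the models, estimators, and numerical choices behind
`mfca3`, and what the synthetic-data tests do and do not establish about
real recordings.

## Data model and units

All quantities are held internally in ms / mV / pA / pC; converters live only
at the I/O boundary. A `PairedRecording` is an ordered list of trials; each
trial couples channel sweeps (`presynaptic_current`, `postsynaptic_voltage`,
`postsynaptic_current`) with a `StimulusProtocol` (stimulus times, train
frequency, repetition interval, HFS marker). The default sampling interval is
0.02 ms (50 kHz). Time zero is sweep start; feature extraction receives
stimulus times explicitly rather than re-detecting them. Latencies are
measured from the stimulus to the event onset.

Supported formats are HDF5 (canonical: `/trial_<k>/<role>` float64 datasets
with a `dt_ms` attribute; protocol and acquisition time as group attributes)
and a CSV directory (`trial_<k>_<role>.csv` with `time_ms,value` columns plus
a `protocol.json` sidecar). Vendor formats and streaming acquisition are out
of scope.

## Event kinetics: operational definitions

* **Baseline** — mean over the 5 ms immediately preceding the (first)
  stimulus of a train. For later train events the baseline stays anchored to
  the train's first stimulus: a compound voltage response is referenced to
  the pre-train baseline, so temporal summation is part of the measured
  peak, as it is in the cell.
* **EPSC isolation in trains** — on current channels the decaying tail of
  preceding events is fit (single exponential over the 4 ms before the
  stimulus) and subtracted before measuring, isolating each release event.
  This is what lets measured EPSC facilitation ratios match the generative
  multipliers to three digits in the noiseless limit. The extrapolation is
  accurate because EPSC decay (τ ≈ 6.5 ms) is fast relative to the 20-ms
  pulse spacing; it is *not* applied to voltage channels, where the slow
  decay makes a 4-ms fit unstable and where summation-inclusive peaks are
  the quantity of interest.
* **Peak amplitude** — maximum of the boxcar-smoothed deflection (0.4 ms for
  voltage, 0.1 ms for current) minus baseline, with polarity chosen by the
  larger absolute excursion (EPSCs at −70 mV are inward, reported as
  positive magnitudes with `polarity = −1`). Smoothing-then-max is robust on
  step-edged events and bounds the upward bias a raw pointwise maximum picks
  up from noise. The peak is searched from the stimulus to the next stimulus
  or 40 ms, whichever comes first — the EPSP kernel (rise 3.6 ms, decay
  134 ms) peaks ≈ 11.9 ms after onset, outside the 0–10 ms attribution
  window, so the peak search is deliberately wider than that window.
* **Onset and latency** — the chord through the 20% and 80% points of the
  rising phase, extrapolated to the baseline level. The 0–10 ms
  post-stimulus window is used for attribution (onset, spikes, action
  currents).
* **20–80% rise time** — between linearly interpolated threshold crossings
  scanned backward from the peak.
* **Decay** — least-squares monoexponential with offset
  (`fit_exponential`), from two measured rise times past the peak to the
  next stimulus or sweep end. Starting past the peak keeps the residual
  rising component out of the segment (fitting from the peak itself biases
  the fast EPSC τ by ≈ +4%; the offset start reduces this to < 0.2%). Seeds:
  offset from the final 10% of the segment, τ and amplitude from a
  log-linear regression on the tail; τ is bounded positive; non-convergence
  is reported as a flagged status, never an exception. A two-component
  variant is available for general multiexponential decays.
* **Maximal slope** — maximum of the central-difference first derivative
  over a 60-µs total span (±1 sample at 50 kHz), on the 1-kHz filtered
  trace, over the rising phase up to the peak / the 10-ms window / the spike
  onset, whichever is earliest. Ties break to the earliest time. This is the
  PTP metric because it is linear in synaptic amplitude and insensitive to
  spike contamination.
* **Charge** — trapezoidal integral of the baseline-subtracted current over
  60 ms from the stimulus (capped at the next stimulus), reported in pC;
  `train_charge` integrates from the first stimulus of a train.
* **Failure** — smoothed peak amplitude ≤ 3 × the raw baseline noise SD
  (plus a 1e-9 absolute floor so bit-flat noiseless sweeps classify
  correctly). Failures carry NaN kinetic fields and are excluded from
  kinetic averages; the failure fraction is reported separately.

### Filtering

The 1-kHz low-pass is a 4th-order Butterworth applied forward–backward
(zero phase, so onset latency is preserved). Because filtfilt squares the
magnitude response, the design cutoff is pre-warped upward
(f_d = f_c / (√2 − 1)^(1/8) ≈ 1.117 f_c) so the *combined* response is −3 dB
at the nominal 1 kHz. DC gain is exactly 1. Voltage channels are filtered
before kinetic analysis; current channels are not (a 1-kHz cutoff would
distort the 0.65-ms EPSC rise).

### Spike detection and de-spiking

A spike onset is the first sample where dV/dt exceeds 20 mV/ms sustained for
0.1 ms, computed on a 0.2-ms boxcar-smoothed trace, with a 2-ms refractory
period. Raw 50-kHz differentiation of 0.5-mV noise has ≈ 17 mV/ms slope SD —
useless against a 20 mV/ms criterion — while smoothing brings it to
≈ 2.5 mV/ms without touching the ≈ 150 mV/ms slope of an action potential.
Spikes are attributed to the stimulus whose 0–10 ms window contains the
onset; unattributable crossings are ignored. The threshold separates EPSP
slopes (≲ 15 mV/ms even at 4.4-fold potentiation) from spikes in the
simulated regime and is configurable for other regimes.

Before kinetic analysis the detected spikes are excised and bridged by
linear interpolation ("de-spiking") and only then is the trace filtered:
zero-phase filtering otherwise spreads the spike ≈ 0.5 ms backward into the
EPSP rising phase and biases the maximal slope of potentiated events a few
percent low.

## Plasticity quantification

* **Facilitation** — mean amplitude per stimulus index; ratios of means
  normalized to stimulus 1; SEM of per-trial ratios alongside.
* **PTP time course** — per-trial EPSP₁ maximal slope, normalized to the
  mean over all pre-tetanus trials; the *peak* is the single largest
  normalized post-tetanus value (not a fitted quantity); the window mean is
  taken over the closed interval 22–122 s after the tetanus end (trials at
  exactly 22 s or 122 s are included); percentages are 100 × normalized
  value.
* **Decay fit** — `1 + A·exp(−max(t − t₀, 0)/τ)` over *all* post-tetanus
  trials, with the offset fixed at the baseline (return to 100%) and the
  decay clock starting at the window onset t₀ = 22 s. The plateau-then-decay
  form matches the quantification convention that treats the first ≈ 20 s
  after the tetanus as the fully potentiated phase; it fits the noiseless
  simulation exactly. The same form (offset fixed at the baseline
  probability) is used for the detonation time course; per-trial binary
  spike outcomes can optionally be binned in time before fitting (default:
  per-trial, no binning — adequate because the fit is anchored by the fixed
  offset).
* **Spike probabilities** — exact counts: p_i = spikes on stimulus i /
  trials in period, for the control (pre-tetanus) period and the 22–122 s
  PTP window.
* **Summary statistics** — mean ± SEM and paired two-sided t-tests
  (scipy); identical pairs report t = 0, p = 1 by convention. No
  multiple-testing correction (single paired comparisons).

## Temporal summation model

`summation_ratios` implements the closed form
ratio_k = Σ_{j<k} exp(−j·Δ/τ) for the instant-rise monoexponential kernel
(peaks coincide with pulse times), the default because it reproduces the
reference ratios 1.86 / 2.60 at τ = 134 ms, Δ = 20 ms exactly. A finite-rise
(difference-of-exponentials) kernel is available for sensitivity analysis;
its peaks are located numerically between consecutive pulses on a 5-µs grid
and differ from the closed form by < 5% at the default kinetics. Ratios are
full precision internally and rounded to 2 decimals only at reporting.
`decompose_train_growth` superposes kernels scaled by the measured EPSC
facilitation ratios to predict the combined EPSP growth and reports which
component (release vs summation) dominates per stimulus.

## The simulator: what it emulates and what it does not

`synthetic_data` generates sweep-organized paired recordings at 50 kHz with:

* difference-of-exponentials EPSP/EPSC kernels, peak-normalized, with rise
  time constants calibrated numerically so the kernel 20–80% rise times are
  3.6 ms (EPSP, decay τ 134 ms) and 0.65 ms (EPSC, decay τ 6.5 ms);
* unitary peak amplitudes 9.6 mV / 100 pA, scaled by deterministic per-pulse
  facilitation multipliers (1, 2.57, 3.12; pulses beyond the table reuse the
  last entry) and by the PTP factor;
* PTP factor 1 before the tetanus, 4.42 immediately after, constant for the
  first 22 s, then decaying exponentially with τ = 89 s. The 22-s plateau
  encodes the convention that the 22–122 s window is the quantified PTP
  phase; the decay clock starts at the window onset;
* Bernoulli release failures (default probability 0.05 — failures are
  observed at this synapse but no rate is printed; multi-release-site mossy
  fiber boutons have low unitary failure rates), optional lognormal-free
  Gaussian amplitude jitter (default CV 0);
* synaptic latency 1.06 ms, defined *operationally*: the chord-onset of the
  difference-of-exponentials kernel lands ≈ 0.58 ms before its foot (the
  early rise is concave), so the generator computes that offset numerically
  and shifts each kernel so the measured onset equals stimulus + latency.
  The latency parameter therefore means exactly what the analysis reports;
* all-or-none presynaptic action currents (biphasic 0.3-ms transients);
* threshold-triggered stereotyped spikes: when the clean (noise-free) trace
  exceeds the pre-stimulus level by `spike_threshold` (default 20 mV) within
  0–10 ms of a stimulus, a raised-sine spike (100 mV, 2 ms) is pasted at the
  crossing, subject to a 2-ms refractory period. Referencing the threshold
  to the level *at the stimulus* lets events riding on earlier
  depolarization detonate, and makes ground-truth spike flags match
  slope-based detection exactly in the noiseless limit. Decisions are made
  on the clean trace so ground truth is well defined; noise is added
  afterwards;
* additive white Gaussian noise, 0.5 mV (voltage) / 5 pA (current) by
  default. One seeded generator per experiment; the seed is recorded in the
  recording metadata and output is bit-reproducible.

Plan builders cover the three standard protocols: repeated single stimuli,
50-Hz triplets (20 or 40 s repetition interval), and the PTP experiment
(baseline trains, one 100 Hz × 100 tetanus, recovery trains every 20 s).
The default PTP schedule uses 10 baseline and 15 post-tetanus trials at 20-s
intervals with 600-ms sweeps — enough trials inside and beyond the 22–122 s
window to constrain the decay fit while keeping a full simulated experiment
around a second of compute.

**Not emulated:** conductance-based or integrate-and-fire dynamics (the
spike is a pasted waveform), stochastic vesicle-pool depletion (facilitation
is deterministic multipliers), 1/f or line noise, series-resistance
artifacts, inhibitory circuitry, spontaneous (non-stimulus-locked) events.
Consequently, passing recovery tests demonstrates that the *estimators*
are unbiased and robust at realistic noise under the assumed kinetic model —
not that the model captures every feature of real recordings. In particular,
real EPSP onsets are sigmoidal (maximal slope mid-rise) whereas the
difference-of-exponentials kernel has its steepest point at the foot, and
real spike thresholds are dynamic.

## Numerical choices and degenerate inputs

* Derivative stencil: ±h samples with 2·h·dt the largest even multiple of
  dt not exceeding 60 µs; an error is raised if 2·dt exceeds the span.
* Exponential fits on constant input return amplitude ≈ 0 with the constant
  as offset and a "degenerate" status rather than failing.
* A flat normalized PTP series (no potentiation) reports peak and window
  mean of 100% with the decay fit flagged degenerate; an all-zero spike
  series skips the detonation fit with a status message.
* Fewer than 3 post-tetanus trials inside the PTP window raises an
  insufficient-data error, as does an empty period in spike-probability
  counts.
* The acceptance script's summation computation is cross-checked at run
  time against a brute-force sampled superposition at 1-µs resolution and
  aborts on disagreement > 1e-4.

## Known limitations

* EPSC isolation by tail extrapolation assumes monoexponential decay of the
  compound residual; at inter-pulse intervals ≲ 2 decay time constants the
  extrapolation error grows.
* The de-spiking bridge leaves a ≈ 0.5% low bias on the maximal slope of
  events whose spike onset falls close to the slope maximum (noiseless PTP
  peak reads ≈ 440% for a generative 442%).
* Failure classification on later events of compound voltage trains is
  unreliable (the summed response masks single-pulse failures); failure
  statistics should be taken from single-stimulus protocols or from
  residual-subtracted EPSC trains.
* The spike-slope criterion (20 mV/ms) is calibrated for the simulated
  regime; recordings with faster synaptic kinetics or slower spikes need the
  configurable threshold revisited against known events.
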