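# mfca3

Analysis of **unitary mossy fiber → CA3 pyramidal neuron paired recordings**:
kinetic feature extraction for stimulus-locked EPSPs/EPSCs, short-term
facilitation and post-tetanic potentiation (PTP) quantification,
spike-probability ("detonation") analysis, a temporal-summation superposition
model, and a seeded synthetic paired-recording simulator so that every stage
of the pipeline is testable without raw electrophysiology data.

## The scientific problem

Hippocampal mossy fiber boutons form unusually large synapses on CA3
pyramidal neurons. A single unitary EPSP (≈ 9.6 mV peak, 20–80% rise ≈ 3.6 ms,
decay τ ≈ 134 ms) usually fails to discharge the postsynaptic cell, but the
synapse shows strong short-term facilitation during 50 Hz bursts
(EPSC₂/EPSC₁ ≈ 2.57, EPSC₃/EPSC₁ ≈ 3.12) and exceptionally large PTP after a
100 Hz tetanus (HFS, 100 stimuli). This package implements the quantitative
analyses behind the question *when does the synapse "detonate"* — i.e. when
does one presynaptic action potential suffice to fire the CA3 neuron:

- **Event kinetics** — latency (stimulus → chord-extrapolated onset), peak
  amplitude, 20–80% rise time, monoexponential decay fit with offset, maximal
  rising-phase slope (60-µs derivative window on a 1-kHz low-pass filtered
  trace), charge (60-ms integration), failure classification.
- **Facilitation** — per-stimulus EPSC amplitudes normalized to the first
  event of the train.
- **Temporal summation** — with an instant-rise, monoexponentially decaying
  kernel of time constant τ at inter-pulse interval Δ, the peak of the k-th
  of n identical EPSPs obeys the closed form

  ratio_k = Σ_{j=0}^{k−1} exp(−j·Δ/τ)

  For τ = 134 ms and Δ = 20 ms (50 Hz triplet) this gives **1 : 1.86 : 2.60** —
  the growth expected from passive summation alone. Comparing it with the
  measured EPSC facilitation separates presynaptic (release) from
  postsynaptic (summation) contributions to train growth.
- **PTP and detonation** — per-trial EPSP₁ maximal slope normalized to the
  pre-tetanus baseline, its peak and mean in the standard 22–122 s
  post-tetanus window, a baseline-anchored exponential decay fit, and exact
  per-stimulus spike probabilities in control vs PTP periods.

## Worked example

Simulate a full PTP-induction experiment (baseline 50 Hz triplets, one
100 Hz × 100 tetanus, recovery trials every 20 s), extract features, and
quantify plasticity:

```bash
mfca3 run --seed 7 --outdir demo
mfca3 report --outdir demo
```

```
PTP / detonation summary
  epsp1_baseline_mean_slope_mV_per_ms: 3.403
  ptp_window_s: 22, 122
  ptp_peak_percent: 412.5
  ptp_window_mean_percent: 278.1
  ptp_decay_tau_s: 88.41
  detonation_baseline_p1: 0
  detonation_window_p1: 1
  spike_probability_control: 0, 1, 0.9
  spike_probability_ptp: 1, 1, 0.8
  summation_ratios: 1, 1.86, 2.6
```

Reading the output: at baseline the first stimulus never fires the cell
(`p₁ = 0`) while the facilitated later pulses do — *conditional* detonation.
After the tetanus the EPSP₁ slope is potentiated ~4-fold (peak 412% of
baseline under 0.5 mV recording noise; the generative peak factor is 4.42)
and decays with τ ≈ 88 s (generative 89 s); within the 22–122 s window a
*single* stimulus reliably detonates the cell (`p₁ = 1`) — the plasticity-
dependent switch to full detonation.

The summation model alone:

```bash
mfca3 summation --tau 134 --interval 20 --n 3
```

```
pulse  peak_ratio
    1  1.00
    2  1.86
    3  2.60
```

The same analyses are available as a library (`mfca3.summation_ratios`,
`mfca3.extract_recording_features`, `mfca3.analyze_ptp_experiment`, …), and
the simulator (`mfca3.simulate_experiment`) returns a per-stimulus
ground-truth table (true amplitudes, failure and spike flags, PTP factor)
for recovery testing.

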