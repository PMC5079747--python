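"""Generative simulator of paired bouton-stimulation / CA3 recordings.

The simulator emits sweep-organized paired recordings with the statistical
structure the analysis assumes: stimulus-locked unitary EPSPs/EPSCs built from
difference-of-exponentials kernels, deterministic per-pulse facilitation,
slowly decaying post-tetanic potentiation (PTP) after a 100 Hz tetanus,
all-or-none presynaptic action currents, Bernoulli release failures, additive
white Gaussian recording noise, and stereotyped postsynaptic spikes pasted
where the clean depolarization crosses threshold within the 0-10 ms
post-stimulus window.

Default kinetic parameters reproduce measured unitary mossy-fiber EPSP/EPSC
properties: 9.6 mV peak, 1.06 ms latency, 3.6 ms 20-80% rise, 134 ms decay
time constant for EPSPs; 0.65 ms rise and 6.5 ms decay for EPSCs; train
facilitation ratios (1, 2.57, 3.12); PTP peak factor 4.42 decaying with an
89 s time constant.

Two calibrations connect generator parameters to the operational definitions
used by the feature extractor:

* ``calibrate_rise_tau`` chooses the kernel's rise time constant so the
  20-80% rise time of the unit kernel equals a target value.
* ``chord_onset_offset`` evaluates where the standard onset estimator (the
  20-80% chord extrapolated back to baseline) lands relative to the kernel's
  true foot.  The kernel has a convex early rise, so the chord onset falls
  *before* the foot; the simulator shifts each kernel so that the measured
  onset equals stimulus time + ``synaptic_latency``, making the latency
  parameter mean the same operational quantity the analysis reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .trace_io import (
    DEFAULT_DT_MS,
    PairedRecording,
    StimulusProtocol,
    Sweep,
    Trial,
)

__all__ = [
    "SynapseModelParams",
    "SimulationPlan",
    "epsp_kernel",
    "calibrate_rise_tau",
    "chord_onset_offset",
    "ptp_factor",
    "simulate_trial",
    "simulate_experiment",
    "single_stimulus_plan",
    "triplet_plan",
    "ptp_experiment_plan",
]

#: Rise time constants (ms) calibrated so the unit kernel's 20-80% rise time
#: equals 3.6 ms (EPSP, decay tau 134 ms) and 0.65 ms (EPSC, decay tau 6.5 ms).
DEFAULT_EPSP_RISE_TAU = 3.080219
DEFAULT_EPSC_RISE_TAU = 0.738591


def epsp_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Peak-normalized difference-of-exponentials synaptic kernel.

    ``k(t) = (exp(-t/decay_tau) - exp(-t/rise_tau)) / peak`` for t >= 0, zero
    before.  ``rise_tau = 0`` gives the instant-rise limit ``exp(-t/decay_tau)``.
    The late-time log-slope is exactly -1/decay_tau, so a monoexponential fit
    of the tail recovers the decay time constant.
    """
    t = np.asarray(t, dtype=float)
    if decay_tau <= 0:
        raise ValueError("decay_tau must be > 0")
    if rise_tau != 0.0 and not (0.0 < rise_tau < decay_tau):
        raise ValueError("require 0 <= rise_tau < decay_tau")
    tp = np.maximum(t, 0.0)
    if rise_tau == 0.0:
        k = np.exp(-tp / decay_tau)
    else:
        k = np.exp(-tp / decay_tau) - np.exp(-tp / rise_tau)
        t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
        peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
        k = k / peak
    return np.where(t >= 0, k, 0.0)


def kernel_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Time of the kernel maximum relative to its foot, ms."""
    if rise_tau == 0.0:
        return 0.0
    return rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)


def _kernel_rise_2080(rise_tau: float, decay_tau: float, dt: float = 0.001) -> float:
    t = np.arange(0.0, 6.0 * kernel_peak_time(rise_tau, decay_tau) + dt, dt)
    k = epsp_kernel(t, rise_tau, decay_tau)
    ipk = int(np.argmax(k))

    def crossing(level: float) -> float:
        i = int(np.searchsorted(k[: ipk + 1] >= level, True))
        y0, y1 = k[i - 1], k[i]
        return t[i - 1] + (level - y0) / (y1 - y0) * dt

    return crossing(0.8) - crossing(0.2)


def calibrate_rise_tau(rise_2080: float, decay_tau: float) -> float:
    """Rise time constant giving a target 20-80% rise time for the kernel."""
    f = lambda tr: _kernel_rise_2080(tr, decay_tau) - rise_2080
    hi = min(0.99 * decay_tau, 50.0 * rise_2080)
    return brentq(f, 1e-3 * rise_2080, hi, xtol=1e-7)


def chord_onset_offset(rise_tau: float, decay_tau: float, dt: float = 0.0005) -> float:
    """Chord-extrapolated onset of the unit kernel relative to its foot, ms.

    Negative values mean the 20-80% chord, extended back to baseline, crosses
    zero before the kernel actually departs from baseline.
    """
    t = np.arange(0.0, 6.0 * kernel_peak_time(rise_tau, decay_tau) + dt, dt)
    k = epsp_kernel(t, rise_tau, decay_tau)
    ipk = int(np.argmax(k))

    def crossing(level: float) -> float:
        i = int(np.searchsorted(k[: ipk + 1] >= level, True))
        y0, y1 = k[i - 1], k[i]
        return t[i - 1] + (level - y0) / (y1 - y0) * dt

    t20, t80 = crossing(0.2), crossing(0.8)
    slope = 0.6 / (t80 - t20)
    return t20 - 0.2 / slope


@dataclass
class SynapseModelParams:
    """Generative parameters of the synthetic paired recording.

    Amplitudes are unitary peak values before facilitation/PTP scaling; the
    EPSC is emitted as an inward (negative) current.  ``spike_threshold`` is
    depolarization from rest in mV; spikes are decided on the clean (noise
    free) trace so ground truth is well defined.  ``failure_prob`` is the
    per-stimulus probability that release fails entirely.
    """

    epsp_amp: float = 9.6                 # mV
    epsp_rise_tau: float = DEFAULT_EPSP_RISE_TAU   # ms
    epsp_decay_tau: float = 134.0         # ms
    epsc_amp: float = 100.0               # pA (magnitude; emitted negative)
    epsc_rise_tau: float = DEFAULT_EPSC_RISE_TAU   # ms
    epsc_decay_tau: float = 6.5           # ms
    synaptic_latency: float = 1.06        # ms, stimulus -> measured onset
    facilitation_ratios: tuple[float, ...] = (1.0, 2.57, 3.12)
    failure_prob: float = 0.05
    amplitude_jitter: float = 0.0         # CV of per-event amplitude, successes
    ptp_peak_factor: float = 4.42
    ptp_decay_tau: float = 89.0           # s
    ptp_onset_delay: float = 22.0         # s: plateau before decay starts
    noise_sd: float = 0.5                 # mV, voltage channels
    noise_sd_current: float = 5.0         # pA, current channels
    spike_threshold: float = 20.0         # mV depolarization from rest
    refractory: float = 2.0               # ms
    resting_potential: float = -70.0      # mV
    action_current_amp: float = 1500.0    # pA
    spike_height: float = 100.0           # mV
    spike_width: float = 2.0              # ms
    dt: float = DEFAULT_DT_MS             # ms

    def __post_init__(self) -> None:
        for name in ("epsp_decay_tau", "epsc_decay_tau", "ptp_decay_tau", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.failure_prob <= 1.0):
            raise ValueError("failure_prob must be in [0, 1]")
        if self.facilitation_ratios[0] != 1.0:
            raise ValueError("facilitation_ratios[0] must be 1")
        if self.ptp_peak_factor < 1.0:
            raise ValueError("ptp_peak_factor must be >= 1")
        if self.epsp_rise_tau >= self.epsp_decay_tau or self.epsc_rise_tau >= self.epsc_decay_tau:
            raise ValueError("rise time constants must be < decay time constants")

    def facilitation(self, i: int) -> float:
        """Per-pulse multiplier; pulses beyond the table reuse the last entry."""
        return self.facilitation_ratios[min(i, len(self.facilitation_ratios) - 1)]


def ptp_factor(t_since_hfs: float | np.ndarray, params: SynapseModelParams) -> np.ndarray | float:
    """PTP multiplier as a function of time (s) since the end of the tetanus.

    1 before the tetanus (t < 0); full potentiation ``ptp_peak_factor`` during
    the first ``ptp_onset_delay`` seconds; then a monoexponential return to
    baseline with time constant ``ptp_decay_tau``.
    """
    t = np.asarray(t_since_hfs, dtype=float)
    decay_t = np.maximum(t - params.ptp_onset_delay, 0.0)
    factor = 1.0 + (params.ptp_peak_factor - 1.0) * np.exp(-decay_t / params.ptp_decay_tau)
    out = np.where(t < 0, 1.0, factor)
    return float(out) if np.isscalar(t_since_hfs) else out


def _spike_waveform(dt: float, height: float, width: float) -> np.ndarray:
    """Stereotyped spike: a raised-sine bump of given width and height."""
    n = max(int(round(width / dt)), 4)
    x = np.arange(n) / n
    return height * np.sin(np.pi * x) ** 2


@dataclass
class TrialResult:
    channels: dict[str, Sweep]
    truth: pd.DataFrame


def simulate_trial(
    protocol: StimulusProtocol,
    params: SynapseModelParams,
    rng: np.random.Generator,
    t_since_hfs: float = -np.inf,
    sweep_duration: float = 600.0,
    channels: Sequence[str] = ("presynaptic_current", "postsynaptic_voltage"),
    sweep_index: int = 0,
    acquisition_time: float = 0.0,
) -> TrialResult:
    """Simulate one trial and return its channel sweeps plus ground truth.

    ``t_since_hfs`` is seconds from the end of the PTP-inducing tetanus to
    sweep start (-inf before induction).  The ground-truth table has one row
    per stimulus with the drawn failure flag, the true unitary amplitude
    (facilitation x PTP x jitter applied), the PTP factor, and spike flag and
    time for voltage channels.
    """
    n = int(round(sweep_duration / params.dt))
    t = np.arange(n) * params.dt
    stims = protocol.stim_times
    if stims[-1] + 10.0 > sweep_duration:
        raise ValueError("sweep_duration too short for the stimulus train")

    failures = rng.random(stims.size) < params.failure_prob
    jitter = (
        rng.normal(1.0, params.amplitude_jitter, size=stims.size)
        if params.amplitude_jitter > 0
        else np.ones(stims.size)
    )
    jitter = np.clip(jitter, 0.0, None)
    factors = np.array(
        [
            ptp_factor(t_since_hfs + s / 1000.0, params) if np.isfinite(t_since_hfs) else 1.0
            for s in stims
        ]
    )

    out: dict[str, Sweep] = {}
    truth_rows: list[dict] = []
    base_rows = [
        {
            "stim_index": i,
            "stim_time_ms": stims[i],
            "failure": bool(failures[i]),
            "ptp_factor": factors[i],
            "spike": False,
            "spike_time_ms": np.nan,
        }
        for i in range(stims.size)
    ]

    if "presynaptic_current" in channels:
        pre = np.zeros(n)
        # all-or-none action current shortly after each suprathreshold pulse
        ac_width = 0.3  # ms
        m = max(int(round(ac_width / params.dt)), 3)
        wav = -params.action_current_amp * np.sin(np.pi * np.arange(m) / m)
        for s in stims:
            i0 = int(round((s + 0.2) / params.dt))
            pre[i0 : i0 + m] += wav[: max(0, min(m, n - i0))]
        pre += rng.normal(0.0, params.noise_sd_current, size=n)
        out["presynaptic_current"] = Sweep(
            pre, dt=params.dt, channel_role="presynaptic_current",
            sweep_index=sweep_index, acquisition_time=acquisition_time,
        )

    # kernel onset correction: place the kernel so the chord-estimated onset
    # sits at stim + synaptic_latency
    epsp_corr = chord_onset_offset(params.epsp_rise_tau, params.epsp_decay_tau)
    epsc_corr = chord_onset_offset(params.epsc_rise_tau, params.epsc_decay_tau)

    if "postsynaptic_voltage" in channels:
        clean = np.zeros(n)
        amps_v = np.where(failures, 0.0, params.epsp_amp * jitter) * np.array(
            [params.facilitation(i) for i in range(stims.size)]
        ) * factors
        for i, s in enumerate(stims):
            if amps_v[i] == 0.0:
                continue
            onset = s + params.synaptic_latency - epsp_corr
            clean += amps_v[i] * epsp_kernel(t - onset, params.epsp_rise_tau, params.epsp_decay_tau)
        # threshold-triggered stereotyped spikes, decided on the clean trace;
        # the threshold is depolarization added since the stimulus (local
        # pre-stimulus reference), so events riding on earlier depolarization
        # still detonate
        v = clean.copy()
        spike_wave = _spike_waveform(params.dt, params.spike_height, params.spike_width)
        last_spike_t = -np.inf
        rows = [dict(r) for r in base_rows]
        for i, s in enumerate(stims):
            i0 = int(round(s / params.dt)) + 1
            i1 = min(int(round((s + 10.0) / params.dt)) + 1, n)
            level = clean[i0 - 1] + params.spike_threshold
            above = clean[i0 - 1 : i1] >= level
            # first upward crossing of the level inside the 0-10 ms window
            crossings = np.flatnonzero(above[1:] & ~above[:-1])
            if crossings.size == 0:
                continue
            ic = i0 + int(crossings[0])
            tc = ic * params.dt
            if tc - last_spike_t < params.refractory:
                continue
            m = min(spike_wave.size, n - ic)
            v[ic : ic + m] += spike_wave[:m]
            last_spike_t = tc
            rows[i]["spike"] = True
            rows[i]["spike_time_ms"] = tc - s
        v = v + params.resting_potential
        if params.noise_sd > 0:
            v = v + rng.normal(0.0, params.noise_sd, size=n)
        out["postsynaptic_voltage"] = Sweep(
            v, dt=params.dt, channel_role="postsynaptic_voltage",
            sweep_index=sweep_index, acquisition_time=acquisition_time,
        )
        for i, r in enumerate(rows):
            r["amplitude_mV"] = amps_v[i]
        base_rows = rows

    if "postsynaptic_current" in channels:
        cur = np.zeros(n)
        amps_c = np.where(failures, 0.0, params.epsc_amp * jitter) * np.array(
            [params.facilitation(i) for i in range(stims.size)]
        ) * factors
        for i, s in enumerate(stims):
            if amps_c[i] == 0.0:
                continue
            onset = s + params.synaptic_latency - epsc_corr
            cur -= amps_c[i] * epsp_kernel(t - onset, params.epsc_rise_tau, params.epsc_decay_tau)
        if params.noise_sd_current > 0:
            cur = cur + rng.normal(0.0, params.noise_sd_current, size=n)
        out["postsynaptic_current"] = Sweep(
            cur, dt=params.dt, channel_role="postsynaptic_current",
            sweep_index=sweep_index, acquisition_time=acquisition_time,
        )
        for i, r in enumerate(base_rows):
            r["amplitude_pA"] = amps_c[i]

    truth = pd.DataFrame(base_rows)
    truth.insert(0, "trial_index", sweep_index)
    truth.insert(1, "acquisition_time_s", acquisition_time)
    truth.insert(2, "t_since_hfs_s", t_since_hfs)
    return TrialResult(channels=out, truth=truth)


@dataclass
class SimulationPlan:
    """Trial schedule for one simulated experiment.

    ``schedule`` is an ordered list of (acquisition_time_s, protocol); times
    must be strictly increasing.  ``channels`` lists the roles to emit per
    trial; ``sweep_duration`` is per-trial length in ms (the HFS trial is
    extended automatically to cover its train).
    """

    schedule: list[tuple[float, StimulusProtocol]]
    params: SynapseModelParams = field(default_factory=SynapseModelParams)
    channels: tuple[str, ...] = ("presynaptic_current", "postsynaptic_voltage")
    sweep_duration: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        times = [t for t, _ in self.schedule]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("schedule times must be strictly increasing")


def single_stimulus_plan(
    n_trials: int = 10,
    interval_s: float = 20.0,
    params: SynapseModelParams | None = None,
    channels: tuple[str, ...] = ("presynaptic_current", "postsynaptic_voltage"),
    sweep_duration: float = 600.0,
    seed: int = 0,
) -> SimulationPlan:
    """Repeated single-stimulus trials (unitary event characterization)."""
    proto = StimulusProtocol.train(1, start=20.0, repetition_interval=interval_s)
    schedule = [(k * interval_s, proto) for k in range(n_trials)]
    return SimulationPlan(schedule, params or SynapseModelParams(), channels,
                          sweep_duration, seed)


def triplet_plan(
    n_trials: int = 10,
    frequency: float = 50.0,
    interval_s: float = 40.0,
    params: SynapseModelParams | None = None,
    channels: tuple[str, ...] = ("presynaptic_current", "postsynaptic_voltage"),
    sweep_duration: float = 600.0,
    seed: int = 0,
) -> SimulationPlan:
    """Repeated 3-stimulus 50 Hz trains (facilitation / burst detonation)."""
    proto = StimulusProtocol.train(3, frequency, start=20.0, repetition_interval=interval_s)
    schedule = [(k * interval_s, proto) for k in range(n_trials)]
    return SimulationPlan(schedule, params or SynapseModelParams(), channels,
                          sweep_duration, seed)


def ptp_experiment_plan(
    n_baseline: int = 10,
    n_post: int = 15,
    interval_s: float = 20.0,
    train_stimuli: int = 3,
    frequency: float = 50.0,
    params: SynapseModelParams | None = None,
    channels: tuple[str, ...] = ("presynaptic_current", "postsynaptic_voltage"),
    sweep_duration: float = 600.0,
    seed: int = 0,
) -> SimulationPlan:
    """PTP induction protocol: baseline trains, one 100 Hz x 100 tetanus,
    then post-tetanus trains at the same repetition interval."""
    if train_stimuli > 1:
        proto = StimulusProtocol.train(train_stimuli, frequency, start=20.0,
                                       repetition_interval=interval_s)
    else:
        proto = StimulusProtocol.train(1, start=20.0, repetition_interval=interval_s)
    schedule: list[tuple[float, StimulusProtocol]] = [
        (k * interval_s, proto) for k in range(n_baseline)
    ]
    t_hfs = n_baseline * interval_s
    schedule.append((t_hfs, StimulusProtocol.hfs(start=20.0)))
    for k in range(n_post):
        schedule.append((t_hfs + (k + 1) * interval_s, proto))
    return SimulationPlan(schedule, params or SynapseModelParams(), channels,
                          sweep_duration, seed)


def simulate_experiment(plan: SimulationPlan) -> tuple[PairedRecording, pd.DataFrame]:
    """Run a full simulated experiment.

    Returns the recording and a per-stimulus ground-truth table (true
    amplitudes, failure flags, spike flags and times, PTP factor).  Fully
    reproducible from ``plan.seed``.
    """
    rng = np.random.default_rng(plan.seed)
    params = plan.params
    trials: list[Trial] = []
    truth_tables: list[pd.DataFrame] = []
    hfs_end_s: float | None = None
    for k, (acq, proto) in enumerate(plan.schedule):
        duration = plan.sweep_duration
        if proto.is_hfs:
            duration = max(duration, proto.stim_times[-1] + 100.0)
        t_since = -np.inf if hfs_end_s is None else acq - hfs_end_s
        res = simulate_trial(
            proto, params, rng,
            t_since_hfs=t_since,
            sweep_duration=duration,
            channels=plan.channels,
            sweep_index=k,
            acquisition_time=acq,
        )
        trials.append(Trial(channels=res.channels, protocol=proto, acquisition_time=acq))
        truth_tables.append(res.truth)
        if proto.is_hfs:
            hfs_end_s = acq + proto.stim_times[-1] / 1000.0
    rec = PairedRecording(
        trials=trials,
        holding_potential=params.resting_potential,
        metadata={"simulated": True, "seed": plan.seed},
    )
    truth = pd.concat(truth_tables, ignore_index=True)
    return rec, truth


def params_from_dict(d: dict) -> SynapseModelParams:
    """Build SynapseModelParams from a plain dict (e.g. a JSON config)."""
    base = SynapseModelParams()
    known = {k: v for k, v in d.items() if hasattr(base, k)}
    if "facilitation_ratios" in known:
        known["facilitation_ratios"] = tuple(known["facilitation_ratios"])
    unknown = set(d) - set(known)
    if unknown:
        raise ValueError(f"unknown simulator parameters: {sorted(unknown)}")
    return replace(base, **known)
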