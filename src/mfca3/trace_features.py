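"""Kinetic feature extraction for stimulus-locked synaptic events.

Operational definitions follow standard intracellular-recording practice:

* Event onset is the intersection of the chord through the 20% and 80%
  points of the rising phase with the preceding baseline; latency is measured
  from the stimulus to that onset.
* Peak amplitude is baseline-subtracted; the 20-80% rise time is taken
  between interpolated threshold crossings on the rising phase.
* The decay time course is fit with a monoexponential including an offset,
  from the peak to the end of the sweep or the next stimulus.
* The maximal slope of the rising phase is the maximum of the first
  time-derivative, computed with a 60-us central-difference window on the
  1-kHz low-pass filtered trace (voltage channels).
* Charge is the integral of the baseline-subtracted current, reported in pC.
* Onsets, spikes and action currents are attributed to a stimulus only
  within the 0-10 ms post-stimulus analysis window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .trace_io import PairedRecording, StimulusProtocol, Sweep

__all__ = [
    "FeatureConfig",
    "EventFeatures",
    "SpikeEvent",
    "ExponentialFit",
    "lowpass_1khz",
    "detect_action_currents",
    "measure_onset",
    "event_features",
    "fit_exponential",
    "max_slope",
    "detect_spikes",
    "train_charge",
    "extract_recording_features",
]


@dataclass
class FeatureConfig:
    """Windows and thresholds for feature extraction (times in ms)."""

    analysis_window_ms: float = 10.0     # onset/spike attribution window
    baseline_ms: float = 5.0             # baseline before the (first) stimulus
    residual_fit_ms: float = 4.0         # pre-stimulus span for residual-decay fit
    peak_window_ms: float = 40.0         # peak search limit (capped at next stim)
    peak_smooth_voltage_ms: float = 0.4  # mean around peak, voltage channels
    peak_smooth_current_ms: float = 0.1  # mean around peak, current channels
    filter_voltage: bool = True          # 1-kHz low-pass before kinetic analysis
    failure_sd_mult: float = 3.0         # failure if amplitude <= mult * noise SD
    derivative_span_us: float = 60.0     # central-difference window
    spike_slope_threshold: float = 20.0  # mV/ms
    spike_sustain_ms: float = 0.1        # criterion must hold this long
    spike_refractory_ms: float = 2.0
    spike_smooth_ms: float = 0.2         # boxcar before spike differentiation
    spike_blank_ms: float = 3.0          # de-spiking span after spike onset
    action_current_threshold: float = 100.0  # pA
    charge_window_ms: float = 60.0       # integration window from first stimulus


#: Sentinel used for kinetic fields of failure events.
NAN = float("nan")


@dataclass
class EventFeatures:
    """Per-stimulus kinetic descriptors of one synaptic event.

    Kinetic fields are NaN for failures.  ``peak_amplitude`` is the
    baseline-subtracted deflection magnitude (mV or pA); ``polarity`` is +1
    for depolarizing/outward and -1 for inward deflections.
    """

    stim_time: float
    onset_time: float = NAN
    latency: float = NAN
    peak_amplitude: float = NAN
    peak_time: float = NAN
    polarity: int = 1
    rise_time_20_80: float = NAN
    decay_tau: float = NAN
    decay_offset: float = NAN
    max_slope: float = NAN
    max_slope_time: float = NAN
    charge: float = NAN
    baseline: float = NAN
    noise_sd: float = NAN
    is_failure: bool = False
    fit_ok: bool = True
    fit_message: str = ""

    def to_dict(self) -> dict:
        return {
            "stim_time_ms": self.stim_time,
            "onset_time_ms": self.onset_time,
            "latency_ms": self.latency,
            "amplitude": self.peak_amplitude,
            "peak_time_ms": self.peak_time,
            "polarity": self.polarity,
            "rise_time_20_80_ms": self.rise_time_20_80,
            "decay_tau_ms": self.decay_tau,
            "decay_offset": self.decay_offset,
            "max_slope": self.max_slope,
            "max_slope_time_ms": self.max_slope_time,
            "charge_pC": self.charge,
            "baseline": self.baseline,
            "noise_sd": self.noise_sd,
            "is_failure": self.is_failure,
            "fit_ok": self.fit_ok,
        }


@dataclass
class SpikeEvent:
    """A detected action potential attributed to one stimulus."""

    spike_time: float        # ms, within the sweep
    stimulus_index: int
    latency_to_onset: float  # ms from the stimulus to spike onset


@dataclass
class ExponentialFit:
    """Result of a 1- or 2-component exponential fit with optional offset."""

    amplitudes: np.ndarray
    taus: np.ndarray
    offset: float
    success: bool
    residual_norm: float
    message: str = ""

    @property
    def tau(self) -> float:
        """Slowest (dominant) time constant."""
        return float(np.max(self.taus))

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.offset)
        for a, tau in zip(self.amplitudes, self.taus):
            out = out + a * np.exp(-t / tau)
        return out


# ---------------------------------------------------------------------------
# Filtering and derivatives
# ---------------------------------------------------------------------------

def lowpass_1khz(sweep: Sweep, cutoff_hz: float = 1000.0, order: int = 4) -> Sweep:
    """Zero-phase Butterworth low-pass with -3 dB at ``cutoff_hz``.

    Forward-backward filtering squares the magnitude response, so the design
    cutoff is pre-warped upward such that the *combined* response is -3 dB at
    the nominal cutoff; DC gain is exactly 1 and onset latency is preserved.
    """
    fs = 1000.0 / sweep.dt  # Hz
    # |H|^2 = 1/2 at f_c  =>  single-pass (f_c/f_d)^(2*order) = sqrt(2) - 1
    f_design = cutoff_hz / (math.sqrt(2.0) - 1.0) ** (1.0 / (2 * order))
    if f_design >= fs / 2:
        raise ValueError(
            f"sampling too coarse for a {cutoff_hz:g} Hz cutoff (dt={sweep.dt} ms)"
        )
    sos = signal.butter(order, f_design, btype="low", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, sweep.samples)
    return sweep.copy_with(filtered)


def _derivative(samples: np.ndarray, dt: float, span_us: float) -> np.ndarray:
    """Central-difference first derivative with total span <= ``span_us``.

    Uses a +/- h sample stencil with 2*h*dt the largest even multiple of the
    sampling interval not exceeding the requested span (at 50 kHz and 60 us:
    h = 1, span 40 us).  Units: input units per ms.
    """
    span_ms = span_us / 1000.0
    h = int(span_ms / (2.0 * dt) + 1e-9)
    if h < 1:
        raise ValueError(
            f"derivative span {span_us} us shorter than 2 samples at dt={dt} ms"
        )
    d = np.full(samples.size, np.nan)
    d[h:-h] = (samples[2 * h :] - samples[: -2 * h]) / (2 * h * dt)
    return d


def max_slope(
    sweep: Sweep,
    window: tuple[float, float],
    span_us: float = 60.0,
) -> tuple[float, float]:
    """Maximum first derivative within ``window`` (ms), with its time.

    Ties are broken by the earliest time.  Returns (slope in units/ms, time).
    """
    t0, t1 = window
    d = _derivative(sweep.samples, sweep.dt, span_us)
    i0, i1 = sweep.index_at(t0), sweep.index_at(t1)
    if i1 <= i0:
        raise ValueError("window shorter than the derivative span")
    seg = d[i0 : i1 + 1]
    valid = np.isfinite(seg)
    if not valid.any():
        raise ValueError("window lies outside the differentiable range")
    seg = np.where(valid, seg, -np.inf)
    imax = int(np.argmax(seg))  # argmax returns the first maximum
    return float(seg[imax]), float(sweep.t0 + (i0 + imax) * sweep.dt)


# ---------------------------------------------------------------------------
# Exponential fitting
# ---------------------------------------------------------------------------

def _tail_seed(t: np.ndarray, y: np.ndarray, offset: float) -> tuple[float, float]:
    """Log-linear seed (amplitude, tau) from the decaying part of y - offset."""
    z = y - offset
    sign = 1.0 if np.nanmean(z[: max(3, z.size // 4)]) >= 0 else -1.0
    z = sign * z
    pos = z > max(1e-12, 1e-3 * np.nanmax(np.abs(z)))
    if pos.sum() < 3:
        return sign * float(np.nanmax(np.abs(z), initial=0.0)), max(
            (t[-1] - t[0]) / 3.0, 1e-6
        )
    coeff = np.polyfit(t[pos], np.log(z[pos]), 1)
    tau = -1.0 / coeff[0] if coeff[0] < 0 else (t[-1] - t[0])
    amp = sign * math.exp(coeff[1])
    return amp, max(tau, 1e-6)


def fit_exponential(
    t: np.ndarray,
    y: np.ndarray,
    n_components: int = 1,
    with_offset: bool = True,
) -> ExponentialFit:
    """Least-squares multiexponential fit ``sum_i A_i exp(-t/tau_i) [+ c]``.

    Time constants are constrained positive.  Seeds come from the mean of the
    final 10% of the segment (offset) and a log-linear regression on the tail
    (amplitude and tau); the two-component seed peels the slow component
    first.  Non-convergence is reported in ``success``/``message`` rather
    than raised.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if t.size != y.size:
        raise ValueError("t and y must have equal length")
    if t.size < 3 * (2 * n_components + 1):
        raise ValueError(
            f"need at least {3 * (2 * n_components + 1)} points for {n_components} component(s)"
        )
    t_shift = t - t[0]
    c0 = float(np.mean(y[-max(3, y.size // 10) :])) if with_offset else 0.0

    # nearly constant input: report amplitude ~ 0 and the constant offset
    if np.ptp(y) <= 1e-12 * max(1.0, abs(c0)):
        return ExponentialFit(
            amplitudes=np.zeros(n_components),
            taus=np.full(n_components, (t_shift[-1] or 1.0)),
            offset=float(np.mean(y)) if with_offset else 0.0,
            success=True,
            residual_norm=0.0,
            message="degenerate: constant input",
        )

    a0, tau0 = _tail_seed(t_shift, y, c0)
    if n_components == 1:
        p0 = [a0, tau0]
    else:
        slow = a0 * np.exp(-t_shift / tau0)
        a1, tau1 = _tail_seed(t_shift, y - slow, c0)
        p0 = [a0, tau0, a1, max(min(tau1, tau0 / 2.0), 1e-6)]
    if with_offset:
        p0.append(c0)

    def model(x, *p):
        out = np.zeros_like(x)
        for i in range(n_components):
            out = out + p[2 * i] * np.exp(-x / p[2 * i + 1])
        if with_offset:
            out = out + p[-1]
        return out

    lo = []
    hi = []
    for _ in range(n_components):
        lo += [-np.inf, 1e-9]
        hi += [np.inf, np.inf]
    if with_offset:
        lo.append(-np.inf)
        hi.append(np.inf)
    try:
        popt, _ = optimize.curve_fit(
            model, t_shift, y, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        return ExponentialFit(
            amplitudes=np.full(n_components, np.nan),
            taus=np.full(n_components, np.nan),
            offset=np.nan,
            success=False,
            residual_norm=np.nan,
            message=f"fit failed: {exc}",
        )
    amplitudes = np.array([popt[2 * i] for i in range(n_components)])
    taus = np.array([popt[2 * i + 1] for i in range(n_components)])
    offset = float(popt[-1]) if with_offset else 0.0
    # report amplitudes referenced to t[0] = segment start
    resid = y - model(t_shift, *popt)
    order = np.argsort(taus)[::-1]
    return ExponentialFit(
        amplitudes=amplitudes[order],
        taus=taus[order],
        offset=offset,
        success=True,
        residual_norm=float(np.linalg.norm(resid)),
    )


# ---------------------------------------------------------------------------
# Event geometry: baseline, peak, onset, rise
# ---------------------------------------------------------------------------

def _baseline_window(
    anchor_time: float,
    config: FeatureConfig,
) -> tuple[float, float]:
    """Baseline interval immediately preceding ``anchor_time``.

    For later events in a train the anchor is the *first* stimulus of the
    train, so amplitudes of compound (voltage) responses are referenced to
    the pre-train baseline — temporal summation is part of the measured
    peak, as it is in the recorded cell.
    """
    return anchor_time - config.baseline_ms, anchor_time


def subtract_residual_decay(
    sweep: Sweep,
    stim_time: float,
    config: FeatureConfig | None = None,
    center: float | None = None,
) -> Sweep:
    """Remove the decaying tail of preceding events from ``stim_time`` on.

    Fits a single exponential (no offset) to the ``residual_fit_ms`` of trace
    immediately preceding the stimulus and subtracts its extrapolation from
    the rest of the sweep.  Used to isolate later events of a train on
    current channels, where event kinetics are fast enough for the
    extrapolation to be accurate.  Returns the sweep unchanged if the
    residual is not resolvable.
    """
    config = config or FeatureConfig()
    i0 = sweep.index_at(stim_time - config.residual_fit_ms)
    i1 = sweep.index_at(stim_time)
    if i1 - i0 < 9:
        return sweep
    if center is None:
        center = float(np.median(sweep.samples))
    t = sweep.time()
    y = sweep.samples[i0:i1] - center
    fit = fit_exponential(t[i0:i1], y, n_components=1, with_offset=False)
    if not fit.success or not np.isfinite(fit.taus[0]) or fit.taus[0] <= 0:
        return sweep
    resid = fit(t[i0:] - t[i0])
    corrected = sweep.samples.copy()
    corrected[i0:] -= resid  # leaves ~center + this event from stim_time on
    return sweep.copy_with(corrected)


def _interp_crossing(t: np.ndarray, y: np.ndarray, i: int, level: float) -> float:
    """Linear interpolation of the crossing between samples i-1 and i."""
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t[i])
    return float(t[i - 1] + (level - y0) / (y1 - y0) * (t[i] - t[i - 1]))


@dataclass
class _EventGeometry:
    baseline: float
    noise_sd: float
    polarity: int
    peak_index: int
    peak_time: float
    amplitude: float
    t20: float = NAN
    t80: float = NAN
    onset_time: float = NAN
    rise_time: float = NAN


def _event_geometry(
    sweep: Sweep,
    stim_time: float,
    config: FeatureConfig,
    baseline_anchor: float | None = None,
    next_stim: float | None = None,
    raw_sweep: Sweep | None = None,
) -> _EventGeometry:
    """Baseline, polarity, smoothed peak, chord onset and 20-80% rise."""
    raw = raw_sweep if raw_sweep is not None else sweep
    t = sweep.time()
    y = sweep.samples
    b0, b1 = _baseline_window(
        stim_time if baseline_anchor is None else baseline_anchor, config
    )
    ib0, ib1 = sweep.index_at(b0), sweep.index_at(b1)
    if ib1 <= ib0:
        raise ValueError("baseline window empty; stimulus too close to sweep start")
    baseline = float(np.mean(y[ib0:ib1]))
    noise_sd = float(np.std(raw.samples[ib0:ib1], ddof=1))

    p_end = stim_time + config.peak_window_ms
    if next_stim is not None:
        p_end = min(p_end, next_stim)
    ip0 = sweep.index_at(stim_time) + 1
    ip1 = sweep.index_at(p_end)
    seg = y[ip0 : ip1 + 1] - baseline
    if seg.size < 3:
        raise ValueError("peak window too short")
    imax, imin = int(np.argmax(seg)), int(np.argmin(seg))
    polarity = 1 if seg[imax] >= -seg[imin] else -1

    # peak = maximum of the boxcar-smoothed deflection; smoothing suppresses
    # the upward bias a raw pointwise maximum picks up from noise
    smooth_ms = (
        config.peak_smooth_voltage_ms
        if sweep.channel_role == "postsynaptic_voltage"
        else config.peak_smooth_current_ms
    )
    w = max(int(round(smooth_ms / sweep.dt)), 1)
    zseg = polarity * seg
    smoothed = np.convolve(zseg, np.ones(w) / w, mode="same") if w > 1 else zseg
    ipk_rel = int(np.argmax(smoothed))
    amplitude = float(smoothed[ipk_rel])
    ipk = ip0 + ipk_rel
    geom = _EventGeometry(
        baseline=baseline,
        noise_sd=noise_sd,
        polarity=polarity,
        peak_index=ipk,
        peak_time=float(t[ipk]),
        amplitude=amplitude,
    )

    # rising-phase threshold crossings: scan back from the peak
    z = polarity * (y - baseline)
    peak_val = amplitude
    istim = sweep.index_at(stim_time)

    def last_crossing(level: float) -> float | None:
        val = level * peak_val
        for i in range(ipk, istim, -1):
            if z[i - 1] < val <= z[i]:
                return _interp_crossing(t, z, i, val)
        return None

    t80 = last_crossing(0.8)
    t20 = last_crossing(0.2)
    if t20 is not None and t80 is not None and t80 > t20:
        geom.t20, geom.t80 = t20, t80
        geom.rise_time = t80 - t20
        chord_slope = 0.6 * peak_val / (t80 - t20)
        geom.onset_time = t20 - 0.2 * peak_val / chord_slope
    return geom


def measure_onset(
    sweep: Sweep,
    stim_time: float,
    baseline_window: tuple[float, float] | None = None,
    config: FeatureConfig | None = None,
) -> float:
    """Event onset: 20-80% chord of the rising phase extrapolated to baseline.

    ``baseline_window`` (ms) overrides the default pre-stimulus baseline.
    Returns the onset time in ms within the sweep.
    """
    config = config or FeatureConfig()
    if baseline_window is not None:
        b0, b1 = baseline_window
        if b1 > stim_time:
            raise ValueError("baseline window must precede the stimulus")
        config = replace(config, baseline_ms=stim_time - b0)
    geom = _event_geometry(sweep, stim_time, config)
    if not np.isfinite(geom.onset_time):
        raise ValueError("no resolvable rising phase (possible failure)")
    return geom.onset_time


def event_features(
    sweep: Sweep,
    stim_time: float,
    config: FeatureConfig | None = None,
    prev_stim: float | None = None,
    next_stim: float | None = None,
    train_start: float | None = None,
    slope_end: float | None = None,
    analysis_sweep: Sweep | None = None,
) -> EventFeatures:
    """Full kinetic characterization of the event evoked at ``stim_time``.

    Voltage sweeps are low-pass filtered at 1 kHz before kinetic analysis
    (configurable); failure classification compares the smoothed peak
    amplitude against ``failure_sd_mult`` times the raw baseline noise SD.
    Failures carry NaN kinetic fields.

    For later events of a train (``prev_stim`` given) the baseline is the
    window preceding ``train_start`` (the train's first stimulus).  On
    current channels the decaying tail of preceding events is additionally
    fit and subtracted, so EPSC train amplitudes isolate each release event;
    voltage amplitudes are left summation-inclusive, as in the recorded
    cell.

    ``slope_end`` caps the maximal-slope search window (used to confine the
    measurement to the rising phase *preceding* an overlaid action
    potential).  ``analysis_sweep`` supplies a pre-filtered (and de-spiked)
    copy of the sweep to avoid re-filtering per stimulus.
    """
    config = config or FeatureConfig()
    if analysis_sweep is not None:
        analysis = analysis_sweep
    elif sweep.channel_role == "postsynaptic_voltage" and config.filter_voltage:
        analysis = lowpass_1khz(sweep)
    else:
        analysis = sweep
    anchor = train_start if prev_stim is not None else None
    if prev_stim is not None and sweep.channel_role == "postsynaptic_current":
        analysis = subtract_residual_decay(analysis, stim_time, config)
    geom = _event_geometry(
        analysis, stim_time, config, baseline_anchor=anchor, next_stim=next_stim,
        raw_sweep=sweep,
    )
    feats = EventFeatures(
        stim_time=stim_time,
        baseline=geom.baseline,
        noise_sd=geom.noise_sd,
        polarity=geom.polarity,
    )
    # 1e-9 floor absorbs float rounding on noiseless traces
    if geom.amplitude <= config.failure_sd_mult * geom.noise_sd + 1e-9:
        feats.is_failure = True
        return feats

    feats.peak_amplitude = geom.amplitude
    feats.peak_time = geom.peak_time
    feats.onset_time = geom.onset_time
    feats.latency = geom.onset_time - stim_time
    feats.rise_time_20_80 = geom.rise_time

    # maximal slope of the rising phase, within the analysis window and
    # before any overlaid spike
    slope_cap = min(geom.peak_time, stim_time + config.analysis_window_ms)
    if slope_end is not None:
        slope_cap = min(slope_cap, slope_end)
    slope_end = slope_cap
    if slope_end > stim_time + 2 * analysis.dt:
        z = analysis.copy_with(geom.polarity * analysis.samples)
        try:
            s, st = max_slope(z, (stim_time, slope_end), config.derivative_span_us)
            feats.max_slope = s
            feats.max_slope_time = st
        except ValueError:
            pass

    # monoexponential decay fit from just past the peak to the next stimulus
    # or sweep end; starting two rise times after the peak keeps the residual
    # rising component out of the fitted segment
    end_t = analysis.t0 + (analysis.n_samples - 1) * analysis.dt
    if next_stim is not None:
        end_t = min(end_t, next_stim)
    delay = 2.0 * geom.rise_time if np.isfinite(geom.rise_time) else 0.0
    i0 = analysis.index_at(geom.peak_time + delay)
    i1 = analysis.index_at(end_t)
    if i1 - i0 >= 9:
        tseg = analysis.time()[i0 : i1 + 1]
        yseg = analysis.samples[i0 : i1 + 1]
        fit = fit_exponential(tseg, yseg, n_components=1, with_offset=True)
        feats.fit_ok = fit.success
        feats.fit_message = fit.message
        if fit.success:
            feats.decay_tau = float(fit.taus[0])
            feats.decay_offset = fit.offset
    else:
        feats.fit_ok = False
        feats.fit_message = "decay segment too short for a fit"

    if sweep.channel_role.endswith("current"):
        c_end = stim_time + config.charge_window_ms
        if next_stim is not None:
            c_end = min(c_end, next_stim)
        ic0, ic1 = analysis.index_at(stim_time), analysis.index_at(c_end)
        seg = geom.polarity * (analysis.samples[ic0 : ic1 + 1] - geom.baseline)
        feats.charge = float(np.trapezoid(seg, dx=analysis.dt)) / 1000.0  # pA*ms -> pC
    return feats


def train_charge(
    sweep: Sweep,
    protocol: StimulusProtocol,
    config: FeatureConfig | None = None,
) -> float:
    """Total charge (pC) over the integration window from the first stimulus."""
    config = config or FeatureConfig()
    t0 = protocol.stim_times[0]
    b0, b1 = _baseline_window(t0, config)
    baseline = float(np.mean(sweep.samples[sweep.index_at(b0) : sweep.index_at(b1)]))
    i0 = sweep.index_at(t0)
    i1 = sweep.index_at(t0 + config.charge_window_ms)
    seg = sweep.samples[i0 : i1 + 1] - baseline
    q = float(np.trapezoid(seg, dx=sweep.dt)) / 1000.0
    # report magnitude of the dominant polarity
    return abs(q)


# ---------------------------------------------------------------------------
# Discrete event detection
# ---------------------------------------------------------------------------

def despike(
    sweep: Sweep,
    spike_events: list[SpikeEvent],
    config: FeatureConfig | None = None,
) -> Sweep:
    """Replace detected action potentials by linear interpolation.

    Blanks from shortly before each spike onset to ``spike_blank_ms`` after
    it and bridges the gap linearly, so the underlying EPSP time course can
    be filtered and differentiated without contamination from the spike
    (zero-phase filtering otherwise spreads the spike backward into the
    rising phase).
    """
    config = config or FeatureConfig()
    if not spike_events:
        return sweep
    y = sweep.samples.copy()
    for ev in spike_events:
        i0 = sweep.index_at(ev.spike_time - 0.5)
        i1 = sweep.index_at(ev.spike_time + config.spike_blank_ms)
        if i1 <= i0 + 1:
            continue
        y[i0 : i1 + 1] = np.linspace(y[i0], y[i1], i1 - i0 + 1)
    return sweep.copy_with(y)


def detect_action_currents(
    pre_sweep: Sweep,
    protocol: StimulusProtocol,
    threshold: float | None = None,
    config: FeatureConfig | None = None,
) -> np.ndarray:
    """Per-stimulus success flags for presynaptic action currents.

    A stimulus counts as suprathreshold when the absolute deflection from the
    sweep median exceeds ``threshold`` (pA) within its 0-10 ms window.
    """
    config = config or FeatureConfig()
    if threshold is None:
        threshold = config.action_current_threshold
    if pre_sweep.channel_role != "presynaptic_current":
        raise ValueError("expected a presynaptic_current sweep")
    center = float(np.median(pre_sweep.samples))
    flags = np.zeros(protocol.n_stimuli, dtype=bool)
    for i, s in enumerate(protocol.stim_times):
        i0 = pre_sweep.index_at(s) + 1
        i1 = pre_sweep.index_at(s + config.analysis_window_ms)
        seg = np.abs(pre_sweep.samples[i0 : i1 + 1] - center)
        flags[i] = bool(seg.size and seg.max() > threshold)
    return flags


def detect_spikes(
    post_sweep: Sweep,
    protocol: StimulusProtocol,
    config: FeatureConfig | None = None,
) -> tuple[list[SpikeEvent], np.ndarray]:
    """Detect action potentials and attribute them to stimuli.

    A spike onset is the first sample where dV/dt exceeds the slope criterion
    (default 20 mV/ms) sustained for ``spike_sustain_ms``, computed on a
    lightly smoothed trace; a refractory period suppresses re-triggering.
    Spikes are attributed to the stimulus whose 0-10 ms window contains the
    onset; unattributable threshold crossings are ignored.

    Returns (spike events, per-stimulus boolean flags).
    """
    config = config or FeatureConfig()
    if post_sweep.channel_role != "postsynaptic_voltage":
        raise ValueError("expected a postsynaptic_voltage sweep")
    y = post_sweep.samples
    w = max(int(round(config.spike_smooth_ms / post_sweep.dt)), 1)
    if w > 1:
        kernel = np.ones(w) / w
        y = np.convolve(y, kernel, mode="same")
    d = _derivative(y, post_sweep.dt, config.derivative_span_us)
    above = np.nan_to_num(d, nan=-np.inf) > config.spike_slope_threshold
    sustain = max(int(round(config.spike_sustain_ms / post_sweep.dt)), 1)
    if sustain > 1:
        ok = np.convolve(above.astype(int), np.ones(sustain, dtype=int), mode="valid")
        starts_all = np.flatnonzero(ok == sustain)
    else:
        starts_all = np.flatnonzero(above)
    # collapse runs into onsets separated by the refractory period
    events: list[SpikeEvent] = []
    flags = np.zeros(protocol.n_stimuli, dtype=bool)
    refr = config.spike_refractory_ms
    last = -np.inf
    t0 = post_sweep.t0
    dt = post_sweep.dt
    for idx in starts_all:
        t_on = t0 + idx * dt
        if t_on - last < refr:
            continue
        last = t_on
        for i, s in enumerate(protocol.stim_times):
            if s < t_on <= s + config.analysis_window_ms:
                events.append(
                    SpikeEvent(spike_time=t_on, stimulus_index=i, latency_to_onset=t_on - s)
                )
                flags[i] = True
                break
    return events, flags


# ---------------------------------------------------------------------------
# Recording-level extraction
# ---------------------------------------------------------------------------

def extract_recording_features(
    rec: PairedRecording,
    config: FeatureConfig | None = None,
    skip_hfs: bool = True,
) -> pd.DataFrame:
    """Tidy per-(trial, stimulus, channel) feature table for a recording.

    HFS (tetanus) trials are skipped by default: their 100-pulse trains are
    induction, not measurement.  Voltage rows carry spike flags/times;
    presynaptic rows carry action-current flags; current rows carry charge.
    """
    config = config or FeatureConfig()
    rows: list[dict] = []
    for k, trial in enumerate(rec.trials):
        proto = trial.protocol
        if proto.is_hfs and skip_hfs:
            continue
        stims = proto.stim_times
        for role, sweep in trial.channels.items():
            if role == "presynaptic_current":
                flags = detect_action_currents(sweep, proto, config=config)
                for i, s in enumerate(stims):
                    rows.append(
                        {
                            "trial_index": k,
                            "acquisition_time_s": trial.acquisition_time,
                            "channel_role": role,
                            "stim_index": i,
                            "stim_time_ms": s,
                            "action_current": bool(flags[i]),
                        }
                    )
                continue
            spike_events: list[SpikeEvent] = []
            spike_flags = np.zeros(len(stims), dtype=bool)
            analysis_sweep = None
            if role == "postsynaptic_voltage":
                spike_events, spike_flags = detect_spikes(sweep, proto, config)
                clean = despike(sweep, spike_events, config)
                if config.filter_voltage:
                    analysis_sweep = lowpass_1khz(clean)
                else:
                    analysis_sweep = clean
            spike_times = {e.stimulus_index: e.latency_to_onset for e in spike_events}
            for i, s in enumerate(stims):
                prev_s = stims[i - 1] if i > 0 else None
                next_s = stims[i + 1] if i + 1 < len(stims) else None
                slope_end = None
                if i in spike_times:
                    # measure the EPSP slope strictly before the spike onset
                    slope_end = s + spike_times[i] - 0.3
                feats = event_features(
                    sweep, s, config, prev_stim=prev_s, next_stim=next_s,
                    train_start=stims[0], slope_end=slope_end,
                    analysis_sweep=analysis_sweep,
                )
                row = {
                    "trial_index": k,
                    "acquisition_time_s": trial.acquisition_time,
                    "channel_role": role,
                    "stim_index": i,
                    **feats.to_dict(),
                }
                if role == "postsynaptic_voltage":
                    row["spike"] = bool(spike_flags[i])
                    row["spike_latency_ms"] = spike_times.get(i, np.nan)
                rows.append(row)
    return pd.DataFrame(rows)
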