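"""Facilitation, post-tetanic potentiation, and detonation quantification.

This module turns per-trial kinetic features into the plasticity measures of
a paired-recording experiment:

* train facilitation, as per-stimulus EPSC amplitude ratios normalized to
  the first event of the train;
* the PTP time course, as the per-trial maximal slope of the first EPSP
  normalized to the pre-tetanus baseline mean, with its peak, the mean over
  the standard 22-122 s post-tetanus window, and a monoexponential decay fit
  constrained to return to baseline;
* detonation, as per-stimulus spike probabilities (exact counts) compared
  between the control period and the PTP window, with the decay of the
  first-stimulus spike probability fit the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trace_io import PairedRecording
from .trace_features import FeatureConfig, extract_recording_features

__all__ = [
    "FacilitationResult",
    "PtpResult",
    "DetonationResult",
    "SpikeProbabilityCurve",
    "SummaryStats",
    "InsufficientDataError",
    "facilitation_ratios",
    "spike_probability",
    "ptp_time_course",
    "detonation_time_course",
    "summary_stats",
    "analyze_ptp_experiment",
]

#: Standard post-tetanus quantification window, seconds after HFS end.
PTP_WINDOW_S = (22.0, 122.0)


class InsufficientDataError(ValueError):
    """Not enough trials for the requested quantification."""


@dataclass
class FacilitationResult:
    """Per-stimulus train amplitudes and their normalized ratios."""

    mean_amplitude: np.ndarray       # pA, per stimulus index
    sem_amplitude: np.ndarray
    ratios: np.ndarray               # mean_i / mean_1; ratios[0] == 1
    ratio_sem: np.ndarray            # SEM of per-trial ratios (NaN for n=1)
    n_sweeps: int


@dataclass
class SpikeProbabilityCurve:
    """Per-stimulus-index spike probability for a set of trials."""

    probabilities: np.ndarray
    n_trials: int
    period: str = "control"


@dataclass
class PtpResult:
    """Normalized EPSP1 maximal-slope time course around the tetanus."""

    times_since_hfs_s: np.ndarray    # post-tetanus trials
    normalized: np.ndarray           # slope / baseline mean, post-tetanus
    baseline_times_s: np.ndarray     # relative to HFS end (negative)
    baseline_normalized: np.ndarray
    baseline_mean_slope: float
    peak_percent: float              # 100 * max normalized value after HFS
    window_mean_percent: float       # mean over the closed PTP window
    window_s: tuple[float, float] = PTP_WINDOW_S
    decay_tau_s: float = float("nan")
    decay_amplitude: float = float("nan")
    fit_ok: bool = False
    fit_message: str = ""


@dataclass
class DetonationResult:
    """First-stimulus spike probability time course around the tetanus."""

    times_since_hfs_s: np.ndarray
    probabilities: np.ndarray        # per trial (or per bin)
    baseline_probability: float
    window_probability: float
    window_s: tuple[float, float] = PTP_WINDOW_S
    decay_tau_s: float = float("nan")
    decay_amplitude: float = float("nan")
    fit_ok: bool = False
    fit_message: str = ""


@dataclass
class SummaryStats:
    mean: float
    sem: float
    n: int
    p_value: float = float("nan")
    t_statistic: float = float("nan")


def facilitation_ratios(amplitudes: np.ndarray | pd.DataFrame) -> FacilitationResult:
    """Facilitation from a (trials x stimuli) amplitude table.

    Ratios are computed from the per-stimulus means, normalized to the first
    stimulus; the SEM of per-trial ratios is reported alongside.  Trials with
    a failure on the first stimulus contribute to means but not to per-trial
    ratios.
    """
    a = np.asarray(amplitudes, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.shape[0] < 1 or a.shape[1] < 2:
        raise ValueError("need >= 1 trial and >= 2 stimuli")
    def _sem(x: np.ndarray) -> np.ndarray:
        n = np.sum(np.isfinite(x), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(x, axis=0, ddof=1)
        return np.where(n >= 2, sd / np.sqrt(np.maximum(n, 1)), np.nan)

    mean = np.nanmean(a, axis=0)
    sem = _sem(a)
    if not np.isfinite(mean[0]) or mean[0] == 0:
        raise ZeroDivisionError("mean amplitude of the first stimulus is zero")
    ratios = mean / mean[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        per_trial = a / a[:, [0]]
    ratio_sem = _sem(per_trial)
    return FacilitationResult(
        mean_amplitude=mean,
        sem_amplitude=sem,
        ratios=ratios,
        ratio_sem=ratio_sem,
        n_sweeps=a.shape[0],
    )


def spike_probability(
    spike_matrix: np.ndarray,
    period_mask: np.ndarray | None = None,
    period: str = "control",
) -> SpikeProbabilityCurve:
    """Exact per-stimulus spike probability over (masked) trials.

    ``spike_matrix`` is a (trials x stimuli) boolean array; ``period_mask``
    selects the trials belonging to the period.
    """
    m = np.asarray(spike_matrix, dtype=bool)
    if m.ndim == 1:
        m = m[None, :]
    if m.size == 0:
        raise ValueError("spike matrix is empty")
    if period_mask is not None:
        mask = np.asarray(period_mask, dtype=bool)
        m = m[mask]
    if m.shape[0] == 0:
        raise InsufficientDataError(f"no trials in period {period!r}")
    return SpikeProbabilityCurve(
        probabilities=m.mean(axis=0),
        n_trials=m.shape[0],
        period=period,
    )


def _fit_plateau_decay(
    t: np.ndarray,
    y: np.ndarray,
    offset: float,
    t_origin: float,
) -> tuple[float, float, bool, str]:
    """Fit ``y = offset + A * exp(-max(t - t_origin, 0)/tau)``.

    The offset is fixed (return to baseline); the decay clock starts at
    ``t_origin`` so that trials recorded during the initial fully potentiated
    plateau are fit exactly.  Returns (tau, A, ok, message).
    """
    z = y - offset
    if np.allclose(z, 0.0, atol=1e-12):
        return float("nan"), 0.0, False, "degenerate: series at baseline"
    if np.ptp(z) <= 1e-12 * max(1.0, np.abs(z).max()):
        return float("nan"), float(z.mean()), False, "degenerate: constant series"

    a0 = float(z[0])
    pos = z / (a0 if a0 != 0 else 1.0)
    decay_t = np.maximum(t - t_origin, 0.0)
    usable = pos > 1e-3
    if usable.sum() >= 2 and np.ptp(decay_t[usable]) > 0:
        slope = np.polyfit(decay_t[usable], np.log(pos[usable]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else float(np.ptp(t) or 1.0)
    else:
        tau0 = float(np.ptp(t) or 1.0)

    def model(x, a, tau):
        return offset + a * np.exp(-np.maximum(x - t_origin, 0.0) / tau)

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[a0, max(tau0, 1e-3)],
            bounds=([-np.inf, 1e-9], [np.inf, np.inf]), maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return float("nan"), float("nan"), False, f"fit failed: {exc}"
    return float(popt[1]), float(popt[0]), True, ""


def ptp_time_course(
    trial_times_s: np.ndarray,
    slopes: np.ndarray,
    hfs_end_s: float,
    window: tuple[float, float] = PTP_WINDOW_S,
) -> PtpResult:
    """PTP quantification from per-trial EPSP1 maximal slopes.

    ``trial_times_s`` are acquisition times (s); trials before ``hfs_end_s``
    form the baseline.  Each slope is normalized to the baseline mean; the
    peak is the maximum post-tetanus normalized value, the window mean is
    taken over the closed interval ``window`` (s after the tetanus), and the
    decay is fit with a baseline-anchored exponential whose clock starts at
    the window onset.  Percentages are 100 x normalized value.
    """
    t = np.asarray(trial_times_s, dtype=float)
    y = np.asarray(slopes, dtype=float)
    pre = t < hfs_end_s
    post = ~pre
    if not pre.any():
        raise InsufficientDataError("no baseline trials before the tetanus")
    baseline_mean = float(np.nanmean(y[pre]))
    if not np.isfinite(baseline_mean) or baseline_mean == 0:
        raise InsufficientDataError("baseline slopes unusable")
    norm = y / baseline_mean
    t_post = t[post] - hfs_end_s
    n_post = norm[post]
    ok = np.isfinite(n_post)
    t_post, n_post = t_post[ok], n_post[ok]
    in_window = (t_post >= window[0]) & (t_post <= window[1])
    if in_window.sum() < 3:
        raise InsufficientDataError(
            f"fewer than 3 post-tetanus trials inside the {window} s window"
        )
    tau, amp, fit_ok, msg = _fit_plateau_decay(t_post, n_post, 1.0, window[0])
    return PtpResult(
        times_since_hfs_s=t_post,
        normalized=n_post,
        baseline_times_s=t[pre] - hfs_end_s,
        baseline_normalized=norm[pre],
        baseline_mean_slope=baseline_mean,
        peak_percent=100.0 * float(np.max(n_post)),
        window_mean_percent=100.0 * float(np.mean(n_post[in_window])),
        window_s=window,
        decay_tau_s=tau,
        decay_amplitude=amp,
        fit_ok=fit_ok,
        fit_message=msg,
    )


def detonation_time_course(
    trial_times_s: np.ndarray,
    spikes_first: np.ndarray,
    hfs_end_s: float,
    window: tuple[float, float] = PTP_WINDOW_S,
    bin_s: float | None = None,
) -> DetonationResult:
    """First-stimulus spike-probability time course around the tetanus.

    ``spikes_first`` holds one boolean per trial (spike on stimulus 1).  The
    post-tetanus series is optionally binned (``bin_s``); the decay toward
    the baseline probability is fit with the same baseline-anchored
    exponential used for the PTP slope series.  An all-zero post-tetanus
    series skips the fit with a status message.
    """
    t = np.asarray(trial_times_s, dtype=float)
    s = np.asarray(spikes_first, dtype=float)
    pre = t < hfs_end_s
    post = ~pre
    if not pre.any() or not post.any():
        raise InsufficientDataError("need trials on both sides of the tetanus")
    p_base = float(s[pre].mean())
    t_post = t[post] - hfs_end_s
    p_post = s[post]
    if bin_s is not None:
        edges = np.arange(t_post.min(), t_post.max() + bin_s, bin_s)
        idx = np.clip(np.digitize(t_post, edges) - 1, 0, len(edges) - 2)
        t_b, p_b = [], []
        for b in np.unique(idx):
            sel = idx == b
            t_b.append(t_post[sel].mean())
            p_b.append(p_post[sel].mean())
        t_post, p_post = np.asarray(t_b), np.asarray(p_b)
    in_window = (t_post >= window[0]) & (t_post <= window[1])
    p_window = float(p_post[in_window].mean()) if in_window.any() else float("nan")
    if np.all(p_post == 0.0):
        tau, amp, fit_ok, msg = float("nan"), 0.0, False, "skipped: no post-tetanus spikes"
    else:
        tau, amp, fit_ok, msg = _fit_plateau_decay(t_post, p_post, p_base, window[0])
    return DetonationResult(
        times_since_hfs_s=t_post,
        probabilities=p_post,
        baseline_probability=p_base,
        window_probability=p_window,
        window_s=window,
        decay_tau_s=tau,
        decay_amplitude=amp,
        fit_ok=fit_ok,
        fit_message=msg,
    )


def summary_stats(values: np.ndarray, paired_with: np.ndarray | None = None) -> SummaryStats:
    """Mean, SEM, and (optionally) a paired two-sided t-test.

    With ``paired_with`` given, the test compares ``values`` against the
    paired sample; identical pairs (zero variance of differences) report
    p = 1 by convention (t = 0).
    """
    a = np.asarray(values, dtype=float)
    if a.size < 2:
        raise ValueError("need n >= 2 for the SEM")
    out = SummaryStats(
        mean=float(a.mean()),
        sem=float(a.std(ddof=1) / np.sqrt(a.size)),
        n=a.size,
    )
    if paired_with is not None:
        b = np.asarray(paired_with, dtype=float)
        if b.size != a.size:
            raise ValueError("paired samples must have equal length")
        diff = a - b
        if np.allclose(diff, 0.0):
            out.t_statistic, out.p_value = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(a, b)
            out.t_statistic, out.p_value = float(t), float(p)
    return out


# ---------------------------------------------------------------------------
# End-to-end experiment analysis
# ---------------------------------------------------------------------------

@dataclass
class PtpExperimentReport:
    """Bundle of plasticity measures for one PTP-induction experiment."""

    ptp: PtpResult
    detonation: DetonationResult
    control_spikes: SpikeProbabilityCurve
    window_spikes: SpikeProbabilityCurve
    facilitation: FacilitationResult | None = None
    features: pd.DataFrame = field(default_factory=pd.DataFrame)


def _spike_matrix(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(trial times, trial indices, trials x stimuli spike matrix) from the
    voltage rows of a feature table."""
    v = features[features.channel_role == "postsynaptic_voltage"]
    if v.empty:
        raise InsufficientDataError("no postsynaptic_voltage features")
    pivot = v.pivot_table(index="trial_index", columns="stim_index",
                          values="spike", aggfunc="first")
    times = v.groupby("trial_index")["acquisition_time_s"].first()
    order = pivot.index.to_numpy()
    return times.loc[order].to_numpy(), order, pivot.to_numpy().astype(bool)


def analyze_ptp_experiment(
    rec: PairedRecording,
    config: FeatureConfig | None = None,
    window: tuple[float, float] = PTP_WINDOW_S,
    features: pd.DataFrame | None = None,
) -> PtpExperimentReport:
    """Full plasticity quantification of a PTP-induction recording.

    Extracts per-trial features (unless supplied), locates the tetanus trial,
    builds the normalized EPSP1 maximal-slope time course, the detonation
    time course, and control-vs-PTP-window spike-probability curves.
    """
    config = config or FeatureConfig()
    hfs_idx = rec.hfs_trial_index()
    if hfs_idx is None:
        raise InsufficientDataError("recording contains no HFS trial")
    hfs_trial = rec[hfs_idx]
    hfs_end_s = hfs_trial.acquisition_time + hfs_trial.protocol.stim_times[-1] / 1000.0
    if features is None:
        features = extract_recording_features(rec, config)

    v1 = features[
        (features.channel_role == "postsynaptic_voltage") & (features.stim_index == 0)
    ]
    if v1.empty:
        raise InsufficientDataError("no first-stimulus EPSP features")
    trial_t = v1["acquisition_time_s"].to_numpy()
    slopes = v1["max_slope"].to_numpy()
    ptp = ptp_time_course(trial_t, slopes, hfs_end_s, window)

    times, _, spikes = _spike_matrix(features)
    det = detonation_time_course(times, spikes[:, 0], hfs_end_s, window)
    t_rel = times - hfs_end_s
    control = spike_probability(spikes, times < hfs_end_s, period="control")
    in_win = (t_rel >= window[0]) & (t_rel <= window[1])
    window_curve = spike_probability(spikes, in_win, period="post-HFS")

    facil = None
    cur = features[features.channel_role == "postsynaptic_current"]
    if not cur.empty and cur.stim_index.max() >= 1:
        pre_cur = cur[cur.acquisition_time_s < hfs_end_s]
        src = pre_cur if not pre_cur.empty else cur
        pivot = src.pivot_table(index="trial_index", columns="stim_index",
                                values="amplitude", aggfunc="first")
        facil = facilitation_ratios(pivot.to_numpy())

    return PtpExperimentReport(
        ptp=ptp,
        detonation=det,
        control_spikes=control,
        window_spikes=window_curve,
        facilitation=facil,
        features=features,
    )
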