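"""Data model and I/O for sweep-organized paired intracellular recordings.

A paired recording couples a presynaptic channel (tight-seal bouton-attached
stimulation; action currents in pA) with a postsynaptic channel (whole-cell
voltage in mV or current in pA) on a common stimulus protocol.  Everything is
kept in canonical units internally: time in ms, voltage in mV, current in pA.

Supported on-disk formats:

* ``hdf5`` (canonical): one group per trial (``/trial_<k>``) with one float64
  dataset per channel role and the protocol stored as group attributes.
* ``csv_dir``: a directory of ``trial_<k>_<role>.csv`` files (columns
  ``time_ms,value``) plus a ``protocol.json`` sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "CHANNEL_ROLES",
    "Sweep",
    "StimulusProtocol",
    "Trial",
    "PairedRecording",
    "SchemaError",
    "UnsupportedFormatError",
    "read_recording",
    "write_recording",
]

#: Recognized channel roles.  Presynaptic current carries the action currents
#: of the stimulated bouton; postsynaptic voltage/current carry EPSPs/EPSCs.
CHANNEL_ROLES = ("presynaptic_current", "postsynaptic_voltage", "postsynaptic_current")

#: Default sampling interval, ms (50 kHz acquisition).
DEFAULT_DT_MS = 0.02


class SchemaError(ValueError):
    """A file does not match the expected recording schema."""


class UnsupportedFormatError(ValueError):
    """Requested I/O format is not supported."""


@dataclass
class Sweep:
    """One uniformly sampled trace.

    Parameters
    ----------
    samples
        Sample values, mV for voltage channels and pA for current channels.
    dt
        Sampling interval in ms (default 0.02 ms, i.e. 50 kHz).
    t0
        Time of the first sample relative to sweep start, ms.
    channel_role
        One of :data:`CHANNEL_ROLES`.
    sweep_index
        Trial index within the recording.
    acquisition_time
        Seconds since the start of the experiment.
    """

    samples: np.ndarray
    dt: float = DEFAULT_DT_MS
    t0: float = 0.0
    channel_role: str = "postsynaptic_voltage"
    sweep_index: int = 0
    acquisition_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(
                f"channel_role must be one of {CHANNEL_ROLES}, got {self.channel_role!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Sweep duration in ms."""
        return self.n_samples * self.dt

    def time(self) -> np.ndarray:
        """Time base in ms, relative to sweep start."""
        return self.t0 + np.arange(self.n_samples) * self.dt

    def index_at(self, t_ms: float) -> int:
        """Nearest sample index for a time in ms (clipped to valid range)."""
        i = int(round((t_ms - self.t0) / self.dt))
        return min(max(i, 0), self.n_samples - 1)

    def copy_with(self, samples: np.ndarray) -> "Sweep":
        return Sweep(
            samples=np.asarray(samples, dtype=float),
            dt=self.dt,
            t0=self.t0,
            channel_role=self.channel_role,
            sweep_index=self.sweep_index,
            acquisition_time=self.acquisition_time,
        )


@dataclass
class StimulusProtocol:
    """Stimulus timing for one trial.

    ``stim_times`` are ms offsets within the sweep; a train of ``n_stimuli``
    at ``frequency`` Hz has consecutive spacing 1000/frequency ms.  ``is_hfs``
    marks the tetanus used for PTP induction (100 stimuli at 100 Hz).
    """

    stim_times: np.ndarray
    pulse_duration: float = 0.1
    frequency: float | None = None
    repetition_interval: float = 20.0
    is_hfs: bool = False

    def __post_init__(self) -> None:
        self.stim_times = np.atleast_1d(np.asarray(self.stim_times, dtype=float))
        if self.stim_times.size == 0:
            raise ValueError("protocol must contain at least one stimulus")
        if np.any(np.diff(self.stim_times) <= 0):
            raise ValueError("stim_times must be strictly increasing")
        if not (0 < self.pulse_duration <= 1.0):
            raise ValueError("pulse_duration must be in (0, 1] ms")
        if self.frequency is not None and self.n_stimuli > 1:
            expected = 1000.0 / self.frequency
            if not np.allclose(np.diff(self.stim_times), expected, rtol=1e-6):
                raise ValueError(
                    f"stim spacing inconsistent with frequency {self.frequency} Hz"
                )
        if self.is_hfs and not (self.n_stimuli == 100 and self.frequency == 100.0):
            raise ValueError("is_hfs requires 100 stimuli at 100 Hz")

    @property
    def n_stimuli(self) -> int:
        return self.stim_times.size

    @classmethod
    def train(
        cls,
        n_stimuli: int,
        frequency: float | None = None,
        start: float = 20.0,
        pulse_duration: float = 0.1,
        repetition_interval: float = 20.0,
        is_hfs: bool = False,
    ) -> "StimulusProtocol":
        """Build a regular train starting at ``start`` ms."""
        if n_stimuli > 1 and frequency is None:
            raise ValueError("frequency required for trains with more than one stimulus")
        spacing = 0.0 if frequency is None else 1000.0 / frequency
        times = start + spacing * np.arange(n_stimuli)
        return cls(
            stim_times=times,
            pulse_duration=pulse_duration,
            frequency=frequency,
            repetition_interval=repetition_interval,
            is_hfs=is_hfs,
        )

    @classmethod
    def hfs(cls, start: float = 20.0, pulse_duration: float = 0.1) -> "StimulusProtocol":
        """The PTP-inducing tetanus: 100 stimuli at 100 Hz."""
        return cls.train(100, 100.0, start=start, pulse_duration=pulse_duration, is_hfs=True)

    def to_dict(self) -> dict:
        return {
            "stim_times_ms": self.stim_times.tolist(),
            "pulse_duration_ms": self.pulse_duration,
            "frequency_hz": self.frequency,
            "repetition_interval_s": self.repetition_interval,
            "is_hfs": bool(self.is_hfs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            stim_times=np.asarray(d["stim_times_ms"], dtype=float),
            pulse_duration=float(d.get("pulse_duration_ms", 0.1)),
            frequency=None if d.get("frequency_hz") is None else float(d["frequency_hz"]),
            repetition_interval=float(d.get("repetition_interval_s", 20.0)),
            is_hfs=bool(d.get("is_hfs", False)),
        )


@dataclass
class Trial:
    """One trial: channel sweeps keyed by role, with its protocol."""

    channels: dict[str, Sweep]
    protocol: StimulusProtocol
    acquisition_time: float = 0.0

    def __post_init__(self) -> None:
        if not any(r.startswith("postsynaptic") for r in self.channels):
            raise SchemaError("every trial needs at least one postsynaptic channel")
        for role in self.channels:
            if role not in CHANNEL_ROLES:
                raise SchemaError(f"unknown channel role {role!r}")

    def __getitem__(self, role: str) -> Sweep:
        return self.channels[role]

    def __contains__(self, role: str) -> bool:
        return role in self.channels


@dataclass
class PairedRecording:
    """An ordered collection of trials from one paired recording."""

    trials: list[Trial]
    holding_potential: float = -70.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [t.acquisition_time for t in self.trials]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("acquisition_time must be nondecreasing across trials")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i: int) -> Trial:
        return self.trials[i]

    def hfs_trial_index(self) -> int | None:
        """Index of the (first) HFS trial, or None."""
        for i, t in enumerate(self.trials):
            if t.protocol.is_hfs:
                return i
        return None


# ---------------------------------------------------------------------------
# HDF5 backend
# ---------------------------------------------------------------------------

def _write_hdf5(rec: PairedRecording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["holding_potential_mV"] = rec.holding_potential
        f.attrs["metadata_json"] = json.dumps(rec.metadata)
        f.attrs["n_trials"] = rec.n_trials
        for k, trial in enumerate(rec.trials):
            g = f.create_group(f"trial_{k:04d}")
            p = trial.protocol
            g.attrs["stim_times_ms"] = p.stim_times
            g.attrs["pulse_duration_ms"] = p.pulse_duration
            g.attrs["frequency_hz"] = np.nan if p.frequency is None else p.frequency
            g.attrs["repetition_interval_s"] = p.repetition_interval
            g.attrs["is_hfs"] = bool(p.is_hfs)
            g.attrs["acquisition_time_s"] = trial.acquisition_time
            for role, sw in trial.channels.items():
                ds = g.create_dataset(role, data=sw.samples, dtype="float64")
                ds.attrs["dt_ms"] = sw.dt
                ds.attrs["t0_ms"] = sw.t0


def _read_hdf5(path: Path) -> PairedRecording:
    trials: list[Trial] = []
    with h5py.File(path, "r") as f:
        names = sorted(n for n in f if n.startswith("trial_"))
        if not names:
            raise SchemaError(f"{path}: no trial_<k> groups found")
        for k, name in enumerate(names):
            g = f[name]
            freq = float(g.attrs["frequency_hz"])
            protocol = StimulusProtocol(
                stim_times=np.asarray(g.attrs["stim_times_ms"], dtype=float),
                pulse_duration=float(g.attrs["pulse_duration_ms"]),
                frequency=None if np.isnan(freq) else freq,
                repetition_interval=float(g.attrs["repetition_interval_s"]),
                is_hfs=bool(g.attrs["is_hfs"]),
            )
            acq = float(g.attrs["acquisition_time_s"])
            channels = {}
            for role in g:
                if role not in CHANNEL_ROLES:
                    raise SchemaError(f"{path}:{name}: unknown channel role {role!r}")
                ds = g[role]
                channels[role] = Sweep(
                    samples=np.asarray(ds[()], dtype=float),
                    dt=float(ds.attrs["dt_ms"]),
                    t0=float(ds.attrs.get("t0_ms", 0.0)),
                    channel_role=role,
                    sweep_index=k,
                    acquisition_time=acq,
                )
            trials.append(Trial(channels=channels, protocol=protocol, acquisition_time=acq))
        holding = float(f.attrs.get("holding_potential_mV", -70.0))
        metadata = json.loads(f.attrs.get("metadata_json", "{}"))
    return PairedRecording(trials=trials, holding_potential=holding, metadata=metadata)


# ---------------------------------------------------------------------------
# CSV-directory backend
# ---------------------------------------------------------------------------

def _write_csv_dir(rec: PairedRecording, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "holding_potential_mV": rec.holding_potential,
        "metadata": rec.metadata,
        "trials": [
            {**t.protocol.to_dict(), "acquisition_time_s": t.acquisition_time}
            for t in rec.trials
        ],
    }
    (path / "protocol.json").write_text(json.dumps(sidecar, indent=1))
    for k, trial in enumerate(rec.trials):
        for role, sw in trial.channels.items():
            out = path / f"trial_{k:04d}_{role}.csv"
            data = np.column_stack([sw.time(), sw.samples])
            np.savetxt(out, data, delimiter=",", header="time_ms,value",
                       comments="", fmt="%.17g")


def _read_csv_dir(path: Path) -> PairedRecording:
    sidecar_path = path / "protocol.json"
    if not sidecar_path.exists():
        raise SchemaError(f"{path}: missing protocol.json sidecar")
    sidecar = json.loads(sidecar_path.read_text())
    trials: list[Trial] = []
    for k, tmeta in enumerate(sidecar["trials"]):
        protocol = StimulusProtocol.from_dict(tmeta)
        acq = float(tmeta.get("acquisition_time_s", 0.0))
        channels = {}
        for role in CHANNEL_ROLES:
            f = path / f"trial_{k:04d}_{role}.csv"
            if not f.exists():
                continue
            data = np.loadtxt(f, delimiter=",", skiprows=1, ndmin=2)
            t, v = data[:, 0], data[:, 1]
            dt = float((t[-1] - t[0]) / (t.size - 1))
            if not np.allclose(np.diff(t), dt, rtol=1e-6, atol=1e-9):
                raise UnsupportedFormatError(f"{f}: non-uniform sampling")
            channels[role] = Sweep(
                samples=v, dt=dt, t0=float(t[0]), channel_role=role,
                sweep_index=k, acquisition_time=acq,
            )
        if not channels:
            raise SchemaError(f"{path}: no channel files for trial {k}")
        trials.append(Trial(channels=channels, protocol=protocol, acquisition_time=acq))
    return PairedRecording(
        trials=trials,
        holding_potential=float(sidecar.get("holding_potential_mV", -70.0)),
        metadata=sidecar.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, format: str = "hdf5") -> PairedRecording:
    """Read a paired recording from disk.

    Parameters
    ----------
    path
        File (hdf5) or directory (csv_dir) to read.
    format
        ``"hdf5"`` or ``"csv_dir"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "hdf5":
        return _read_hdf5(path)
    if format == "csv_dir":
        return _read_csv_dir(path)
    raise UnsupportedFormatError(f"unsupported format {format!r}")


def write_recording(rec: PairedRecording, path: str | Path, format: str = "hdf5") -> Path:
    """Write a paired recording; round-trips losslessly with read_recording."""
    path = Path(path)
    if format == "hdf5":
        _write_hdf5(rec, path)
    elif format == "csv_dir":
        _write_csv_dir(rec, path)
    else:
        raise UnsupportedFormatError(f"unsupported format {format!r}")
    return path
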