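"""Protocol-driven synthetic sEMG session generator.

Emulates the acquisition protocol: a session of randomized task cues, each a
5 s contraction followed by 10 s rest, three task classes (1 = wrist flexion,
2 = fist, 3 = wrist extension), three EMG channels sampled at 1 kHz plus six
near-constant inertial channels.

Burst model
-----------
Each EMG channel carries a band-limited (default 50-150 Hz) Gaussian-noise
carrier, amplitude-modulated by a per-event trapezoidal gain profile (linear
onset/offset ramps) and scaled by a per-(task, channel) gain matrix.  Class 1
is dominant on channel 1 (flexor side), class 3 on channel 3 (extensor side),
and class 2's gain row is a tunable mixture of the two — the
``class2_overlap`` dial reproduces the fist task's confusability with the
wrist tasks.  Signal units are arbitrary sensor-amplified units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from myogrip.dataio import Recording, write_recording

__all__ = [
    "ProtocolConfig",
    "GeneratorConfig",
    "EventSchedule",
    "build_schedule",
    "synthesize_recording",
    "generate_dataset",
]

DEFAULT_GAIN_MATRIX = np.array(
    [
        [1.00, 0.25, 0.05],  # class 1: wrist flexion, flexor channel dominant
        [0.25, 1.00, 0.25],  # class 2: fist, mid channel dominant (pre-overlap)
        [0.05, 0.25, 1.00],  # class 3: wrist extension, extensor channel dominant
    ]
)

DEFAULT_IMU_OFFSETS = np.array([0.02, -0.01, 1.0, 0.0, 0.0, 0.0])


@dataclass(frozen=True)
class ProtocolConfig:
    """Cue-protocol constants of one acquisition session."""

    sampling_rate: float = 1000.0
    task_duration: float = 5.0
    rest_duration: float = 10.0
    repetitions_per_task: int = 10
    task_classes: tuple[int, ...] = (1, 2, 3)
    cue_order: str = "random"  # "random" | "fixed"

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.task_duration <= 0:
            raise ValueError("task_duration must be positive")
        if self.rest_duration < 0:
            raise ValueError("rest_duration must be non-negative")
        if self.repetitions_per_task < 1:
            raise ValueError("repetitions_per_task must be >= 1")
        if not self.task_classes or len(set(self.task_classes)) != len(self.task_classes):
            raise ValueError("task_classes must be non-empty with distinct ids")
        if self.cue_order not in ("random", "fixed"):
            raise ValueError("cue_order must be 'random' or 'fixed'")


@dataclass(frozen=True)
class GeneratorConfig:
    """Signal-synthesis knobs, independent of the cue protocol."""

    n_emg_channels: int = 3
    n_imu_channels: int = 6
    band: tuple[float, float] = (50.0, 150.0)
    baseline_noise_sd: float = 0.05
    burst_gain_matrix: np.ndarray | None = None
    class2_overlap: float = 0.5
    onset_ramp: float = 1.0
    amplitude_jitter: float = 0.25
    imu_noise_sd: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_emg_channels < 1 or self.n_imu_channels < 0:
            raise ValueError("channel counts invalid")
        if not (0.0 <= self.class2_overlap <= 1.0):
            raise ValueError("class2_overlap must lie in [0, 1]")
        if self.baseline_noise_sd < 0:
            raise ValueError("baseline_noise_sd must be non-negative")
        if self.onset_ramp < 0:
            raise ValueError("onset_ramp must be non-negative")
        if self.amplitude_jitter < 0:
            raise ValueError("amplitude_jitter must be non-negative")
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ValueError(f"band must satisfy 0 < low < high, got {self.band}")
        if self.burst_gain_matrix is not None:
            m = np.asarray(self.burst_gain_matrix, dtype=float)
            if np.any(m < 0):
                raise ValueError("burst_gain_matrix entries must be >= 0")
            object.__setattr__(self, "burst_gain_matrix", m)

    def base_gain_matrix(self, task_classes: tuple[int, ...]) -> np.ndarray:
        """Per-(task, channel) gain rows before any overlap mixing."""
        if self.burst_gain_matrix is not None:
            base = np.asarray(self.burst_gain_matrix, dtype=float)
        else:
            if len(task_classes) == 3 and self.n_emg_channels == 3:
                base = DEFAULT_GAIN_MATRIX.copy()
            else:
                # generic fallback: each class dominant on one cyclic channel
                base = np.full((len(task_classes), self.n_emg_channels), 0.2)
                for i in range(len(task_classes)):
                    base[i, i % self.n_emg_channels] = 1.0
        if base.shape != (len(task_classes), self.n_emg_channels):
            raise ValueError(
                f"gain matrix shape {base.shape} != "
                f"({len(task_classes)}, {self.n_emg_channels})"
            )
        return base

    def effective_gain_matrix(self, task_classes: tuple[int, ...]) -> np.ndarray:
        """Expected gain rows per task class, with the class-2 overlap applied.

        With ``class2_overlap = w`` and classes {1, 2, 3} present, class 2's
        expected row is ``(1 - w) * base_row2 + w * 0.5 * (row1 + row3)``: at
        ``w = 0`` the three rows are distinct, at ``w = 1`` class 2 is an
        even mixture of the wrist-flexion and wrist-extension patterns.

        During synthesis each class-2 event leans toward flexion or extension
        by a per-event random amount (see ``synthesize_recording``); this
        matrix is the event-average pattern.
        """
        base = self.base_gain_matrix(task_classes)
        gains = base.copy()
        if self.class2_overlap > 0 and {1, 2, 3} <= set(task_classes):
            i1 = task_classes.index(1)
            i2 = task_classes.index(2)
            i3 = task_classes.index(3)
            w = self.class2_overlap
            gains[i2] = (1 - w) * base[i2] + w * 0.5 * (base[i1] + base[i3])
        return gains


@dataclass(frozen=True)
class EventSchedule:
    """Time-sorted, non-overlapping list of (class id, onset s, offset s)."""

    events: tuple[tuple[int, float, float], ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for cls, onset, offset in self.events:
            if offset <= onset:
                raise ValueError("event offset must exceed onset")
            if onset < prev_end - 1e-9:
                raise ValueError("events must be non-overlapping and time-sorted")
            prev_end = offset

    def __len__(self) -> int:
        return len(self.events)

    @property
    def classes(self) -> tuple[int, ...]:
        return tuple(sorted({cls for cls, _, _ in self.events}))

    def total_cued_time(self) -> float:
        return sum(offset - onset for _, onset, offset in self.events)

    def end_time(self) -> float:
        return self.events[-1][2] if self.events else 0.0


def build_schedule(protocol: ProtocolConfig, seed: int = 0) -> EventSchedule:
    """Lay out one session's cue sequence on the time axis.

    Every class appears ``repetitions_per_task`` times; each cue occupies
    ``task_duration`` seconds and is followed by ``rest_duration`` seconds of
    rest.  With ``cue_order="random"`` the interleaving is a seeded shuffle;
    with ``"fixed"`` cues run in class-id order.
    """
    cues = [cls for cls in protocol.task_classes for _ in range(protocol.repetitions_per_task)]
    if protocol.cue_order == "random":
        rng = np.random.default_rng(seed)
        rng.shuffle(cues)
    else:
        cues.sort()
    period = protocol.task_duration + protocol.rest_duration
    events = tuple(
        (cls, i * period, i * period + protocol.task_duration) for i, cls in enumerate(cues)
    )
    return EventSchedule(events=events)


def _band_carrier(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float],
                  n_channels: int) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise, one independent column per channel."""
    lo, hi = band
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    white = rng.standard_normal((n, n_channels))
    carrier = sps.sosfilt(sos, white, axis=0)
    rms = np.sqrt(np.mean(carrier**2, axis=0))
    rms[rms == 0] = 1.0
    return carrier / rms


def _event_gain_rows(
    schedule: EventSchedule,
    protocol: ProtocolConfig,
    gen: GeneratorConfig,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """One gain row per event, with the stochastic class-2 overlap applied.

    At overlap ``w`` each class-2 event uses
    ``(1 - w) * base_row2 + w * (u * row1 + (1 - u) * row3)`` with a per-event
    ``u ~ Uniform(0, 1)``: extreme draws make the fist pattern resemble a
    wrist-flexion or wrist-extension event, which is what produces the
    class-2 confusion structure downstream.  The event-average row equals
    ``effective_gain_matrix``'s class-2 row.
    """
    classes = protocol.task_classes
    base = gen.base_gain_matrix(classes)
    by_class = {cls: base[i] for i, cls in enumerate(classes)}
    mix = gen.class2_overlap > 0 and {1, 2, 3} <= set(classes)
    rows = []
    for cls, _, _ in schedule.events:
        if mix and cls == 2:
            u = rng.uniform()
            w = gen.class2_overlap
            row = (1 - w) * by_class[2] + w * (u * by_class[1] + (1 - u) * by_class[3])
        else:
            row = by_class[cls]
        if gen.amplitude_jitter > 0:
            # per-event, per-channel contraction-strength variability
            row = row * rng.lognormal(0.0, gen.amplitude_jitter, size=row.shape)
        rows.append(row)
    return rows


def _gain_profile(schedule: EventSchedule, event_rows: list[np.ndarray],
                  fs: float, n_samples: int, ramp_s: float, n_channels: int) -> np.ndarray:
    """Per-sample, per-channel burst amplitude: trapezoid per event times gain row."""
    profile = np.zeros((n_samples, n_channels))
    for (cls, onset, offset), row in zip(schedule.events, event_rows):
        i0 = int(round(onset * fs))
        i1 = min(int(round(offset * fs)), n_samples)
        if i1 <= i0:
            continue
        dur = i1 - i0
        ramp = min(int(round(ramp_s * fs)), dur // 2)
        shape = np.ones(dur)
        if ramp > 0:
            shape[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
            shape[dur - ramp :] = np.linspace(1.0, 0.0, ramp + 1)[1:]
        profile[i0:i1] = shape[:, None] * row[None, :]
    return profile


def synthesize_recording(
    schedule: EventSchedule,
    protocol: ProtocolConfig,
    gen: GeneratorConfig,
    trial_id: str = "session",
    label: int | None = None,
    tail: float | None = None,
) -> Recording:
    """Render a schedule into a reproducible multichannel recording.

    EMG channels carry band-limited bursts during events (scaled by the
    effective gain matrix) on top of baseline white noise; IMU channels are a
    constant offset plus small white noise.  Fully deterministic given
    (schedule, protocol, gen).

    ``tail`` seconds of rest are appended after the last event (defaults to
    the protocol rest duration).
    """
    fs = protocol.sampling_rate
    lo, hi = gen.band
    if hi >= fs / 2:
        raise ValueError(
            f"band upper edge {hi} Hz violates the Nyquist limit {fs / 2} Hz at fs={fs}"
        )
    tail = protocol.rest_duration if tail is None else tail
    n_samples = int(round((schedule.end_time() + tail) * fs))
    if n_samples <= 0:
        raise ValueError("schedule renders to an empty recording")
    rng = np.random.default_rng(gen.seed)

    event_rows = _event_gain_rows(schedule, protocol, gen, rng)
    carrier = _band_carrier(rng, n_samples, fs, gen.band, gen.n_emg_channels)
    profile = _gain_profile(schedule, event_rows, fs, n_samples, gen.onset_ramp,
                            gen.n_emg_channels)
    emg = carrier * profile + gen.baseline_noise_sd * rng.standard_normal(
        (n_samples, gen.n_emg_channels)
    )

    offsets = DEFAULT_IMU_OFFSETS[: gen.n_imu_channels]
    if len(offsets) < gen.n_imu_channels:
        offsets = np.resize(DEFAULT_IMU_OFFSETS, gen.n_imu_channels)
    imu = offsets[None, :] + gen.imu_noise_sd * rng.standard_normal(
        (n_samples, gen.n_imu_channels)
    )
    return Recording(emg=emg, imu=imu, sampling_rate=fs, label=label, trial_id=trial_id)


def single_task_recording(
    cls: int, protocol: ProtocolConfig, gen: GeneratorConfig, trial_id: str
) -> Recording:
    """One labeled task burst (onset at t=0, no rest padding) — the per-file unit."""
    schedule = EventSchedule(events=((cls, 0.0, protocol.task_duration),))
    return synthesize_recording(schedule, protocol, gen, trial_id=trial_id, label=cls, tail=0.0)


def generate_dataset(
    protocol: ProtocolConfig,
    gen: GeneratorConfig,
    n_trials_per_task: int,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write a balanced dataset of single-task CSV files plus a manifest.

    Produces ``n_trials_per_task * len(task_classes)`` files named
    ``class<k>_t<nn>.csv``, each holding one labeled task window, and a
    ``manifest.csv`` listing (file, class, seed).  Per-file seeds are derived
    deterministically from ``gen.seed``.
    """
    if n_trials_per_task < 1:
        raise ValueError("n_trials_per_task must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    idx = 0
    for trial in range(n_trials_per_task):
        for cls in protocol.task_classes:
            file_seed = int(gen.seed) * 1_000_003 + idx
            rec = single_task_recording(
                cls, protocol, replace(gen, seed=file_seed), trial_id=f"t{trial:02d}"
            )
            path = write_recording(rec, out_dir)
            rows.append({"file": path.name, "class": cls, "seed": file_seed})
            idx += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
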