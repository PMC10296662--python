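"""Recording I/O in the dataset CSV layout and window segmentation.

A recording file is a comma-separated table with one row per sample and nine
columns for the default sensor set: three EMG channels (``emg1..emg3``)
followed by six inertial channels (``acc1..acc3``, ``gyr1..gyr3``).  The
class label is carried in the filename as ``class<k>_<trial_id>.csv``; files
without the prefix are unlabeled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "AnalysisWindow",
    "write_recording",
    "read_recording",
    "segment",
    "emg_column_names",
    "imu_column_names",
]

_FILENAME_RE = re.compile(r"^class(\d+)_(.+)$")


def emg_column_names(n: int) -> list[str]:
    return [f"emg{i + 1}" for i in range(n)]


def imu_column_names(n: int) -> list[str]:
    """Inertial column names: accelerometer axes first, then gyroscope axes."""
    half = n // 2
    names = [f"acc{i + 1}" for i in range(half)]
    names += [f"gyr{i + 1}" for i in range(n - half)]
    return names


@dataclass
class Recording:
    """A multichannel timed signal with an optional task label.

    Attributes
    ----------
    emg
        ``(samples, n_emg)`` array of EMG channels.
    imu
        ``(samples, n_imu)`` array of inertial channels.
    sampling_rate
        Sample rate in Hz, shared by all channels.
    label
        Task class id, or ``None`` for unlabeled / multi-task recordings.
    trial_id
        Short identifier used in the output filename.
    """

    emg: np.ndarray
    imu: np.ndarray
    sampling_rate: float
    label: int | None = None
    trial_id: str = "t00"

    def __post_init__(self) -> None:
        self.emg = np.atleast_2d(np.asarray(self.emg, dtype=float))
        self.imu = np.atleast_2d(np.asarray(self.imu, dtype=float))
        if self.emg.shape[0] != self.imu.shape[0]:
            raise ValueError(
                f"emg and imu row counts differ: {self.emg.shape[0]} vs {self.imu.shape[0]}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def filename(self) -> str:
        if self.label is None:
            return f"{self.trial_id}.csv"
        return f"class{self.label}_{self.trial_id}.csv"


@dataclass
class AnalysisWindow:
    """Fixed-duration EMG slice on which one classification decision is made."""

    samples: np.ndarray
    sampling_rate: float
    duration: float
    label: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        expected = int(round(self.duration * self.sampling_rate))
        if self.samples.shape[0] != expected:
            raise ValueError(
                f"window has {self.samples.shape[0]} samples, "
                f"expected round({self.duration} * {self.sampling_rate}) = {expected}"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as CSV; returns the written file path.

    ``path`` may be a directory (the canonical ``class<k>_<trial>.csv``
    filename is appended) or a full file path.
    """
    path = Path(path)
    if path.is_dir():
        path = path / rec.filename()
    n_emg = rec.emg.shape[1]
    n_imu = rec.imu.shape[1]
    df = pd.DataFrame(
        np.hstack([rec.emg, rec.imu]),
        columns=emg_column_names(n_emg) + imu_column_names(n_imu),
    )
    # %.17g guarantees exact float64 round-trips through the text format
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def _label_from_filename(path: Path) -> tuple[int | None, str]:
    m = _FILENAME_RE.match(path.stem)
    if m:
        return int(m.group(1)), m.group(2)
    return None, path.stem


def read_recording(
    path: str | Path,
    sampling_rate: float = 1000.0,
    n_emg: int = 3,
    header: bool | str = "auto",
) -> Recording:
    """Read a CSV recording; the label is recovered from the filename.

    Parameters
    ----------
    header
        ``True``/``False`` to force a header row, or ``"auto"`` to sniff: a
        first line with any non-numeric token is treated as a header.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    if header == "auto":
        with open(path) as fh:
            first = fh.readline()
        header = _looks_like_header(first)
    try:
        df = pd.read_csv(path, header=0 if header else None, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    if df.isna().any().any():
        bad = int(np.where(df.isna().any(axis=1))[0][0])
        raise ValueError(f"{path}: ragged or missing values near data row {bad + 1}")
    values = df.to_numpy(dtype=float)
    if values.shape[1] < n_emg:
        raise ValueError(f"{path}: expected at least {n_emg} EMG columns, found {values.shape[1]}")
    label, trial_id = _label_from_filename(path)
    return Recording(
        emg=values[:, :n_emg],
        imu=values[:, n_emg:],
        sampling_rate=sampling_rate,
        label=label,
        trial_id=trial_id,
    )


def _looks_like_header(line: str) -> bool:
    for tok in line.strip().split(","):
        try:
            float(tok)
        except ValueError:
            return True
    return False


def segment(rec: Recording, schedule, window_duration: float) -> list[AnalysisWindow]:
    """Cut one onset-anchored analysis window per scheduled event.

    Each window starts at the event onset, lasts ``window_duration`` seconds,
    carries the event's class label, and contains EMG channels only.
    """
    if window_duration <= 0:
        raise ValueError("window_duration must be positive")
    fs = rec.sampling_rate
    n = int(round(window_duration * fs))
    windows: list[AnalysisWindow] = []
    for i, (cls, onset, offset) in enumerate(schedule.events):
        if window_duration > (offset - onset) + 1e-9:
            raise ValueError(
                f"event {i} (class {cls} at {onset:.3f}s): window of {window_duration}s "
                f"exceeds event duration {offset - onset:.3f}s"
            )
        start = int(round(onset * fs))
        if start + n > rec.n_samples:
            raise ValueError(
                f"event {i} (class {cls} at {onset:.3f}s): window extends past recording end"
            )
        windows.append(
            AnalysisWindow(
                samples=rec.emg[start : start + n],
                sampling_rate=fs,
                duration=window_duration,
                label=cls,
            )
        )
    return windows
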