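"""Signal conditioning: Nyquist sizing, RMS-envelope smoothing, peak normalization.

The conditioning chain reduces a raw multichannel EMG analysis window to a
smooth, range-bounded representation:

1. ``rms_envelope`` — root-mean-square over consecutive, non-overlapping
   fixed-length blocks (default 50 ms), which decimates and denoises the
   signal while preserving its activation profile.
2. ``peak_normalize`` — per-channel division by the channel's envelope peak
   over the whole analysis window, bounding every value to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from myogrip.dataio import AnalysisWindow

__all__ = [
    "Envelope",
    "NormalizedEnvelope",
    "nyquist_min_rate",
    "rms_envelope",
    "peak_normalize",
]


@dataclass(frozen=True)
class Envelope:
    """Blockwise RMS-smoothed signal.

    Attributes
    ----------
    values
        ``(env_samples, n_channels)`` array of non-negative envelope values.
    envelope_rate
        Effective sampling rate of the envelope in Hz (source rate / block size).
    source_window_ms
        Duration of the smoothing block in milliseconds.
    """

    values: np.ndarray
    envelope_rate: float
    source_window_ms: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("envelope values must be a 2-D (samples x channels) array")
        if np.any(v < 0):
            raise ValueError("envelope values must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class NormalizedEnvelope:
    """Envelope scaled per channel into [0, 1] by its own peak."""

    values: np.ndarray
    peak_per_channel: np.ndarray
    envelope_rate: float
    source_window_ms: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size and (v.min() < 0 or v.max() > 1 + 1e-12):
            raise ValueError("normalized envelope values must lie in [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "peak_per_channel", np.asarray(self.peak_per_channel, dtype=float))

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def nyquist_min_rate(fmax: float) -> float:
    """Minimum sampling rate (Hz) that can represent content up to ``fmax`` Hz.

    >>> nyquist_min_rate(150)
    300.0
    """
    if fmax <= 0:
        raise ValueError(f"fmax must be positive, got {fmax}")
    return 2.0 * float(fmax)


def _block_size(window_ms: float, sampling_rate: float) -> int:
    return int(round(window_ms * sampling_rate / 1000.0))


def rms_envelope(win: AnalysisWindow, window_ms: float = 50.0, hop_ms: float | None = None) -> Envelope:
    """Smooth a window by per-block RMS.

    Each channel is cut into consecutive blocks of ``window_ms`` (advanced by
    ``hop_ms``, which defaults to the block length, i.e. non-overlapping
    blocks) and each block is reduced to ``sqrt(mean(x**2))``.  A trailing
    remainder shorter than one block is dropped.

    Parameters
    ----------
    win
        Analysis window holding raw EMG samples.
    window_ms
        Block duration in milliseconds; must convert to at least one sample.
    hop_ms
        Advance between block starts; defaults to ``window_ms``.
    """
    x = win.samples
    fs = win.sampling_rate
    n = _block_size(window_ms, fs)
    if n < 1:
        raise ValueError(f"window_ms={window_ms} is shorter than one sample at {fs} Hz")
    if n > x.shape[0]:
        raise ValueError(
            f"envelope block of {n} samples exceeds the analysis window of {x.shape[0]} samples"
        )
    hop = n if hop_ms is None else _block_size(hop_ms, fs)
    if hop < 1:
        raise ValueError("hop_ms must convert to at least one sample")
    starts = np.arange(0, x.shape[0] - n + 1, hop)
    # non-overlapping default: a strided reshape would do, but gather keeps hop generic
    blocks = x[starts[:, None] + np.arange(n)[None, :], :]
    values = np.sqrt(np.mean(blocks.astype(float) ** 2, axis=1))
    return Envelope(values=values, envelope_rate=fs / hop, source_window_ms=float(window_ms))


def peak_normalize(env: Envelope, block_samples: int | None = None) -> NormalizedEnvelope:
    """Divide each channel by its peak so values lie in [0, 1].

    The peak is taken over the channel's entire envelope (the full analysis
    window).  Channels whose peak is zero map to all zeros rather than
    raising, so rest-only windows remain processable.

    ``block_samples`` enables an alternative per-block normalization (each
    consecutive run of that many envelope samples scaled by its own peak) for
    sensitivity checks; it is not the default pipeline behaviour.
    """
    v = env.values
    if v.shape[0] == 0:
        raise ValueError("cannot normalize an empty envelope")
    if block_samples is None:
        peak = v.max(axis=0)
        out = np.divide(v, peak, out=np.zeros_like(v), where=peak > 0)
    else:
        if block_samples < 1:
            raise ValueError("block_samples must be >= 1")
        out = np.zeros_like(v)
        for start in range(0, v.shape[0], block_samples):
            blk = v[start : start + block_samples]
            bpeak = blk.max(axis=0)
            out[start : start + block_samples] = np.divide(
                blk, bpeak, out=np.zeros_like(blk), where=bpeak > 0
            )
        peak = v.max(axis=0)
    # guard against >1 from floating division
    np.clip(out, 0.0, 1.0, out=out)
    return NormalizedEnvelope(
        values=out,
        peak_per_channel=peak,
        envelope_rate=env.envelope_rate,
        source_window_ms=env.source_window_ms,
    )
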