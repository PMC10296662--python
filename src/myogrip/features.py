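"""Time-domain feature extraction from normalized envelopes.

Two candidate feature families are implemented:

* ``rms_features`` — RMS over consecutive non-overlapping subwindows
  (default 500 ms), yielding four values per channel for the default 2 s
  analysis window.
* ``statistical_features`` — six per-channel statistics: mean absolute value
  (MAV), two weighted MAV variants, median absolute value, variance, and
  standard deviation.

MAV1 weights samples 1 inside the central 25-75 % of the window and 0.5
elsewhere.  MAV2 replaces the 0.5 plateau with continuous linear ramps,
4n/N rising before the central band and 4(N-n)/N falling after it (1-based
sample index n).  Variance and standard deviation use the population
denominator N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from myogrip.dataio import AnalysisWindow
from myogrip.preprocess import NormalizedEnvelope, peak_normalize, rms_envelope

__all__ = [
    "FeatureVector",
    "rms_features",
    "statistical_features",
    "extract",
    "STAT_FEATURE_NAMES",
]

STAT_FEATURE_NAMES = ("mav", "mav1", "mav2", "medav", "var", "sd")


@dataclass(frozen=True)
class FeatureVector:
    """Ordered real-valued features for one analysis window.

    ``values`` is laid out channel-major: all features of channel 1, then
    channel 2, and so on.  ``layout`` is ``"rms"`` or ``"statistical"``.
    """

    values: np.ndarray
    layout: str
    n_channels: int
    n_per_channel: int
    label: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size != self.n_channels * self.n_per_channel:
            raise ValueError(
                f"feature length {v.size} != {self.n_channels} x {self.n_per_channel}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("features must be finite")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


def rms_features(nenv: NormalizedEnvelope, subwindow_ms: float = 500.0) -> FeatureVector:
    """RMS of consecutive non-overlapping envelope subwindows, channel-major."""
    v = nenv.values
    n_sub = int(round(subwindow_ms / 1000.0 * nenv.envelope_rate))
    if n_sub < 1:
        raise ValueError(
            f"subwindow of {subwindow_ms} ms is shorter than one envelope sample "
            f"at {nenv.envelope_rate} Hz"
        )
    n_blocks = v.shape[0] // n_sub
    if n_blocks < 1:
        raise ValueError("subwindow longer than the analysis window")
    blocks = v[: n_blocks * n_sub].reshape(n_blocks, n_sub, v.shape[1])
    feats = np.sqrt(np.mean(blocks**2, axis=1))  # (n_blocks, n_channels)
    return FeatureVector(
        values=feats.T.ravel(),
        layout="rms",
        n_channels=v.shape[1],
        n_per_channel=n_blocks,
    )


def _mav_weights(n: int, kind: str) -> np.ndarray:
    # 1-based index; central band is 0.25N <= i <= 0.75N
    i = np.arange(1, n + 1, dtype=float)
    central = (i >= 0.25 * n) & (i <= 0.75 * n)
    if kind == "mav1":
        return np.where(central, 1.0, 0.5)
    w = np.ones(n)
    w[i < 0.25 * n] = 4.0 * i[i < 0.25 * n] / n
    w[i > 0.75 * n] = 4.0 * (n - i[i > 0.75 * n]) / n
    return w


def statistical_features(nenv: NormalizedEnvelope | np.ndarray) -> FeatureVector:
    """Six statistics per channel in the fixed order MAV, MAV1, MAV2, MedAV, VAR, SD.

    Accepts a normalized envelope (the pipeline input) or any plain
    (samples, channels) array — the statistics are defined for arbitrary
    real signals.
    """
    v = nenv.values if isinstance(nenv, NormalizedEnvelope) else np.atleast_2d(
        np.asarray(nenv, dtype=float).reshape(-1, 1)
        if np.asarray(nenv).ndim == 1 else np.asarray(nenv, dtype=float)
    )
    if v.shape[0] == 0:
        raise ValueError("cannot featurize an empty envelope")
    n = v.shape[0]
    absv = np.abs(v)
    w1 = _mav_weights(n, "mav1")[:, None]
    w2 = _mav_weights(n, "mav2")[:, None]
    feats = np.stack(
        [
            absv.mean(axis=0),
            (w1 * absv).mean(axis=0),
            (w2 * absv).mean(axis=0),
            np.median(absv, axis=0),
            v.var(axis=0),
            v.std(axis=0),
        ],
        axis=1,
    )  # (n_channels, 6)
    return FeatureVector(
        values=feats.ravel(),
        layout="statistical",
        n_channels=v.shape[1],
        n_per_channel=len(STAT_FEATURE_NAMES),
    )


def extract(
    win: AnalysisWindow,
    method: str = "rms",
    envelope_ms: float = 50.0,
    subwindow_ms: float = 500.0,
) -> FeatureVector:
    """Full conditioning-plus-features chain for one window.

    Composition: RMS envelope -> peak normalization -> chosen feature family.
    The window's label propagates to the feature vector.
    """
    if method not in ("rms", "statistical"):
        raise ValueError(f"unknown feature method {method!r}")
    nenv = peak_normalize(rms_envelope(win, window_ms=envelope_ms))
    if method == "rms":
        fv = rms_features(nenv, subwindow_ms=subwindow_ms)
    else:
        fv = statistical_features(nenv)
    return FeatureVector(
        values=fv.values,
        layout=fv.layout,
        n_channels=fv.n_channels,
        n_per_channel=fv.n_per_channel,
        label=win.label,
    )
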