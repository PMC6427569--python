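"""Deterministic signal transforms: jerk, jerk magnitude, rolling moments.

The transforms turn a 3-axis acceleration trace into a single motion-energy
channel. Per-axis jerk is the first difference of consecutive samples (no
division by the sample period), which cancels any constant orientation or
gravity offset; the resultant jerk magnitude collapses the three axes into
one non-negative series. A short rolling variance (1.5 s) accentuates
contraction bursts, and a rolling mean over roughly one contraction
duration (8 s) smooths it.

All rolling windows are trailing (causal): an output sample at time ``t``
summarises the ``w`` input samples ending at ``t``. Outputs are shorter
than inputs — no edge padding, because padded edges would create spurious
variance spikes for the peak detector.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .io import AccelerometerTrace


@dataclass
class ScalarSeries:
    """A single-channel series sharing the time base of its source trace."""

    t0: float
    fs: float
    values: np.ndarray
    kind: str  # jerk_magnitude | variance | smoothed_variance | jvb

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) < 1:
            raise ValidationError("empty series")
        if self.fs <= 0:
            raise ValidationError("sampling frequency must be positive")
        if self.kind in ("jerk_magnitude", "variance") and np.any(self.values < 0):
            raise ValidationError(f"{self.kind} values must be non-negative")

    def __len__(self):
        return len(self.values)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.times(), "value": self.values})


@dataclass
class JerkSeries:
    """Per-axis jerk in acceleration units per sample; length n-1."""

    t0: float
    fs: float
    jx: np.ndarray
    jy: np.ndarray
    jz: np.ndarray

    def __post_init__(self):
        self.jx = np.asarray(self.jx, dtype=float)
        self.jy = np.asarray(self.jy, dtype=float)
        self.jz = np.asarray(self.jz, dtype=float)
        if not (len(self.jx) == len(self.jy) == len(self.jz)):
            raise ValidationError("jerk axes must have equal length")

    def __len__(self):
        return len(self.jx)


def differentiate(trace: AccelerometerTrace) -> JerkSeries:
    """Per-axis jerk: first difference of consecutive acceleration samples.

    The difference is *not* divided by the sample period; the constant
    factor is immaterial because every downstream threshold is learned on
    the same scale. Output has length ``n - 1`` and starts one sample
    period after the trace.
    """
    if trace.n < 2:
        raise InsufficientDataError("jerk needs at least 2 samples")
    return JerkSeries(
        t0=trace.t0 + 1.0 / trace.fs,
        fs=trace.fs,
        jx=np.diff(trace.x),
        jy=np.diff(trace.y),
        jz=np.diff(trace.z),
    )


def magnitude(jerk: JerkSeries) -> ScalarSeries:
    """Resultant 3-D jerk magnitude sqrt(jx^2 + jy^2 + jz^2)."""
    vals = np.sqrt(jerk.jx**2 + jerk.jy**2 + jerk.jz**2)
    return ScalarSeries(t0=jerk.t0, fs=jerk.fs, values=vals, kind="jerk_magnitude")


def window_samples(window_s: float, fs: float) -> int:
    """Window length in samples: round(window_s * fs)."""
    w = int(round(window_s * fs))
    if w < 2:
        raise ValidationError(f"window of {window_s} s is under 2 samples at {fs} Hz")
    return w


def _check_length(series: ScalarSeries, w: int) -> None:
    if len(series) < w:
        raise InsufficientDataError(
            f"series of length {len(series)} is shorter than the {w}-sample window"
        )


def _rolled(series: ScalarSeries, w: int, rolled_values: np.ndarray, kind: str) -> ScalarSeries:
    # trailing window: output timestamp is the right edge
    return replace(
        series,
        t0=series.t0 + (w - 1) / series.fs,
        values=rolled_values[w - 1 :],
        kind=kind,
    )


def rolling_variance(series: ScalarSeries, window_s: float = 1.5) -> ScalarSeries:
    """Trailing rolling population variance (denominator ``w``).

    Default window 1.5 s — short enough to resolve the high-variability
    contraction bursts against the quiescent chewing pauses.
    """
    w = window_samples(window_s, series.fs)
    _check_length(series, w)
    v = pd.Series(series.values).rolling(w).var(ddof=0).to_numpy()
    # rounding can leave tiny negative residue on near-constant windows
    v = np.maximum(v, 0.0)
    return _rolled(series, w, v, "variance")


def rolling_mean(series: ScalarSeries, window_s: float = 8.0) -> ScalarSeries:
    """Trailing rolling mean; default 8 s, about one contraction duration."""
    w = window_samples(window_s, series.fs)
    _check_length(series, w)
    m = pd.Series(series.values).rolling(w).mean().to_numpy()
    return _rolled(series, w, m, "smoothed_variance")


def rolling_median(series: ScalarSeries, window_s: float, kind: str) -> ScalarSeries:
    """Trailing rolling median (shared backend for the motion-energy baseline)."""
    w = window_samples(window_s, series.fs)
    _check_length(series, w)
    m = pd.Series(series.values).rolling(w).median().to_numpy()
    return _rolled(series, w, m, kind)
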