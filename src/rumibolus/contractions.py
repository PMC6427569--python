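"""Contraction-peak detection, prominence thresholding and interval features.

Reticuloruminal contractions appear as peaks in the smoothed jerk-variance
signal. A zero-derivative detector finds every local maximum; minor
inflexion points are then discarded by topographic prominence — the height
of a peak above the lowest contour line separating it from higher terrain,
with the series ends treated as infinitely low ground. The prominence cut
is chosen at the knee of the peak-count-versus-threshold curve, so it
adapts to the (arbitrary) amplitude scale of each dataset.

Two features are derived: the Inter-Contraction Interval (ICI), the time
between successive retained peaks (about 40-60 s during rumination), and
the Jerk Variance Baseline (JVB), a 40 s rolling median of the smoothed
variance — roughly one inter-contraction period, so single contraction
bursts cannot lift it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InsufficientDataError, NoElbowError, ValidationError
from .kinematics import ScalarSeries, rolling_median


@dataclass
class PeakSet:
    """Detected peaks with their prominences and the threshold applied."""

    times: np.ndarray  # seconds, strictly increasing
    indices: np.ndarray  # sample indices into the source series
    heights: np.ndarray
    prominences: np.ndarray
    threshold: float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.indices = np.asarray(self.indices, dtype=int)
        self.heights = np.asarray(self.heights, dtype=float)
        self.prominences = np.asarray(self.prominences, dtype=float)
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValidationError("peak times must be strictly increasing")
        if np.any(self.prominences <= 0):
            raise ValidationError("prominences must be positive")
        if self.threshold > 0 and np.any(self.prominences < self.threshold):
            raise ValidationError("retained prominence below threshold")

    def __len__(self):
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "height": self.heights, "prominence": self.prominences}
        )


@dataclass
class SensitivityCurve:
    """Surviving peak count as a function of the prominence threshold."""

    thresholds: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValidationError("thresholds must be strictly increasing")
        if np.any(np.diff(self.counts) > 0):
            raise ValidationError("counts must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "count": self.counts})


@dataclass
class ICISeries:
    """Successive peak-time differences; timestamped at the later peak."""

    times: np.ndarray
    intervals_s: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intervals_s = np.asarray(self.intervals_s, dtype=float)
        if np.any(self.intervals_s <= 0):
            raise ValidationError("intervals must be positive")

    def __len__(self):
        return len(self.intervals_s)


def detect_peaks(series: ScalarSeries) -> PeakSet:
    """All local maxima of the series, each with its topographic prominence.

    A sample is a peak when it is strictly greater than both neighbours; a
    flat-topped maximum is reported once, at the plateau midpoint (left
    sample of the middle pair on even widths) — one event per contraction.
    No threshold is applied (``threshold = 0``).
    """
    if len(series) < 3:
        raise InsufficientDataError("peak detection needs at least 3 samples")
    idx, _ = sps.find_peaks(series.values)
    prom = sps.peak_prominences(series.values, idx)[0]
    t = series.t0 + idx / series.fs
    return PeakSet(times=t, indices=idx, heights=series.values[idx], prominences=prom)


def prominence_of(series: ScalarSeries, peak_index: int) -> float:
    """Topographic prominence of the local maximum at ``peak_index``.

    Raises :class:`ValidationError` when the index is not a detected local
    maximum (plateau maxima are addressed by their midpoint index).
    """
    peaks = detect_peaks(series)
    hit = np.flatnonzero(peaks.indices == peak_index)
    if not len(hit):
        raise ValidationError(f"index {peak_index} is not a local maximum")
    return float(peaks.prominences[hit[0]])


def sensitivity_curve(series: ScalarSeries, grid=None) -> SensitivityCurve:
    """Peak count surviving each candidate prominence threshold.

    With ``grid=None`` the sorted distinct prominence values of the detected
    peaks are used, which yields the exact curve with no binning.
    """
    peaks = detect_peaks(series)
    if grid is None:
        grid = np.unique(peaks.prominences)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("threshold grid is empty")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValidationError("grid must be strictly increasing and positive")
    prom_sorted = np.sort(peaks.prominences)
    counts = len(prom_sorted) - np.searchsorted(prom_sorted, grid, side="left")
    return SensitivityCurve(thresholds=grid, counts=counts)


def select_threshold(curve: SensitivityCurve) -> float:
    """Prominence threshold at the knee of the decreasing count curve.

    Kneedle-style with sensitivity 1 and no smoothing (the curve is already
    monotone): both axes are normalised to [0, 1], the difference between
    the chord joining the endpoints and the curve is formed, and the
    threshold maximising that difference is returned. Ties go to the
    smallest threshold, retaining more peaks. A constant or perfectly
    linear curve has no knee and raises :class:`NoElbowError`.
    """
    x = curve.thresholds
    y = curve.counts
    if len(x) < 3:
        raise NoElbowError("need at least 3 curve points")
    if y[0] == y[-1]:
        raise NoElbowError("count curve is constant")
    xn = (x - x[0]) / (x[-1] - x[0])
    yn = (y - y[-1]) / (y[0] - y[-1])  # decreasing: 1 at x[0], 0 at x[-1]
    diff = (1.0 - xn) - yn  # chord minus curve
    best = float(np.max(diff))
    if best <= 1e-12:
        raise NoElbowError("count curve is linear (or concave): no knee")
    return float(x[np.argmax(diff)])  # argmax takes the first (smallest) tie


def apply_threshold(peaks: PeakSet, threshold: float) -> PeakSet:
    """Retain exactly the peaks with prominence >= threshold."""
    keep = peaks.prominences >= threshold
    return replace(
        peaks,
        times=peaks.times[keep],
        indices=peaks.indices[keep],
        heights=peaks.heights[keep],
        prominences=peaks.prominences[keep],
        threshold=float(threshold),
    )


def inter_contraction_intervals(peaks: PeakSet) -> ICISeries:
    """Time differences between successive peaks; empty for < 2 peaks."""
    if len(peaks) < 2:
        return ICISeries(times=np.empty(0), intervals_s=np.empty(0))
    return ICISeries(times=peaks.times[1:], intervals_s=np.diff(peaks.times))


def jerk_variance_baseline(series: ScalarSeries, window_s: float = 40.0) -> ScalarSeries:
    """Jerk Variance Baseline: trailing rolling median of smoothed variance.

    The default 40 s window spans approximately one inter-contraction
    period, so the median sits on the quiescent floor between contractions:
    low during rumination, high during feeding and other active behaviour.
    """
    return rolling_median(series, window_s, kind="jvb")
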