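"""Reading, validation and writing of bolus traces and collar label tracks.

Traces are comma-delimited text with header ``timestamp,x,y,z``, one sample
per row; label tracks use header ``start,end,class`` with class tokens
``rumination``, ``feeding`` or ``other``. Timestamps may be ISO-8601 strings
or plain seconds; internally all times are float seconds on a common epoch,
because every filter window downstream is specified in seconds.

The readers enforce the uniform-sampling contract the rolling filters
assume: a gap is an error (or, in permissive mode, a segment boundary) and
is never silently interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import GapError, ParseError, ValidationError

#: behaviour classes a collar can report
LABEL_CLASSES = ("rumination", "feeding", "other")

#: nominal collar reporting period in seconds
COLLAR_PERIOD_S = 90.0


@dataclass
class AccelerometerTrace:
    """Uniformly sampled 3-axis acceleration.

    Implied sample timestamps are ``t0 + k / fs`` for ``k = 0 .. n-1``.
    Acceleration units are opaque metadata: the pipeline is scale-covariant
    up to the learned decision boundary, so no unit conversion is applied.
    """

    t0: float
    fs: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    unit: str = "arbitrary"

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValidationError("x, y, z must have equal length")
        if len(self.x) < 2:
            raise ValidationError("trace needs at least 2 samples")
        if self.fs <= 0:
            raise ValidationError("sampling frequency must be positive")
        for name, a in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not np.all(np.isfinite(a)):
                raise ValidationError(f"axis {name} contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.x)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def scaled(self, c: float) -> "AccelerometerTrace":
        return replace(self, x=self.x * c, y=self.y * c, z=self.z * c)


@dataclass
class LabelTrack:
    """Ordered, non-overlapping behaviour intervals from a collar."""

    intervals: list = field(default_factory=list)  # (start_s, end_s, class)

    def __post_init__(self):
        iv = sorted(self.intervals, key=lambda r: r[0])
        for start, end, cls in iv:
            if end <= start:
                raise ValidationError(f"interval ({start}, {end}) has end <= start")
            if cls not in LABEL_CLASSES:
                raise ValidationError(f"unknown class token {cls!r}")
        for (s0, e0, _), (s1, _, _) in zip(iv, iv[1:]):
            if s1 < e0 - 1e-9:
                raise ValidationError(
                    f"intervals overlap: [{s0}, {e0}) and starting {s1}"
                )
        self.intervals = [(float(s), float(e), c) for s, e, c in iv]

    def __len__(self):
        return len(self.intervals)


def _parse_times(raw: pd.Series, path, col: str) -> np.ndarray:
    """Timestamps as float seconds; accepts numeric seconds or ISO-8601."""
    try:
        return raw.astype(float).to_numpy()
    except (ValueError, TypeError):
        pass
    try:
        ts = pd.to_datetime(raw, format="ISO8601", utc=True)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: column {col!r}: unparseable timestamp ({exc})") from exc
    return ts.astype("int64").to_numpy() / 1e9


def _read_csv(path, required_cols):
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise as a parse error
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in required_cols:
        bad = df.index[df[col].isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ParseError(f"{path}: malformed value in column {col!r} at line {bad[0] + 2}")
    return df


def _trace_from_frame(t, df, fs):
    return AccelerometerTrace(
        t0=float(t[0]),
        fs=fs,
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        z=df["z"].to_numpy(float),
    )


def read_trace(path, fs_expected: float = 12.5, on_gap: str = "error"):
    """Read a trace file, validating uniform sampling at ``fs_expected``.

    Consecutive-row spacing must stay within +/-20% of ``1/fs_expected``;
    spacings above that bound are gaps.  ``on_gap='error'`` (default) raises
    :class:`GapError` naming every gap interval; ``on_gap='split'`` returns a
    list of independent uniform trace segments instead, since the rolling
    filters are invalid across a gap.  The median spacing must agree with
    ``1/fs_expected`` to within 5%.
    """
    if on_gap not in ("error", "split"):
        raise ValueError("on_gap must be 'error' or 'split'")
    df = _read_csv(path, ["timestamp", "x", "y", "z"])
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise ParseError(f"{path}: malformed value in column {col!r} at line {bad[0] + 2}")
        df[col] = vals
    t = _parse_times(df["timestamp"], path, "timestamp")
    if len(t) < 2:
        raise ValidationError(f"{path}: trace needs at least 2 samples")
    dt_nominal = 1.0 / fs_expected
    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise ValidationError(f"{path}: timestamps not strictly increasing at line {i + 3}")
    gaps = dt > 1.2 * dt_nominal
    jitter = dt < 0.8 * dt_nominal
    if np.any(jitter):
        i = int(np.argmax(jitter))
        raise ValidationError(
            f"{path}: inter-sample interval {dt[i]:.6g} s at line {i + 3} is more "
            f"than 20% below the nominal {dt_nominal:.6g} s"
        )
    if np.any(gaps) and on_gap == "error":
        idx = np.flatnonzero(gaps)
        spans = [(float(t[i] - t[0]), float(t[i + 1] - t[0])) for i in idx]
        first = spans[0]
        raise GapError(
            f"{path}: {len(spans)} sampling gap(s); first gap spans "
            f"[{first[0]:.3f}, {first[1]:.3f}] s from trace start",
            gaps=spans,
        )
    # segment boundaries (no gaps -> single segment)
    bounds = np.concatenate(([0], np.flatnonzero(gaps) + 1, [len(t)]))
    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 2:
            continue
        seg_dt = np.median(np.diff(t[a:b]))
        if abs(seg_dt - dt_nominal) > 0.05 * dt_nominal:
            raise GapError(
                f"{path}: median inter-sample interval {seg_dt:.6g} s differs from "
                f"nominal {dt_nominal:.6g} s by more than 5%"
            )
        segments.append(_trace_from_frame(t[a:b], df.iloc[a:b], fs_expected))
    if on_gap == "error":
        return segments[0]
    return segments


def read_labels(path) -> LabelTrack:
    """Read a collar label file; intervals are returned sorted by start."""
    df = _read_csv(path, ["start", "end", "class"])
    start = _parse_times(df["start"], path, "start")
    end = _parse_times(df["end"], path, "end")
    classes = df["class"].astype(str).str.strip()
    bad = df.index[~classes.isin(LABEL_CLASSES)]
    if len(bad):
        raise ParseError(
            f"{path}: unknown class token {classes[bad[0]]!r} at line {bad[0] + 2}"
        )
    return LabelTrack(list(zip(start, end, classes)))


def write_trace(trace: AccelerometerTrace, path) -> None:
    """Write a trace as ``timestamp,x,y,z`` CSV (lossless inverse of read)."""
    df = pd.DataFrame(
        {
            "timestamp": trace.times(),
            "x": trace.x,
            "y": trace.y,
            "z": trace.z,
        }
    )
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, index=False, float_format="%.17g")


def write_labels(track: LabelTrack, path) -> None:
    df = pd.DataFrame(track.intervals, columns=["start", "end", "class"])
    df.to_csv(path, index=False)
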