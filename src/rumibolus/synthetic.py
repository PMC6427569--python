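"""Synthetic in-reticulum accelerometer traces with known behaviour labels.

The generator emulates the signal structure the detection pipeline relies
on, not rumen biomechanics. During rumination the jerk energy shows
quasi-periodic bursts — one per reticuloruminal contraction, lasting about
8-10 s and spaced 40-60 s apart — over a low quiescent floor while the
animal chews. During feeding and other active behaviour the floor itself
is higher and spikes arrive aperiodically — a Poisson-like renewal process
with a short refractory gap, so they are frequent but not rhythmic. A
constant-magnitude gravity vector, slowly re-orienting as the
bolus shifts in the reticulum, is added to all three axes; per-sample
differencing must cancel it.

Bursts are amplitude-modulated Gaussian noise rather than a deterministic
waveform: the pipeline responds to jerk variance, not waveform shape, so
noise bursts are the minimal model that reproduces the phenomenology. The
modulation envelope is a raised cosine — contractions wax and wane rather
than switching on — which keeps each burst unimodal after smoothing. All
physical scales are arbitrary units; only energy ratios matter, because
the pipeline is scale-covariant up to the learned threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import COLLAR_PERIOD_S, AccelerometerTrace, LabelTrack

STATES = ("rumination", "feeding", "other")

#: minimum total schedule duration: two feature blocks
MIN_SCHEDULE_S = 540.0


@dataclass
class Segment:
    start: float
    end: float
    state: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError("segment end must exceed start")
        if self.state not in STATES:
            raise ValidationError(f"unknown behaviour state {self.state!r}")


@dataclass
class BehaviourSchedule:
    """Contiguous, non-overlapping behaviour segments."""

    segments: list

    def __post_init__(self):
        segs = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if abs(b.start - a.end) > 1e-9:
                raise ValidationError("segments must be contiguous")
        if self.duration < MIN_SCHEDULE_S:
            raise ValidationError(
                f"schedule must cover at least {MIN_SCHEDULE_S:.0f} s (two blocks)"
            )
        self.segments = segs

    @property
    def start(self) -> float:
        return self.segments[0].start

    @property
    def duration(self) -> float:
        return self.segments[-1].end - self.segments[0].start

    @classmethod
    def alternating(cls, states=("rumination", "feeding"), segment_s=1800.0, total_s=14400.0):
        segs, t, i = [], 0.0, 0
        while t < total_s - 1e-9:
            end = min(t + segment_s, total_s)
            segs.append(Segment(t, end, states[i % len(states)]))
            t, i = end, i + 1
        return cls(segs)


@dataclass
class SimulationParams:
    """Signal-structure parameters, all in arbitrary acceleration units.

    The quiescent floor and active floor are per-axis white-noise standard
    deviations; the active floor must exceed the quiescent one — that
    contrast is what the motion-energy baseline (JVB) feature measures.
    Contraction spacing defaults to 50 +/- 5 s, inside the physiological
    40-60 s range, with bursts of 9 s (contraction plus regurgitation).
    """

    fs: float = 12.5
    # rumination
    contraction_spacing_s: float = 50.0
    contraction_jitter_s: float = 5.0
    min_spacing_s: float = 20.0  # truncation keeps bursts from overlapping
    burst_duration_s: float = 9.0
    burst_amplitude: float = 0.1
    quiescent_noise: float = 0.0072
    # feeding / other
    active_noise: float = 0.0198
    active_spike_spacing_s: float = 30.0  # mean spacing incl. the refractory gap
    active_min_spacing_s: float = 24.0
    active_spike_duration_s: float = 3.0
    active_spike_amplitude: float = 0.05
    active_spike_amplitude_jitter: float = 0.4  # relative, uniform
    # common
    drift_step: float = 0.002  # orientation random-walk step per sample
    gravity: float = 1.0

    def validate(self) -> None:
        if self.active_noise <= self.quiescent_noise:
            raise ValidationError("active floor must exceed the quiescent floor")
        for name in (
            "fs",
            "contraction_spacing_s",
            "burst_duration_s",
            "active_spike_spacing_s",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def _burst_onsets_rumination(seg: Segment, p: SimulationParams, rng) -> list:
    onsets, t = [], seg.start
    while True:
        gap = max(p.min_spacing_s, rng.normal(p.contraction_spacing_s, p.contraction_jitter_s))
        t += gap
        if t + p.burst_duration_s > seg.end:
            return onsets
        onsets.append(t)


def _burst_onsets_active(seg: Segment, p: SimulationParams, rng) -> list:
    onsets, t = [], seg.start
    while True:
        t += p.active_min_spacing_s + rng.exponential(
            max(p.active_spike_spacing_s - p.active_min_spacing_s, 1e-6)
        )
        if t + p.active_spike_duration_s > seg.end:
            return onsets
        onsets.append(t)


def simulate(
    schedule: BehaviourSchedule,
    params: SimulationParams | None = None,
    seed: int | None = None,
    t0: float = 0.0,
    return_events: bool = False,
):
    """Generate ``(AccelerometerTrace, LabelTrack)`` for a schedule.

    Fully deterministic given ``seed``. The label track reports the
    majority behaviour state of each 90 s interval, mirroring a collar's
    reporting period; the last interval may be shorter. With
    ``return_events=True`` a third element carries the injected
    contraction-onset times for parameter-recovery checks.
    """
    p = params or SimulationParams()
    p.validate()
    rng = np.random.default_rng(seed)
    n = int(round(schedule.duration * p.fs))
    rel_t = np.arange(n) / p.fs  # seconds since schedule start
    sigma = np.zeros(n)

    events = {"rumination_onsets": [], "active_onsets": []}
    amp2 = np.zeros(n)  # squared burst amplitude, added in quadrature
    for seg in schedule.segments:
        s0, s1 = seg.start - schedule.start, seg.end - schedule.start
        in_seg = (rel_t >= s0) & (rel_t < s1)
        if seg.state == "rumination":
            sigma[in_seg] = p.quiescent_noise
            for onset in _burst_onsets_rumination(seg, p, rng):
                o = onset - schedule.start
                hit = np.flatnonzero((rel_t >= o) & (rel_t < o + p.burst_duration_s))
                # raised-cosine envelope: contractions wax and wane
                amp2[hit] += (p.burst_amplitude * np.hanning(len(hit))) ** 2
                events["rumination_onsets"].append(onset)
        else:
            sigma[in_seg] = p.active_noise
            for onset in _burst_onsets_active(seg, p, rng):
                o = onset - schedule.start
                amp = p.active_spike_amplitude * (
                    1.0 + p.active_spike_amplitude_jitter * rng.uniform(-1, 1)
                )
                hit = np.flatnonzero((rel_t >= o) & (rel_t < o + p.active_spike_duration_s))
                amp2[hit] += (amp * np.hanning(len(hit))) ** 2
                events["active_onsets"].append(onset)
    sigma = np.sqrt(sigma**2 + amp2)

    # slow orientation drift: projected Gaussian random walk on the sphere
    v0 = rng.normal(size=3)
    v0 /= np.linalg.norm(v0)
    if p.drift_step > 0:
        steps = rng.normal(scale=p.drift_step, size=(n, 3))
        walk = v0 + np.cumsum(steps, axis=0)
    else:
        walk = np.broadcast_to(v0, (n, 3)).copy()
    walk /= np.linalg.norm(walk, axis=1, keepdims=True)

    noise = rng.normal(size=(n, 3)) * sigma[:, None]
    acc = p.gravity * walk + noise
    trace = AccelerometerTrace(
        t0=t0 + schedule.start, fs=p.fs, x=acc[:, 0], y=acc[:, 1], z=acc[:, 2]
    )
    labels = _label_track(schedule, t0)
    if return_events:
        return trace, labels, events
    return trace, labels


def _label_track(schedule: BehaviourSchedule, t0: float) -> LabelTrack:
    intervals = []
    t = schedule.start
    end = schedule.segments[-1].end
    while t < end - 1e-9:
        e = min(t + COLLAR_PERIOD_S, end)
        # majority state by covered time within the interval
        cover = {}
        for seg in schedule.segments:
            ov = min(seg.end, e) - max(seg.start, t)
            if ov > 0:
                cover[seg.state] = cover.get(seg.state, 0.0) + ov
        state = max(sorted(cover), key=lambda s: cover[s])
        intervals.append((t0 + t, t0 + e, state))
        t = e
    return LabelTrack(intervals)


def default_scenario(seed: int | None = None, params: SimulationParams | None = None):
    """Four hours alternating 30 min rumination / 30 min feeding.

    Contraction spacing is set to 45 +/- 5 s so that the rumination blocks
    centre near (ICI 45 s, low log JVB) and the feeding blocks near
    (ICI 25 s, high log JVB) — the two-cluster geometry the classifier is
    designed around.
    """
    schedule = BehaviourSchedule.alternating()
    if params is None:
        params = SimulationParams(contraction_spacing_s=45.0, contraction_jitter_s=4.0)
    return simulate(schedule, params, seed=seed)
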