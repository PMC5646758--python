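"""Saccade / fixation / blink parsing of raw gaze streams.

Saccades are flagged with a velocity-or-acceleration criterion (22 deg/s,
8000 deg/s^2 by default), the convention of standard video-eyetracker
parsers.  Velocity is obtained by central differences of position followed
by a 3-sample moving average; acceleration is the central difference of the
smoothed speed.  Samples inside blinks — runs of invalid samples plus a
configurable margin — carry no velocity estimate and never contribute to
events.  Fixations are the maximal leftover valid spans; spans shorter than
the configured minimum (32 ms, i.e. 16 consecutive samples at 500 Hz) are
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gaze_io import DetectionConfig, SampleStream

__all__ = [
    "SaccadeEvent",
    "FixationEvent",
    "BlinkEvent",
    "velocity_acceleration_trace",
    "detect_blinks",
    "detect_saccades",
    "detect_fixations",
    "detect_events",
]


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: float
    offset_ms: float
    start_xy: tuple[float, float]
    end_xy: tuple[float, float]
    peak_velocity: float  # deg/s
    latency_ms: float  # onset relative to stimulus onset (t = 0)

    def __post_init__(self) -> None:
        if not self.onset_ms < self.offset_ms:
            raise ValueError("saccade onset must precede offset")

    @property
    def amplitude_deg(self) -> float:
        dx = self.end_xy[0] - self.start_xy[0]
        dy = self.end_xy[1] - self.start_xy[1]
        return float(np.hypot(dx, dy))


@dataclass(frozen=True)
class FixationEvent:
    onset_ms: float
    offset_ms: float
    centroid_xy: tuple[float, float]

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class BlinkEvent:
    onset_ms: float
    offset_ms: float


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) index pairs of True runs in a boolean array."""
    if mask.size == 0:
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return [(int(s), int(e - 1)) for s, e in zip(idx[::2], idx[1::2])]


def _usable_mask(stream: SampleStream, margin_ms: float) -> np.ndarray:
    """Valid samples excluding a margin around invalid spans (blink artifacts)."""
    usable = stream.valid.copy()
    for s, e in _runs(~stream.valid):
        lo = stream.t[s] - margin_ms
        hi = stream.t[e] + margin_ms
        usable &= ~((stream.t >= lo) & (stream.t <= hi))
    return usable


def velocity_acceleration_trace(
    stream: SampleStream, config: DetectionConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample speed (deg/s) and its rate of change (deg/s^2).

    Both traces are aligned to the sample times; samples without a usable
    estimate (stream edges, blinks and their margins) are NaN.
    """
    config = config or DetectionConfig()
    n = len(stream)
    usable = _usable_mask(stream, config.blink_margin_ms)
    if int(usable.sum()) < 3:
        raise ValueError("need at least 3 valid samples to differentiate")
    t_s = stream.t / 1000.0
    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    # central differences where both neighbours are usable
    ok = usable[2:] & usable[:-2] & usable[1:-1]
    span = t_s[2:] - t_s[:-2]
    with np.errstate(invalid="ignore", divide="ignore"):
        vx[1:-1] = np.where(ok, (stream.x[2:] - stream.x[:-2]) / span, np.nan)
        vy[1:-1] = np.where(ok, (stream.y[2:] - stream.y[:-2]) / span, np.nan)
    # 3-sample moving average, ignoring NaN at window edges
    vx_s = _smooth3(vx)
    vy_s = _smooth3(vy)
    speed = np.hypot(vx_s, vy_s)
    acc = np.full(n, np.nan)
    good = np.isfinite(speed)
    ok2 = good[2:] & good[:-2]
    with np.errstate(invalid="ignore"):
        acc[1:-1] = np.where(ok2, (speed[2:] - speed[:-2]) / span, np.nan)
    return speed, acc


def _smooth3(v: np.ndarray) -> np.ndarray:
    """3-sample moving average that keeps a value wherever the center is finite."""
    out = v.copy()
    n = len(v)
    if n < 3:
        return out
    stack = np.full((3, n), np.nan)
    stack[0, 1:] = v[:-1]
    stack[1, :] = v
    stack[2, :-1] = v[1:]
    finite = np.isfinite(stack)
    counts = finite.sum(axis=0)
    sums = np.where(finite, stack, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
    return np.where(np.isfinite(v), mean, np.nan)


def detect_blinks(stream: SampleStream, config: DetectionConfig | None = None) -> list[BlinkEvent]:
    """Runs of invalid samples, reported as blink events."""
    return [BlinkEvent(onset_ms=float(stream.t[s]), offset_ms=float(stream.t[e]))
            for s, e in _runs(~stream.valid)]


def detect_saccades(
    stream: SampleStream, config: DetectionConfig | None = None
) -> list[SaccadeEvent]:
    """Detect saccades by thresholding the velocity/acceleration traces.

    Onset is the first sample where speed OR acceleration exceeds its
    threshold; offset is the first subsequent sample where both are below.
    Above-threshold runs closer than ``merge_gap_ms`` are merged; runs that
    touch a stream edge or a blink (no flanking sub-threshold sample) are
    discarded.  Returns an empty list when nothing crosses threshold.
    """
    config = config or DetectionConfig()
    if int(stream.valid.sum()) < 3:
        return []
    speed, acc = velocity_acceleration_trace(stream, config)
    above = np.zeros(len(stream), dtype=bool)
    finite = np.isfinite(speed)
    above[finite] = (speed[finite] >= config.velocity_threshold)
    fin_a = np.isfinite(acc)
    above[fin_a] |= np.abs(acc[fin_a]) >= config.acceleration_threshold
    runs = _runs(above)
    # merge near-simultaneous crossings
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and stream.t[s] - stream.t[merged[-1][1]] < config.merge_gap_ms:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events: list[SaccadeEvent] = []
    n = len(stream)
    for s, e in merged:
        # require flanking sub-threshold (finite-trace) samples
        if s - 1 < 0 or e + 1 >= n:
            continue
        if not (np.isfinite(speed[s - 1]) and np.isfinite(speed[e + 1])):
            continue
        events.append(SaccadeEvent(
            onset_ms=float(stream.t[s]),
            offset_ms=float(stream.t[e + 1]),
            start_xy=(float(stream.x[s - 1]), float(stream.y[s - 1])),
            end_xy=(float(stream.x[e + 1]), float(stream.y[e + 1])),
            peak_velocity=float(np.nanmax(speed[s:e + 1])),
            latency_ms=float(stream.t[s]),
        ))
    return events


def detect_fixations(
    stream: SampleStream,
    saccades: list[SaccadeEvent],
    blinks: list[BlinkEvent],
    config: DetectionConfig | None = None,
) -> list[FixationEvent]:
    """Maximal valid spans between saccades/blinks, filtered by duration.

    Duration is counted as n_samples * dt so a span of exactly 16 samples at
    500 Hz is retained at 32 ms; 15 samples (30 ms) is dropped.
    """
    config = config or DetectionConfig()
    # the blink margin protects velocity estimates only; fixation membership
    # is decided on raw validity, so a 16-sample valid span next to a blink
    # still counts
    free = stream.valid.copy()
    for ev in saccades:
        free &= ~((stream.t >= ev.onset_ms) & (stream.t <= ev.offset_ms))
    dt = stream.dt_ms
    fixations: list[FixationEvent] = []
    for s, e in _runs(free):
        n_samples = e - s + 1
        duration = n_samples * dt
        if duration < config.min_fixation_ms:
            continue
        fixations.append(FixationEvent(
            onset_ms=float(stream.t[s]),
            offset_ms=float(stream.t[s]) + duration,
            centroid_xy=(float(np.mean(stream.x[s:e + 1])),
                         float(np.mean(stream.y[s:e + 1]))),
        ))
    return fixations


def detect_events(stream: SampleStream, config: DetectionConfig | None = None):
    """Convenience: full parse returning (saccades, fixations, blinks)."""
    config = config or DetectionConfig()
    blinks = detect_blinks(stream, config)
    saccades = detect_saccades(stream, config)
    fixations = detect_fixations(stream, saccades, blinks, config)
    return saccades, fixations, blinks
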