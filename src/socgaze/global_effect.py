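"""Global-effect (center-of-gravity) analysis of saccadic deviation.

Each trial presents a fixation cross that jumps 6 degrees left or right
along the horizontal meridian while a social/nonsocial image pair sits
above and below the target location.  The first saccade's direction is
compared with the direct path from the initial fixation location to the
target; the signed difference — positive toward the social image — is the
per-trial deviation.  Trials whose first saccade starts before 70 ms or
after 500 ms are excluded, and participants capturing fewer than 75% of
trials in either scramble condition are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .event_detection import SaccadeEvent, detect_events
from .gaze_io import DetectionConfig, SampleStream

__all__ = [
    "GETrial",
    "GEParticipantSummary",
    "first_saccade",
    "latency_filter",
    "deviation_angle",
    "process_ge_trial",
    "summarize_participant",
]

CONDITIONS = ("unscrambled", "scrambled")


@dataclass
class GETrial:
    """Layout, raw samples and derived statistic for one global-effect trial."""

    target_side: str  # "left" | "right"
    social_position: str  # "top" | "bottom"
    scrambled: bool
    stream: SampleStream | None = None
    fixation_origin_xy: tuple[float, float] = (0.0, 0.0)
    target_eccentricity_deg: float = 6.0
    first_saccade: SaccadeEvent | None = None
    deviation_deg: float | None = None
    excluded_reason: str | None = None

    @property
    def target_xy(self) -> tuple[float, float]:
        sign = -1.0 if self.target_side == "left" else 1.0
        return (self.fixation_origin_xy[0] + sign * self.target_eccentricity_deg,
                self.fixation_origin_xy[1])

    @property
    def condition(self) -> str:
        return "scrambled" if self.scrambled else "unscrambled"

    @property
    def retained(self) -> bool:
        return self.excluded_reason is None and self.deviation_deg is not None


@dataclass(frozen=True)
class GEParticipantSummary:
    mean_deviation: dict[str, float | None]  # per condition, retained trials only
    captured_fraction: dict[str, float]
    n_retained: dict[str, int]
    n_total: dict[str, int]
    included: bool
    exclusion_reason: str | None = None


def first_saccade(events: list[SaccadeEvent],
                  config: DetectionConfig | None = None) -> SaccadeEvent | None:
    """Earliest saccade with onset at/after stimulus onset.

    Anticipatory saccades beginning before t = 0 are skipped, as are
    movements below the microsaccade amplitude guard (1 degree by default).
    Returns None when no eligible saccade exists.
    """
    config = config or DetectionConfig()
    eligible = [ev for ev in events
                if ev.onset_ms >= 0 and ev.amplitude_deg >= config.min_saccade_amplitude_deg]
    return min(eligible, key=lambda ev: ev.onset_ms) if eligible else None


def latency_filter(saccade: SaccadeEvent, config: DetectionConfig | None = None) -> bool:
    """Keep iff the first-saccade latency lies in [70, 500] ms (inclusive)."""
    config = config or DetectionConfig()
    return config.min_latency_ms <= saccade.latency_ms <= config.max_latency_ms


def deviation_angle(saccade: SaccadeEvent, trial: GETrial) -> float:
    """Signed angle (degrees) between the first saccade and the direct path.

    The magnitude is the angle between the saccade displacement vector
    (start -> end) and the origin -> target vector.  The sign is positive
    when the saccade endpoint lies on the social image's side of the
    origin -> target line, negative on the nonsocial side, and zero on it.
    """
    ox, oy = trial.fixation_origin_xy
    tx, ty = trial.target_xy
    ux, uy = tx - ox, ty - oy
    sx = saccade.end_xy[0] - saccade.start_xy[0]
    sy = saccade.end_xy[1] - saccade.start_xy[1]
    norm_s = math.hypot(sx, sy)
    if norm_s == 0.0:
        raise ValueError("zero-length saccade vector has no direction")
    dot = ux * sx + uy * sy
    cross = ux * sy - uy * sx
    magnitude = math.degrees(math.atan2(abs(cross), dot))
    # endpoint side relative to the origin->target line: perpendicular offset
    ex, ey = saccade.end_xy[0] - ox, saccade.end_xy[1] - oy
    norm_u2 = ux * ux + uy * uy
    proj = (ex * ux + ey * uy) / norm_u2
    py = ey - proj * uy  # perpendicular component (vertical for a horizontal path)
    social_ny = 1.0 if trial.social_position == "top" else -1.0
    side = py * social_ny
    if side > 0:
        return magnitude
    if side < 0:
        return -magnitude
    return 0.0


def process_ge_trial(trial: GETrial, config: DetectionConfig | None = None) -> GETrial:
    """Run detection, first-saccade selection, latency filter and deviation.

    Mutates and returns ``trial``; sets ``excluded_reason`` to ``no_saccade``
    or ``latency`` when the trial contributes no deviation.
    """
    config = config or DetectionConfig()
    saccades, _, _ = detect_events(trial.stream, config)
    sacc = first_saccade(saccades, config)
    if sacc is None:
        trial.excluded_reason = "no_saccade"
        return trial
    trial.first_saccade = sacc
    if not latency_filter(sacc, config):
        trial.excluded_reason = "latency"
        return trial
    trial.deviation_deg = deviation_angle(sacc, trial)
    return trial


def summarize_participant(trials: list[GETrial],
                          config: DetectionConfig | None = None) -> GEParticipantSummary:
    """Per-condition mean signed deviation and the 75% capture rule.

    ``captured_fraction`` is retained/total per scramble condition; the
    participant is included only when both fractions reach the configured
    capture threshold (exactly 75% is included under the strict
    "fewer than" reading).
    """
    config = config or DetectionConfig()
    mean_dev: dict[str, float | None] = {}
    frac: dict[str, float] = {}
    n_ret: dict[str, int] = {}
    n_tot: dict[str, int] = {}
    reason = None
    included = True
    for cond in CONDITIONS:
        sub = [t for t in trials if t.condition == cond]
        kept = [t.deviation_deg for t in sub if t.retained]
        n_tot[cond] = len(sub)
        n_ret[cond] = len(kept)
        frac[cond] = len(kept) / len(sub) if sub else 0.0
        mean_dev[cond] = float(np.mean(kept)) if kept else None
        if not sub or not kept:
            included = False
            reason = reason or f"no_retained_trials_{cond}"
        elif frac[cond] < config.capture_fraction:
            included = False
            reason = reason or "capture<75%"
    return GEParticipantSummary(mean_deviation=mean_dev, captured_fraction=frac,
                                n_retained=n_ret, n_total=n_tot,
                                included=included, exclusion_reason=reason)
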