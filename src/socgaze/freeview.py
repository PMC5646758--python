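"""Preferential-looking (freeview) dwell-time analysis.

A social and a nonsocial image (5.59 x 4.19 degrees each) are shown side by
side for 5 seconds with no task.  Every detected fixation is credited, for
its full duration, to the area of interest (AOI) containing its centroid;
the per-trial statistic is

    proportion_social = dwell_social / (dwell_social + dwell_nonsocial)

so 0.5 means no preference.  Trials with zero in-AOI fixation time
contribute nothing.  Participants capturing gaze data on fewer than 75% of
scrambled trials are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .event_detection import FixationEvent, detect_events
from .gaze_io import DetectionConfig, SampleStream

__all__ = [
    "AOI",
    "FVTrial",
    "FVParticipantSummary",
    "default_fv_layout",
    "assign_dwell",
    "social_proportion",
    "process_fv_trial",
    "summarize_participant",
]

CONDITIONS = ("unscrambled", "scrambled")

IMAGE_WIDTH_DEG = 5.59
IMAGE_HEIGHT_DEG = 4.19
TRIAL_DURATION_MS = 5000.0
DEFAULT_IMAGE_CENTER_X_DEG = 4.5  # horizontal offset of each image center


@dataclass(frozen=True)
class AOI:
    """Axis-aligned rectangle in screen-centered degrees (inclusive bounds)."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("degenerate AOI rectangle")

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2, (self.y_min + self.y_max) / 2)


def default_fv_layout(center_x_deg: float = DEFAULT_IMAGE_CENTER_X_DEG) -> tuple[AOI, AOI]:
    """Left and right image rectangles at +/- ``center_x_deg`` eccentricity."""
    hw, hh = IMAGE_WIDTH_DEG / 2, IMAGE_HEIGHT_DEG / 2
    left = AOI(-center_x_deg - hw, -center_x_deg + hw, -hh, hh)
    right = AOI(center_x_deg - hw, center_x_deg + hw, -hh, hh)
    return left, right


@dataclass
class FVTrial:
    social_side: str  # "left" | "right"
    scrambled: bool
    aoi_left: AOI
    aoi_right: AOI
    stream: SampleStream | None = None
    left_image: str = ""
    right_image: str = ""
    dwell_social_ms: float | None = None
    dwell_nonsocial_ms: float | None = None
    proportion_social: float | None = None

    def __post_init__(self) -> None:
        if self.aoi_left.x_max > self.aoi_right.x_min:
            raise ValueError("AOIs must be disjoint")

    @property
    def condition(self) -> str:
        return "scrambled" if self.scrambled else "unscrambled"

    @property
    def social_aoi(self) -> AOI:
        return self.aoi_left if self.social_side == "left" else self.aoi_right

    @property
    def nonsocial_aoi(self) -> AOI:
        return self.aoi_right if self.social_side == "left" else self.aoi_left

    @property
    def captured(self) -> bool:
        return self.proportion_social is not None


@dataclass(frozen=True)
class FVParticipantSummary:
    mean_proportion: dict[str, float | None]
    captured_fraction: dict[str, float]
    n_captured: dict[str, int]
    n_total: dict[str, int]
    included: bool
    exclusion_reason: str | None = None


def assign_dwell(fixations: list[FixationEvent], trial: FVTrial,
                 discard_first: bool = False) -> tuple[float, float]:
    """Credit each fixation's full duration to the AOI holding its centroid.

    Fixations landing outside both rectangles are credited to neither.
    ``discard_first`` optionally drops the earliest fixation (the one on the
    former fixation-cross location); the default keeps it.
    """
    if discard_first and fixations:
        fixations = sorted(fixations, key=lambda f: f.onset_ms)[1:]
    dwell_social = 0.0
    dwell_nonsocial = 0.0
    for fix in fixations:
        cx, cy = fix.centroid_xy
        if trial.social_aoi.contains(cx, cy):
            dwell_social += fix.duration_ms
        elif trial.nonsocial_aoi.contains(cx, cy):
            dwell_nonsocial += fix.duration_ms
    return dwell_social, dwell_nonsocial


def social_proportion(dwell_social_ms: float, dwell_nonsocial_ms: float) -> float | None:
    """Exact dwell ratio in [0, 1]; None when no time fell in either AOI."""
    if dwell_social_ms < 0 or dwell_nonsocial_ms < 0:
        raise ValueError("dwell times must be nonnegative")
    total = dwell_social_ms + dwell_nonsocial_ms
    if total == 0:
        return None
    return dwell_social_ms / total


def process_fv_trial(trial: FVTrial, config: DetectionConfig | None = None,
                     discard_first: bool = False) -> FVTrial:
    """Detect fixations on the trial stream and fill dwell fields in place."""
    config = config or DetectionConfig()
    _, fixations, _ = detect_events(trial.stream, config)
    ds, dn = assign_dwell(fixations, trial, discard_first=discard_first)
    trial.dwell_social_ms = ds
    trial.dwell_nonsocial_ms = dn
    trial.proportion_social = social_proportion(ds, dn)
    return trial


def summarize_participant(trials: list[FVTrial],
                          config: DetectionConfig | None = None) -> FVParticipantSummary:
    """Per-condition mean dwell proportion and the capture-rate filter.

    A trial counts as captured when its proportion is defined.  Inclusion
    follows the scrambled-condition capture rate: below the configured 75%
    threshold the participant is dropped.
    """
    config = config or DetectionConfig()
    mean_prop: dict[str, float | None] = {}
    frac: dict[str, float] = {}
    n_cap: dict[str, int] = {}
    n_tot: dict[str, int] = {}
    for cond in CONDITIONS:
        sub = [t for t in trials if t.condition == cond]
        props = [t.proportion_social for t in sub if t.captured]
        n_tot[cond] = len(sub)
        n_cap[cond] = len(props)
        frac[cond] = len(props) / len(sub) if sub else 0.0
        mean_prop[cond] = float(np.mean(props)) if props else None
    included = frac["scrambled"] >= config.capture_fraction and n_cap["unscrambled"] > 0
    reason = None if included else "capture<75%"
    return FVParticipantSummary(mean_proportion=mean_prop, captured_fraction=frac,
                                n_captured=n_cap, n_total=n_tot,
                                included=included, exclusion_reason=reason)
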