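"""Data model, readers/writers, configuration and exclusion accounting.

Coordinate convention used throughout the package: screen-centered degrees
of visual angle, +x rightward, +y upward.  Timestamps are trial-relative
milliseconds with stimulus onset at t = 0.  One (monocular) gaze channel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScreenGeometry",
    "DetectionConfig",
    "SampleStream",
    "ParticipantRecord",
    "ExclusionAudit",
    "read_samples",
    "read_trials",
    "write_samples",
    "write_exclusion_log",
    "exclusion_summary",
    "load_config",
]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display geometry used to convert pixels to visual angle.

    Parameters
    ----------
    resolution_px : (width, height) of the display in pixels.
    viewing_distance_m : eye-to-screen distance in meters.
    pixel_pitch_mm : physical size of one pixel in millimeters.
    refresh_rate_hz : display refresh rate (metadata only).
    """

    resolution_px: tuple[int, int] = (1280, 1024)
    viewing_distance_m: float = 1.0
    pixel_pitch_mm: float = 0.3
    refresh_rate_hz: float = 75.0

    def __post_init__(self) -> None:
        w, h = self.resolution_px
        if w <= 0 or h <= 0 or self.viewing_distance_m <= 0 or self.pixel_pitch_mm <= 0:
            raise ValueError("all geometry parameters must be strictly positive")
        if self.refresh_rate_hz <= 0:
            raise ValueError("refresh_rate_hz must be strictly positive")

    def px_to_deg(self, x_px, y_px):
        """Map pixel coordinates (origin top-left, +y down) to centered degrees.

        deg = atan(offset_mm / distance_mm) * 180 / pi, evaluated per axis.
        """
        w, h = self.resolution_px
        cx = (w - 1) / 2.0
        cy = (h - 1) / 2.0
        dist_mm = self.viewing_distance_m * 1000.0
        x_mm = (np.asarray(x_px, dtype=float) - cx) * self.pixel_pitch_mm
        y_mm = (np.asarray(y_px, dtype=float) - cy) * self.pixel_pitch_mm
        x_deg = np.degrees(np.arctan2(x_mm, dist_mm))
        y_deg = -np.degrees(np.arctan2(y_mm, dist_mm))  # +y up
        return x_deg, y_deg

    def deg_to_px(self, x_deg, y_deg):
        """Inverse of :meth:`px_to_deg` (exact at every screen location)."""
        w, h = self.resolution_px
        cx = (w - 1) / 2.0
        cy = (h - 1) / 2.0
        dist_mm = self.viewing_distance_m * 1000.0
        x_mm = np.tan(np.radians(np.asarray(x_deg, dtype=float))) * dist_mm
        y_mm = np.tan(np.radians(-np.asarray(y_deg, dtype=float))) * dist_mm
        return x_mm / self.pixel_pitch_mm + cx, y_mm / self.pixel_pitch_mm + cy


@dataclass(frozen=True)
class DetectionConfig:
    """Event-detection thresholds and trial/participant filters.

    Defaults are the study values: saccades are flagged at 22 deg/s velocity
    or 8000 deg/s^2 acceleration; first saccades with latency outside
    [70, 500] ms exclude the trial; fixations shorter than 32 ms (16 samples
    at 500 Hz) are discarded; participants with fewer than 75% of trials
    captured in a condition are excluded.
    """

    velocity_threshold: float = 22.0  # deg/s
    acceleration_threshold: float = 8000.0  # deg/s^2
    min_latency_ms: float = 70.0
    max_latency_ms: float = 500.0
    min_fixation_ms: float = 32.0
    capture_fraction: float = 0.75
    blink_margin_ms: float = 20.0
    merge_gap_ms: float = 20.0
    min_saccade_amplitude_deg: float = 1.0  # microsaccade guard for "first saccade"

    def __post_init__(self) -> None:
        if min(self.velocity_threshold, self.acceleration_threshold,
               self.min_fixation_ms) <= 0:
            raise ValueError("thresholds must be positive")
        if not self.min_latency_ms < self.max_latency_ms:
            raise ValueError("min_latency_ms must be below max_latency_ms")
        if not 0 < self.capture_fraction <= 1:
            raise ValueError("capture_fraction must be in (0, 1]")

    @property
    def min_fixation_samples(self) -> int:
        """Minimum fixation length in samples at a given rate is derived
        per-stream; at 500 Hz the 32 ms default equals 16 samples."""
        return int(round(self.min_fixation_ms / 2.0))


@dataclass
class SampleStream:
    """Ordered gaze samples for one trial.

    Attributes
    ----------
    t : ndarray, trial-relative timestamps in ms (strictly increasing).
    x, y : ndarray, gaze position in screen-centered degrees; NaN while invalid.
    valid : boolean ndarray, False during blinks/dropout.
    nominal_rate : nominal sampling rate in Hz.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    nominal_rate: float = 500.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("t, x, y, valid must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt_ms(self) -> float:
        """Nominal inter-sample interval in ms."""
        return 1000.0 / self.nominal_rate


@dataclass
class ParticipantRecord:
    """One participant: id, trait-empathy score and trial collections."""

    id: str
    eq_score: int | None = None
    ge_trials: list = field(default_factory=list)
    fv_trials: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["trial_id", "t_ms", "x", "y", "valid"]


def _frame_to_stream(df: pd.DataFrame, geometry: ScreenGeometry | None,
                     units: str, rate: float, path) -> SampleStream:
    t = df["t_ms"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: non-monotone timestamps")
    x = pd.to_numeric(df["x"], errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(df["y"], errors="coerce").to_numpy(dtype=float)
    valid = df["valid"].to_numpy(dtype=bool) if "valid" in df else np.ones(len(t), bool)
    valid = valid & np.isfinite(x) & np.isfinite(y)
    if units == "px":
        if geometry is None:
            raise ValueError("pixel-coded samples require a ScreenGeometry")
        x, y = geometry.px_to_deg(x, y)
    elif units != "deg":
        raise ValueError(f"unknown units {units!r}")
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    return SampleStream(t=t, x=x, y=y, valid=valid, nominal_rate=rate)


def read_samples(path, dialect: str = "csv", geometry: ScreenGeometry | None = None,
                 units: str = "deg", nominal_rate: float = 500.0) -> SampleStream:
    """Read one trial's gaze samples into a :class:`SampleStream` in degrees.

    ``dialect='csv'`` expects a header ``trial_id,t_ms,x,y,valid`` (a single
    trial per file); ``dialect='asc'`` parses an EyeLink-ASC-like text file
    with whitespace-separated ``<t> <x> <y> <pupil>`` sample lines,
    ``SBLINK``/``EBLINK`` markers and a ``MSG <t> SYNCTIME`` (or ``TRIAL_ONSET``)
    line defining stimulus onset.  Dropout rows are flagged invalid, never
    deleted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        df = pd.read_csv(path)
        missing = [c for c in ("trial_id", "t_ms", "x", "y") if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        if df["trial_id"].nunique() > 1:
            raise ValueError(f"{path}: multiple trial ids; use read_trials()")
        return _frame_to_stream(df, geometry, units, nominal_rate, path)
    if dialect == "asc":
        return _read_asc(path, geometry, units, nominal_rate)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_trials(path, geometry: ScreenGeometry | None = None, units: str = "deg",
                nominal_rate: float = 500.0) -> dict[str, SampleStream]:
    """Read a multi-trial tabular sample file; returns {trial_id: stream}."""
    df = pd.read_csv(path)
    out = {}
    for tid, sub in df.groupby("trial_id", sort=False):
        out[str(tid)] = _frame_to_stream(sub, geometry, units, nominal_rate, path)
    return out


def _read_asc(path: Path, geometry, units: str, rate: float) -> SampleStream:
    t_list: list[float] = []
    x_list: list[float] = []
    y_list: list[float] = []
    valid_list: list[bool] = []
    onset: float | None = None
    in_blink = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "**", ";")):
            continue
        tok = line.split()
        tag = tok[0].upper()
        if tag == "MSG":
            if len(tok) >= 3 and tok[2].upper() in ("SYNCTIME", "TRIAL_ONSET"):
                onset = float(tok[1])
            continue
        if tag == "SBLINK":
            in_blink = True
            continue
        if tag == "EBLINK":
            in_blink = False
            continue
        if tag in ("SSACC", "ESACC", "SFIX", "EFIX", "START", "END",
                   "INPUT", "SAMPLES", "EVENTS"):
            continue
        # sample line: <t> <x> <y> <pupil>
        try:
            t = float(tok[0])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparseable line {raw!r}") from exc
        missing = len(tok) < 3 or tok[1] == "." or tok[2] == "."
        if missing or in_blink:
            t_list.append(t)
            x_list.append(np.nan)
            y_list.append(np.nan)
            valid_list.append(False)
            continue
        try:
            x = float(tok[1])
            y = float(tok[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparseable line {raw!r}") from exc
        t_list.append(t)
        x_list.append(x)
        y_list.append(y)
        valid_list.append(True)
    t_arr = np.asarray(t_list, dtype=float)
    if onset is not None:
        t_arr = t_arr - onset
    if len(t_arr) > 1 and not np.all(np.diff(t_arr) > 0):
        raise ValueError(f"{path}: non-monotone timestamps")
    x_arr = np.asarray(x_list, dtype=float)
    y_arr = np.asarray(y_list, dtype=float)
    if units == "px":
        if geometry is None:
            raise ValueError("pixel-coded samples require a ScreenGeometry")
        ok = np.isfinite(x_arr)
        xd, yd = geometry.px_to_deg(np.where(ok, x_arr, 0), np.where(ok, y_arr, 0))
        x_arr = np.where(ok, xd, np.nan)
        y_arr = np.where(ok, yd, np.nan)
    return SampleStream(t=t_arr, x=x_arr, y=y_arr,
                        valid=np.asarray(valid_list, bool), nominal_rate=rate)


def write_samples(stream: SampleStream, path, trial_id: str = "trial") -> None:
    """Write a stream to the tabular CSV dialect (round-trips with read_samples)."""
    df = pd.DataFrame({
        "trial_id": trial_id,
        "t_ms": stream.t,
        "x": np.where(stream.valid, stream.x, np.nan),
        "y": np.where(stream.valid, stream.y, np.nan),
        "valid": stream.valid.astype(int),
    })
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Exclusion accounting
# ---------------------------------------------------------------------------

@dataclass
class ExclusionAudit:
    """Counts of excluded trials/participants keyed by machine-readable reason."""

    trial_reasons: dict[str, int] = field(default_factory=dict)
    participant_reasons: dict[str, int] = field(default_factory=dict)
    n_trials_total: int = 0
    n_participants_total: int = 0

    def record_trial(self, reason: str, count: int = 1) -> None:
        self.trial_reasons[reason] = self.trial_reasons.get(reason, 0) + count

    def record_participant(self, reason: str, count: int = 1) -> None:
        self.participant_reasons[reason] = self.participant_reasons.get(reason, 0) + count

    @property
    def n_trials_excluded(self) -> int:
        return sum(self.trial_reasons.values())

    @property
    def n_participants_excluded(self) -> int:
        return sum(self.participant_reasons.values())

    def summary(self) -> dict:
        return exclusion_summary(self.n_trials_excluded, self.n_trials_total,
                                 self.n_participants_total) | {
            "trial_reasons": dict(self.trial_reasons),
            "participant_reasons": dict(self.participant_reasons),
            "participants_excluded": self.n_participants_excluded,
        }


def exclusion_summary(n_excluded: int, n_total: int, n_participants: int) -> dict:
    """Percentage of removed trials and the per-participant average.

    E.g. 92 exclusions out of 5360 trials over 67 participants gives
    1.716% removed and 1.373 trials per participant.
    """
    if n_excluded < 0 or n_total < 0 or n_excluded > max(n_total, 0):
        raise ValueError("inconsistent exclusion counts")
    percent = 100.0 * n_excluded / n_total if n_total else 0.0
    per_participant = n_excluded / n_participants if n_participants else 0.0
    return {
        "trials_excluded": n_excluded,
        "trials_total": n_total,
        "percent_excluded": percent,
        "mean_excluded_per_participant": per_participant,
    }


def write_exclusion_log(audit: ExclusionAudit, path) -> dict:
    """Write the exclusion audit as JSON; returns the written mapping.

    Totals always reconcile with the inputs: the per-reason counts sum to
    the reported exclusion totals.
    """
    payload = audit.summary()
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return payload


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def load_config(path) -> tuple[DetectionConfig, ScreenGeometry]:
    """Load a YAML config holding ``detection:`` and ``geometry:`` sections.

    Omitted keys fall back to the study defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    det_kwargs = dict(raw.get("detection", {}))
    geo_kwargs = dict(raw.get("geometry", {}))
    if "resolution_px" in geo_kwargs:
        geo_kwargs["resolution_px"] = tuple(geo_kwargs["resolution_px"])
    det_names = {f.name for f in fields(DetectionConfig)}
    geo_names = {f.name for f in fields(ScreenGeometry)}
    bad = (set(det_kwargs) - det_names) | (set(geo_kwargs) - geo_names)
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    return DetectionConfig(**det_kwargs), ScreenGeometry(**geo_kwargs)
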