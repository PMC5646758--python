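"""Synthetic 500 Hz gaze cohorts with known ground truth.

The generator emulates the two-task design end to end: global-effect trials
contain a pre-saccade fixation, one primary saccade whose direction is
rotated toward the social image by the participant's bias plus trial noise,
and a post-saccade fixation; freeview trials alternate fixations between
the two image regions so that the expected social dwell share equals the
participant's dwell proportion.  Saccades follow a minimum-jerk position
profile (peak velocity 1.875 A/T, comfortably above detection threshold for
amplitudes >= 1 degree); fixational jitter is temporally smoothed Gaussian
noise so its sample-to-sample velocities stay well below the saccade
threshold.  Trait-empathy scores are drawn jointly with the dwell biases
through a Gaussian copula to hit a target EQ-dwell correlation.

Defaults reproduce the study conditions: 40 trials per scramble condition,
6-degree target eccentricity, 5 s freeview trials, true deviation 1.433
degrees (unscrambled) / 0 (scrambled), true dwell proportions 0.57 / 0.523,
and an EQ-dwell correlation of 0.278 for unscrambled images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .freeview import (AOI, FVTrial, IMAGE_HEIGHT_DEG, IMAGE_WIDTH_DEG,
                       TRIAL_DURATION_MS, default_fv_layout)
from .gaze_io import ParticipantRecord, SampleStream
from .global_effect import GETrial

__all__ = [
    "SimulationConfig",
    "simulate_ge_trial",
    "simulate_fv_trial",
    "simulate_cohort",
    "simulate_cohort_summaries",
]


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic cohort.

    ``seed`` is mandatory; every stochastic choice flows from it.  The
    per-condition dictionaries use the keys ``unscrambled``/``scrambled``.
    """

    seed: int
    n_participants: int = 76
    trials_per_condition: int = 40
    sampling_rate_hz: float = 500.0
    # global-effect task
    true_deviation_deg: dict = field(
        default_factory=lambda: {"unscrambled": 1.433, "scrambled": 0.0})
    ge_between_sd_deg: dict = field(
        default_factory=lambda: {"unscrambled": 1.39, "scrambled": 0.91})
    ge_trial_noise_sd_deg: float = 1.0
    target_eccentricity_deg: float = 6.0
    ge_trial_duration_ms: float = 800.0
    latency_mean_ms: float = 200.0
    latency_sd_ms: float = 60.0
    latency_bounds_ms: tuple[float, float] = (30.0, 600.0)
    # freeview task
    true_dwell_proportion: dict = field(
        default_factory=lambda: {"unscrambled": 0.57, "scrambled": 0.523})
    dwell_between_sd: dict = field(
        default_factory=lambda: {"unscrambled": 0.092, "scrambled": 0.046})
    dwell_concentration: float = 50.0
    fv_trial_duration_ms: float = TRIAL_DURATION_MS
    fv_image_center_x_deg: float = 4.5
    # trait empathy
    eq_mean: float = 42.0
    eq_sd: float = 12.0
    rho_eq_dwell: dict = field(
        default_factory=lambda: {"unscrambled": 0.278, "scrambled": -0.198})
    rho_dwell_conditions: float = 0.3
    # stream noise
    fixation_jitter_sd_deg: float = 0.05
    jitter_timescale_ms: float = 20.0
    blink_rate_per_trial: float = 0.05
    dropout_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for p in self.true_dwell_proportion.values():
            if not 0.0 < p < 1.0:
                raise ValueError("dwell proportions must lie in (0, 1)")
        if min(self.blink_rate_per_trial, self.dropout_probability,
               self.fixation_jitter_sd_deg) < 0:
            raise ValueError("rates must be nonnegative")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz


# ---------------------------------------------------------------------------
# Kinematic building blocks
# ---------------------------------------------------------------------------

def minimum_jerk_profile(n: int) -> np.ndarray:
    """Normalized minimum-jerk displacement s(tau) = 10t^3 - 15t^4 + 6t^5."""
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def saccade_duration_ms(amplitude_deg: float) -> float:
    """Main-sequence duration: ~2.2 ms per degree plus a 21 ms intercept."""
    return 2.2 * amplitude_deg + 21.0


def _smooth_jitter(rng: np.random.Generator, n: int, sd_deg: float,
                   dt_ms: float, timescale_ms: float) -> np.ndarray:
    """Temporally correlated fixational jitter with the requested RMS."""
    if n == 0 or sd_deg == 0:
        return np.zeros(n)
    sigma = max(1.0, timescale_ms / dt_ms)
    half = int(3 * sigma)
    kern = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    kern /= kern.sum()
    white = rng.normal(0.0, 1.0, n + 2 * half)
    smooth = np.convolve(white, kern, mode="valid")[:n]
    rms = smooth.std()
    return smooth / rms * sd_deg if rms > 0 else np.zeros(n)


def _segments_to_stream(segments: list[np.ndarray], cfg: SimulationConfig,
                        rng: np.random.Generator, total_ms: float,
                        blink_window_ms: tuple[float, float] | None) -> SampleStream:
    """Concatenate (n, 2) position segments into a SampleStream with noise."""
    xy = np.concatenate(segments, axis=0)
    n = int(round(total_ms / cfg.dt_ms))
    if len(xy) >= n:
        xy = xy[:n]
    else:
        xy = np.concatenate([xy, np.repeat(xy[-1:], n - len(xy), axis=0)], axis=0)
    t = np.arange(n) * cfg.dt_ms
    x = xy[:, 0] + _smooth_jitter(rng, n, cfg.fixation_jitter_sd_deg,
                                  cfg.dt_ms, cfg.jitter_timescale_ms)
    y = xy[:, 1] + _smooth_jitter(rng, n, cfg.fixation_jitter_sd_deg,
                                  cfg.dt_ms, cfg.jitter_timescale_ms)
    valid = np.ones(n, dtype=bool)
    if blink_window_ms is not None and rng.random() < cfg.blink_rate_per_trial:
        lo, hi = blink_window_ms
        dur = rng.uniform(100.0, 180.0)
        if hi - dur > lo:
            start = rng.uniform(lo, hi - dur)
            valid &= ~((t >= start) & (t <= start + dur))
    if cfg.dropout_probability > 0:
        valid &= rng.random(n) >= cfg.dropout_probability
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    return SampleStream(t=t, x=x, y=y, valid=valid, nominal_rate=cfg.sampling_rate_hz)


def _saccade_segment(start: np.ndarray, end: np.ndarray, dt_ms: float) -> np.ndarray:
    amp = float(np.hypot(*(end - start)))
    n = max(3, int(round(saccade_duration_ms(amp) / dt_ms)))
    s = minimum_jerk_profile(n)
    return start[None, :] + s[:, None] * (end - start)[None, :]


def _hold_segment(point: np.ndarray, duration_ms: float, dt_ms: float) -> np.ndarray:
    n = max(1, int(round(duration_ms / dt_ms)))
    return np.repeat(point[None, :], n, axis=0)


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


# ---------------------------------------------------------------------------
# Trial generators
# ---------------------------------------------------------------------------

def simulate_ge_trial(cfg: SimulationConfig, participant_bias_deg: float,
                      target_side: str, social_position: str, scrambled: bool,
                      rng: np.random.Generator,
                      trial_noise_sd_deg: float | None = None) -> GETrial:
    """One global-effect trial: fixation, primary saccade, landing fixation.

    The saccade lands at target eccentricity with its direction rotated off
    the direct path by ``participant_bias_deg`` plus zero-mean trial noise;
    positive rotation is toward the social image.
    """
    noise_sd = (cfg.ge_trial_noise_sd_deg if trial_noise_sd_deg is None
                else trial_noise_sd_deg)
    latency = _truncated_normal(rng, cfg.latency_mean_ms, cfg.latency_sd_ms,
                                *cfg.latency_bounds_ms)
    deviation = participant_bias_deg + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
    ecc = cfg.target_eccentricity_deg
    a = math.radians(deviation)
    sign_social = 1.0 if social_position == "top" else -1.0
    sign_x = -1.0 if target_side == "left" else 1.0
    landing = np.array([sign_x * ecc * math.cos(a), sign_social * ecc * math.sin(a)])
    origin = np.zeros(2)
    segments = [
        _hold_segment(origin, latency, cfg.dt_ms),
        _saccade_segment(origin, landing, cfg.dt_ms),
    ]
    elapsed = sum(len(s) for s in segments) * cfg.dt_ms
    segments.append(_hold_segment(landing, cfg.ge_trial_duration_ms - elapsed,
                                  cfg.dt_ms))
    sacc_end = latency + saccade_duration_ms(float(np.hypot(*(landing - origin))))
    blink_window = (sacc_end + 80.0, cfg.ge_trial_duration_ms - 40.0)
    stream = _segments_to_stream(segments, cfg, rng, cfg.ge_trial_duration_ms,
                                 blink_window)
    return GETrial(target_side=target_side, social_position=social_position,
                   scrambled=scrambled, stream=stream,
                   target_eccentricity_deg=ecc)


def _split_durations(rng, total_ms: float, k: int, min_ms: float = 60.0) -> np.ndarray:
    """Dirichlet split of total_ms into k parts, each at least min_ms."""
    k = max(1, min(k, int(total_ms // (min_ms + 20.0)) or 1))
    free = total_ms - k * min_ms
    if free <= 0:
        return np.full(k, total_ms / k)
    return min_ms + rng.dirichlet(np.ones(k)) * free


def simulate_fv_trial(cfg: SimulationConfig, participant_proportion: float,
                      social_side: str, scrambled: bool,
                      rng: np.random.Generator) -> FVTrial:
    """One 5 s freeview trial of alternating fixations between the AOIs.

    A per-trial dwell share is drawn from a Beta distribution centered on
    ``participant_proportion`` (concentration ``dwell_concentration``); the
    in-AOI looking time is split in exactly that ratio, so the expected
    social dwell share over trials equals the participant proportion.
    """
    aoi_left, aoi_right = default_fv_layout(cfg.fv_image_center_x_deg)
    trial = FVTrial(social_side=social_side, scrambled=scrambled,
                    aoi_left=aoi_left, aoi_right=aoi_right)
    p = participant_proportion
    if 0.0 < p < 1.0:
        kappa = cfg.dwell_concentration
        p_trial = float(rng.beta(kappa * p, kappa * (1.0 - p)))
    else:
        p_trial = float(p)
    initial_ms = rng.uniform(200.0, 350.0)
    # budget after the central fixation, reserving time for transit saccades
    n_each = int(rng.integers(3, 6))
    budget = cfg.fv_trial_duration_ms - initial_ms - 2 * n_each * 45.0
    social_ms = p_trial * budget
    nonsocial_ms = (1.0 - p_trial) * budget
    soc_durs = _split_durations(rng, social_ms, n_each) if social_ms > 0 else []
    non_durs = _split_durations(rng, nonsocial_ms, n_each) if nonsocial_ms > 0 else []

    def scatter(aoi: AOI) -> np.ndarray:
        cx, cy = aoi.center
        return np.array([
            rng.uniform(cx - IMAGE_WIDTH_DEG / 2 + 0.7, cx + IMAGE_WIDTH_DEG / 2 - 0.7),
            rng.uniform(cy - IMAGE_HEIGHT_DEG / 2 + 0.7, cy + IMAGE_HEIGHT_DEG / 2 - 0.7),
        ])

    soc_aoi = trial.social_aoi
    non_aoi = trial.nonsocial_aoi
    plan: list[tuple[np.ndarray, float]] = [(np.zeros(2), initial_ms)]
    i = j = 0
    turn_social = bool(rng.random() < 0.5) if len(non_durs) else True
    while i < len(soc_durs) or j < len(non_durs):
        if (turn_social and i < len(soc_durs)) or j >= len(non_durs):
            plan.append((scatter(soc_aoi), float(soc_durs[i])))
            i += 1
        else:
            plan.append((scatter(non_aoi), float(non_durs[j])))
            j += 1
        turn_social = not turn_social
    segments: list[np.ndarray] = []
    prev: np.ndarray | None = None
    for point, dur in plan:
        if prev is not None:
            segments.append(_saccade_segment(prev, point, cfg.dt_ms))
        segments.append(_hold_segment(point, dur, cfg.dt_ms))
        prev = point
    blink_window = (initial_ms + 200.0, cfg.fv_trial_duration_ms - 100.0)
    trial.stream = _segments_to_stream(segments, cfg, rng,
                                       cfg.fv_trial_duration_ms, blink_window)
    return trial


# ---------------------------------------------------------------------------
# Cohort generators
# ---------------------------------------------------------------------------

def _latent_draws(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Joint standard-normal draws (eq, dwell_unscr, dwell_scr) via copula."""
    r_u = cfg.rho_eq_dwell["unscrambled"]
    r_s = cfg.rho_eq_dwell["scrambled"]
    r_c = cfg.rho_dwell_conditions
    corr = np.array([[1.0, r_u, r_s],
                     [r_u, 1.0, r_c],
                     [r_s, r_c, 1.0]])
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation targets are not jointly attainable") from exc
    z = rng.standard_normal((cfg.n_participants, 3))
    return z @ chol.T


def draw_participant_truth(cfg: SimulationConfig,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Ground-truth table: EQ score, dwell proportions, deviation biases."""
    z = _latent_draws(cfg, rng)
    eq = np.clip(np.round(cfg.eq_mean + cfg.eq_sd * z[:, 0]), 0, 80).astype(int)
    truth = {"participant": [f"P{i + 1:03d}" for i in range(cfg.n_participants)],
             "eq_score": eq}
    for cond, col in (("unscrambled", 1), ("scrambled", 2)):
        truth[f"dwell_{cond}"] = np.clip(
            cfg.true_dwell_proportion[cond] + cfg.dwell_between_sd[cond] * z[:, col],
            0.02, 0.98)
    for cond in ("unscrambled", "scrambled"):
        truth[f"deviation_{cond}"] = (cfg.true_deviation_deg[cond]
                                      + cfg.ge_between_sd_deg[cond]
                                      * rng.standard_normal(cfg.n_participants))
    return pd.DataFrame(truth)


def _ge_layouts(n: int) -> list[tuple[str, str]]:
    """Counterbalanced (target_side, social_position) sequence of length n."""
    cells = [(s, p) for s in ("left", "right") for p in ("top", "bottom")]
    return [cells[i % 4] for i in range(n)]


def simulate_cohort(cfg: SimulationConfig,
                    tasks: tuple[str, ...] = ("ge", "fv")
                    ) -> tuple[list[ParticipantRecord], pd.DataFrame]:
    """Full synthetic cohort with raw streams plus its ground-truth table."""
    rng = np.random.default_rng(cfg.seed)
    truth = draw_participant_truth(cfg, rng)
    participants: list[ParticipantRecord] = []
    for _, row in truth.iterrows():
        rec = ParticipantRecord(id=row["participant"], eq_score=int(row["eq_score"]))
        for scrambled, cond in ((False, "unscrambled"), (True, "scrambled")):
            if "ge" in tasks:
                for side, pos in _ge_layouts(cfg.trials_per_condition):
                    rec.ge_trials.append(simulate_ge_trial(
                        cfg, float(row[f"deviation_{cond}"]), side, pos,
                        scrambled, rng))
            if "fv" in tasks:
                for i in range(cfg.trials_per_condition):
                    side = "left" if i % 2 == 0 else "right"
                    rec.fv_trials.append(simulate_fv_trial(
                        cfg, float(row[f"dwell_{cond}"]), side, scrambled, rng))
        participants.append(rec)
    return participants, truth


def simulate_cohort_summaries(cfg: SimulationConfig) -> pd.DataFrame:
    """Stream-free fast path: measured-like participant summaries.

    Applies the same participant- and trial-level noise model as the full
    generator (Beta trial dwell, Gaussian trial deviation) but skips sample
    synthesis and event detection; useful for Monte-Carlo calibration at
    many replicates.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = draw_participant_truth(cfg, rng)
    out = truth.copy()
    k = cfg.trials_per_condition
    kappa = cfg.dwell_concentration
    for cond in ("unscrambled", "scrambled"):
        p = truth[f"dwell_{cond}"].to_numpy()
        trial_p = rng.beta(kappa * p[:, None], kappa * (1 - p[:, None]), (len(p), k))
        out[f"measured_dwell_{cond}"] = trial_p.mean(axis=1)
        bias = truth[f"deviation_{cond}"].to_numpy()
        trial_dev = bias[:, None] + rng.normal(0, cfg.ge_trial_noise_sd_deg,
                                               (len(bias), k))
        out[f"measured_deviation_{cond}"] = trial_dev.mean(axis=1)
    return out
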