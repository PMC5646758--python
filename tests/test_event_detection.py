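import numpy as np
import pytest

from socgaze import DetectionConfig, detect_events, detect_saccades
from socgaze.event_detection import (detect_blinks, detect_fixations,
                                     velocity_acceleration_trace)
from socgaze.simulate import (SimulationConfig, _smooth_jitter,
                              minimum_jerk_profile, simulate_ge_trial)

from conftest import make_stream


def brute_force_saccades(stream, config):
    """Independent oracle: label each sample by thresholding, merge runs.

    Pure-Python scan over the velocity/acceleration traces; runs closer
    than the merge gap coalesce, and runs without a flanking finite
    sub-threshold sample on both sides are rejected.
    """
    speed, acc = velocity_acceleration_trace(stream, config)
    above = []
    for v, a in zip(speed, acc):
        hit = (np.isfinite(v) and v >= config.velocity_threshold) or \
              (np.isfinite(a) and abs(a) >= config.acceleration_threshold)
        above.append(hit)
    runs = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged = []
    for s, e in runs:
        if merged and stream.t[s] - stream.t[merged[-1][1]] < config.merge_gap_ms:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        if s == 0 or e == len(above) - 1:
            continue
        if not (np.isfinite(speed[s - 1]) and np.isfinite(speed[e + 1])):
            continue
        out.append((stream.t[s], stream.t[e + 1]))
    return out


class TestVelocityTrace:
    def test_constant_position_zero_velocity(self, steady_fixation_stream):
        speed, acc = velocity_acceleration_trace(steady_fixation_stream)
        assert np.nanmax(speed) == 0.0
        assert np.nanmax(np.abs(acc)) == 0.0

    def test_constant_drift_pointwise_velocity(self):
        # 0.1 deg per 2 ms sample -> 50 deg/s
        x = np.arange(100) * 0.1
        speed, _ = velocity_acceleration_trace(make_stream(x, np.zeros_like(x)))
        assert np.allclose(speed[2:-2], 50.0)

    def test_gaussian_saccade_peak_recovered(self):
        # integrate an analytic Gaussian velocity profile; peak known in closed form
        dt = 0.002
        t = np.arange(0, 0.4, dt)
        peak, t0, sigma = 300.0, 0.2, 0.015
        v = peak * np.exp(-0.5 * ((t - t0) / sigma) ** 2)
        x = np.cumsum(v) * dt
        speed, _ = velocity_acceleration_trace(make_stream(x, np.zeros_like(x)))
        assert np.nanmax(speed) == pytest.approx(peak, rel=0.02)

    def test_too_short_stream_errors(self):
        with pytest.raises(ValueError, match="3 valid samples"):
            velocity_acceleration_trace(make_stream([0.0, 0.1], [0.0, 0.0]))

    def test_invalid_spans_propagate_as_nan(self):
        valid = np.ones(200, bool)
        valid[80:100] = False
        speed, _ = velocity_acceleration_trace(
            make_stream(np.zeros(200), np.zeros(200), valid=valid))
        # blink plus 20 ms margin (10 samples each side) carries no estimate
        assert np.all(np.isnan(speed[70:110]))


class TestDetectSaccades:
    def test_smooth_fixation_jitter_yields_no_saccade(self, rng):
        x = _smooth_jitter(rng, 1000, 0.05, 2.0, 20.0)
        y = _smooth_jitter(rng, 1000, 0.05, 2.0, 20.0)
        assert np.std(x) == pytest.approx(0.05, rel=1e-6)
        assert detect_saccades(make_stream(x, y)) == []

    def test_single_simulated_saccade_endpoints(self):
        # 6-degree minimum-jerk saccade, ~300 deg/s peak, embedded in fixation
        dt = 2.0
        hold = np.zeros(100)
        prof = minimum_jerk_profile(19) * 6.0  # 38 ms
        x = np.concatenate([hold, prof, np.full(100, 6.0)])
        events = detect_saccades(make_stream(x, np.zeros_like(x)))
        assert len(events) == 1
        ev = events[0]
        assert ev.start_xy[0] == pytest.approx(0.0, abs=0.25)
        assert ev.end_xy[0] == pytest.approx(6.0, abs=0.25)
        assert ev.peak_velocity >= 22.0
        assert ev.onset_ms == pytest.approx(100 * dt, abs=10)

    def test_all_invalid_stream(self):
        n = 100
        stream = make_stream(np.zeros(n), np.zeros(n), valid=np.zeros(n, bool))
        assert detect_saccades(stream) == []
        assert len(detect_blinks(stream)) == 1

    @pytest.mark.parametrize("threshold", [22.0, 40.0, 80.0, 150.0, 300.0])
    def test_threshold_monotonicity(self, rng, threshold):
        """Raising the velocity threshold never increases the saccade count."""
        cfg = SimulationConfig(seed=3, blink_rate_per_trial=0.0)
        trial = simulate_ge_trial(cfg, 1.0, "right", "top", False, rng)
        lo = detect_saccades(trial.stream, DetectionConfig(velocity_threshold=threshold))
        hi = detect_saccades(trial.stream,
                             DetectionConfig(velocity_threshold=threshold * 1.5))
        assert len(hi) <= len(lo)

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_on_short_streams(self, seed):
        """Event boundaries match an independent brute-force threshold scan."""
        cfg = SimulationConfig(seed=seed, ge_trial_duration_ms=400.0,
                               latency_mean_ms=120.0, latency_sd_ms=30.0,
                               latency_bounds_ms=(80.0, 200.0),
                               blink_rate_per_trial=0.5)
        rng = np.random.default_rng(seed)
        trial = simulate_ge_trial(cfg, 1.5, "left", "top", False, rng)
        assert len(trial.stream) <= 200
        config = DetectionConfig()
        ours = [(ev.onset_ms, ev.offset_ms)
                for ev in detect_saccades(trial.stream, config)]
        assert ours == brute_force_saccades(trial.stream, config)


class TestDetectFixations:
    def test_steady_five_second_fixation(self, steady_fixation_stream, config):
        fixations = detect_fixations(steady_fixation_stream, [], [], config)
        assert len(fixations) == 1
        assert fixations[0].duration_ms == pytest.approx(5000, abs=2)

    @pytest.mark.parametrize("n_valid,kept", [(16, True), (15, False)])
    def test_minimum_duration_boundary(self, n_valid, kept, config):
        # a valid span of exactly 16 samples at 500 Hz spans 32 ms: retained
        n = 200
        valid = np.zeros(n, bool)
        valid[50:50 + n_valid] = True
        stream = make_stream(np.zeros(n), np.zeros(n), valid=valid)
        fixations = detect_fixations(stream, [], detect_blinks(stream), config)
        assert (len(fixations) == 1) is kept
        if kept:
            assert fixations[0].duration_ms == pytest.approx(32.0)

    def test_partition_no_overlap(self, rng):
        """Saccade, fixation and blink spans never overlap on a valid sample."""
        cfg = SimulationConfig(seed=11, blink_rate_per_trial=1.0)
        trial = simulate_ge_trial(cfg, 1.0, "right", "bottom", False, rng)
        stream = trial.stream
        saccades, fixations, blinks = detect_events(stream)
        claimed = np.zeros(len(stream), dtype=int)
        for ev in saccades + fixations:
            claimed[(stream.t >= ev.onset_ms) & (stream.t < ev.offset_ms)] += 1
        for ev in blinks:
            claimed[(stream.t >= ev.onset_ms) & (stream.t <= ev.offset_ms)] += 1
        assert claimed.max() <= 1
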