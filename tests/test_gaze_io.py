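import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from socgaze import (DetectionConfig, ExclusionAudit, ScreenGeometry,
                     exclusion_summary, load_config, read_samples, read_trials,
                     write_exclusion_log, write_samples)

from conftest import make_stream


class TestScreenGeometry:
    def test_center_pixel_maps_to_origin(self):
        geom = ScreenGeometry(resolution_px=(1000, 1000), pixel_pitch_mm=0.25)
        x, y = geom.px_to_deg(499.5, 499.5)
        assert x == pytest.approx(0.0, abs=1e-12)
        assert y == pytest.approx(0.0, abs=1e-12)

    def test_off_center_pixel_matches_hand_trigonometry(self):
        # 100 px right of center at 0.25 mm pitch, 1 m: atan(25/1000) rad
        geom = ScreenGeometry(resolution_px=(1000, 1000), pixel_pitch_mm=0.25,
                              viewing_distance_m=1.0)
        x, y = geom.px_to_deg(599.5, 499.5)
        assert x == pytest.approx(math.degrees(math.atan(25.0 / 1000.0)), rel=1e-12)
        # pixel rows grow downward; +y is up
        _, y_down = geom.px_to_deg(499.5, 599.5)
        assert y_down == pytest.approx(-math.degrees(math.atan(25.0 / 1000.0)),
                                       rel=1e-12)

    @given(st.floats(0, 1279), st.floats(0, 1023))
    def test_pixel_degree_roundtrip(self, px, py):
        geom = ScreenGeometry()
        x, y = geom.px_to_deg(px, py)
        bx, by = geom.deg_to_px(x, y)
        assert abs(bx - px) < 0.01 and abs(by - py) < 0.01

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            ScreenGeometry(viewing_distance_m=0.0)


class TestReadSamples:
    def test_constant_center_csv(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("trial_id,t_ms,x,y,valid\n"
                     "a,0,0.0,0.0,1\na,2,0.0,0.0,1\na,4,0.0,0.0,1\n")
        s = read_samples(p)
        assert len(s) == 3 and s.valid.all()
        assert np.allclose(s.x, 0) and np.allclose(s.y, 0)

    def test_missing_x_flags_invalid_without_dropping(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("trial_id,t_ms,x,y,valid\n"
                     "a,0,0.0,0.0,1\na,2,,0.0,1\na,4,0.0,0.0,1\n")
        s = read_samples(p)
        assert len(s) == 3
        assert list(s.valid) == [True, False, True]
        assert np.isnan(s.x[1])

    def test_pixel_units_converted_through_geometry(self, tmp_path):
        geom = ScreenGeometry(resolution_px=(1000, 1000), pixel_pitch_mm=0.25)
        p = tmp_path / "t.csv"
        p.write_text("trial_id,t_ms,x,y,valid\na,0,499.5,499.5,1\na,2,599.5,499.5,1\n")
        s = read_samples(p, geometry=geom, units="px")
        assert s.x[0] == pytest.approx(0.0, abs=1e-12)
        assert s.x[1] == pytest.approx(math.degrees(math.atan(0.025)), rel=1e-9)

    def test_nonmonotone_timestamps_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("trial_id,t_ms,x,y,valid\na,0,0,0,1\na,4,0,0,1\na,2,0,0,1\n")
        with pytest.raises(ValueError, match="monotone"):
            read_samples(p)

    def test_roundtrip_preserves_values(self, tmp_path, rng):
        n = 50
        stream = make_stream(rng.normal(0, 3, n), rng.normal(0, 2, n),
                             valid=rng.random(n) > 0.1)
        path = tmp_path / "rt.csv"
        write_samples(stream, path, trial_id="x1")
        back = read_samples(path)
        assert np.array_equal(back.valid, stream.valid)
        assert np.allclose(back.t, stream.t)
        ok = stream.valid
        assert np.allclose(back.x[ok], stream.x[ok], atol=1e-5)
        assert np.allclose(back.y[ok], stream.y[ok], atol=1e-5)

    def test_read_trials_groups_by_id(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("trial_id,t_ms,x,y,valid\n"
                     "a,0,0,0,1\na,2,0,0,1\nb,0,1,1,1\n")
        d = read_trials(p)
        assert set(d) == {"a", "b"}
        assert len(d["a"]) == 2 and len(d["b"]) == 1


class TestAscDialect:
    def test_samples_blinks_and_onset(self, tmp_path):
        p = tmp_path / "t.asc"
        p.write_text(
            "MSG 1000 SYNCTIME\n"
            "1000 1.0 2.0 900\n"
            "1002 1.1 2.0 900\n"
            "SBLINK R 1004\n"
            "1004 . . 0\n"
            "1006 . . 0\n"
            "EBLINK R 1006 1006\n"
            "1008 1.2 2.1 900\n")
        s = read_samples(p, dialect="asc")
        assert len(s) == 5
        assert s.t[0] == 0.0 and s.t[-1] == 8.0  # onset-relative
        assert list(s.valid) == [True, True, False, False, True]

    def test_unparseable_line_names_its_number(self, tmp_path):
        p = tmp_path / "t.asc"
        p.write_text("1000 1.0 2.0 900\nnot-a-sample here\n")
        with pytest.raises(ValueError, match=":2:"):
            read_samples(p, dialect="asc")


class TestExclusionLog:
    def test_zero_exclusions(self, tmp_path):
        audit = ExclusionAudit(n_trials_total=80, n_participants_total=1)
        payload = write_exclusion_log(audit, tmp_path / "log.json")
        assert payload["trials_excluded"] == 0
        assert payload["percent_excluded"] == 0.0

    def test_study_scale_arithmetic(self):
        # 92 removals over 67 participants' 5360 trials
        s = exclusion_summary(92, 5360, 67)
        assert s["mean_excluded_per_participant"] == pytest.approx(1.373, abs=5e-4)
        assert s["percent_excluded"] == pytest.approx(1.716, abs=5e-4)

    def test_simple_percentage(self):
        assert exclusion_summary(5, 80, 1)["percent_excluded"] == pytest.approx(6.25)

    def test_totals_reconcile(self, tmp_path):
        audit = ExclusionAudit(n_trials_total=100, n_participants_total=2)
        audit.record_trial("latency", 3)
        audit.record_trial("no_saccade", 2)
        payload = write_exclusion_log(audit, tmp_path / "log.json")
        assert payload["trials_excluded"] == sum(payload["trial_reasons"].values()) == 5


def test_load_config_defaults_and_overrides(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text("detection:\n  velocity_threshold: 30\n"
                 "geometry:\n  resolution_px: [800, 600]\n")
    det, geom = load_config(p)
    assert det.velocity_threshold == 30
    assert det.acceleration_threshold == 8000.0  # default retained
    assert geom.resolution_px == (800, 600)
    bad = tmp_path / "bad.yaml"
    bad.write_text("detection:\n  not_a_key: 1\n")
    with pytest.raises(ValueError, match="unknown config"):
        load_config(bad)


def test_detection_config_invariants():
    with pytest.raises(ValueError):
        DetectionConfig(min_latency_ms=500, max_latency_ms=70)
    with pytest.raises(ValueError):
        DetectionConfig(capture_fraction=0.0)
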