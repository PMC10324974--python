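import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from stridepower import imu_processing as imu
from stridepower.signal_io import FormatError, TimeSeries
from stridepower.synthetic import SyntheticTrialConfig, generate_trial

CHANNELS = ["ax", "ay", "az", "gx", "gy", "gz"]


def _imu_series(values, fs=512.0):
    return TimeSeries(fs=fs, channels=CHANNELS, values=values)


def _tone_gain(freq, fs=512.0):
    t = np.arange(int(4 * fs)) / fs
    vals = np.zeros((t.size, 6))
    vals[:, 0] = np.sin(2 * np.pi * freq * t)
    out = imu.lowpass_imu(_imu_series(vals, fs)).values[:, 0]
    return np.abs(out[500:-500]).max()


class TestLowpass:
    def test_dc_unchanged(self):
        vals = np.full((1000, 6), 7.7)
        out = imu.lowpass_imu(_imu_series(vals))
        np.testing.assert_allclose(out.values, 7.7, rtol=1e-6)

    def test_passband_and_stopband_gains(self):
        assert _tone_gain(10.0) == pytest.approx(1.0, rel=0.01)
        assert _tone_gain(150.0) < 0.05

    def test_wrong_channel_count(self):
        ts = TimeSeries(fs=512.0, channels=["a", "b"], values=np.zeros((100, 2)))
        with pytest.raises(FormatError):
            imu.lowpass_imu(ts)


class TestFunctionalCalibration:
    def _recovery_error_deg(self, mount_rotvec):
        cfg = SyntheticTrialConfig(speed=3.0, grade=0.0, duration=15.0, seed=8,
                                   mount_rotvec=mount_rotvec,
                                   noise_sd_accel=0.0, noise_sd_gyro=0.0,
                                   step_variability=0.0)
        trial = generate_trial(cfg)
        filt = imu.lowpass_imu(trial.imu_left)
        R = imu.functional_calibration(filt)
        true_R = Rotation.from_rotvec(cfg.mount_rotvec).as_matrix()
        cos = (np.trace(R @ true_R.T) - 1) / 2
        return math.degrees(math.acos(np.clip(cos, -1, 1)))

    def test_identity_mount_recovered(self):
        assert self._recovery_error_deg((0.0, 0.0, 0.0)) < 1.0

    def test_quarter_turn_about_vertical_recovered(self):
        assert self._recovery_error_deg((0.0, 0.0, np.pi / 2)) < 1.0

    def test_gravity_maps_to_minus_z(self, clean_trial_processed):
        trial = clean_trial_processed["trial"]
        R = clean_trial_processed["R"]
        n_static = int(4.0 * trial.imu_left.fs)
        filt = imu.lowpass_imu(trial.imu_left)
        static_acc = filt.values[:n_static, :3].mean(axis=0)
        gravity = -(R @ static_acc)
        np.testing.assert_allclose(gravity, [0, 0, -9.81], atol=0.1)

    def test_rotation_is_orthonormal(self, clean_trial_processed):
        R = clean_trial_processed["R"]
        assert np.linalg.norm(R @ R.T - np.eye(3)) < 1e-6
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_motion_during_static_window_rejected(self, rng):
        vals = rng.normal(scale=3.0, size=(int(512 * 12), 6))
        vals[:, 2] += 9.81
        with pytest.raises(imu.CalibrationError, match="static"):
            imu.functional_calibration(_imu_series(vals))


class TestSegmentation:
    def test_events_recovered_within_10ms(self, clean_trial_processed):
        d = clean_trial_processed
        trial, cal = d["trial"], d["cal"]
        fs = cal.fs
        offset = trial.config.static_duration
        for field, truth in (("ic", trial.truth.foot_ic_times["left"]),
                             ("tc_event", trial.truth.foot_tc_times["left"])):
            det = np.array([getattr(c, field) for c in d["cycles"]]) / fs - offset
            err = np.array([np.abs(truth - t).min() for t in det])
            assert err.max() < 0.010

    def test_constant_gyro_fails(self):
        vals = np.zeros((int(512 * 12), 6))
        vals[:, 2] = 9.81
        ts = _imu_series(vals)
        with pytest.raises(imu.SegmentationError):
            imu.segment_cycles(ts)

    def test_periodic_gait_gives_periodic_cycles(self, clean_trial_processed):
        cycles = clean_trial_processed["cycles"]
        strides = np.diff([c.midswing_start for c in cycles])
        assert np.ptp(strides) <= 2  # identical cycles, +-1 sample jitter

    def test_event_ordering_enforced(self):
        with pytest.raises(imu.EventOrderError):
            imu.GaitCycle(midswing_start=0, ic=100, tc_event=50, midswing_end=300)


class TestTemporalParams:
    def test_arithmetic_example(self):
        cyc = imu.GaitCycle(0, 100, 250, 512)
        tp = imu.temporal_params(cyc, 512.0, next_contact_sample=330)
        assert tp.tc == pytest.approx(150 / 512)
        assert tp.strd == pytest.approx(1.0)
        assert tp.ts == pytest.approx(1.0 - 150 / 512)
        assert tp.tf == pytest.approx(80 / 512)

    def test_conservation_tc_plus_ts(self, clean_trial_processed):
        for cyc in clean_trial_processed["cycles"]:
            tp = imu.temporal_params(cyc, 512.0)
            assert tp.tc + tp.ts == pytest.approx(tp.strd, abs=1e-12)

    def test_flight_time_from_both_feet(self, clean_trial):
        cfg = clean_trial.config
        feet = {}
        for side, ts in (("left", clean_trial.imu_left),
                         ("right", clean_trial.imu_right)):
            filt = imu.lowpass_imu(ts)
            cal = imu.apply_calibration(filt, imu.functional_calibration(filt))
            feet[side] = imu.segment_cycles(cal, skip_seconds=cfg.static_duration)
        tfs = imu.stride_flight_times(feet["left"], feet["right"], 512.0)
        got = np.array([t for t in tfs if t is not None])
        assert got.size > 0
        np.testing.assert_allclose(got, cfg.flight_time, atol=2 / 512)

    def test_degenerate_events_rejected(self):
        cyc = imu.GaitCycle(0, 100, 250, 512)
        with pytest.raises(imu.EventOrderError):
            imu.temporal_params(cyc, 512.0, next_contact_sample=200)


class TestSpringMass:
    def test_zero_flight_limit(self):
        tp = imu.TemporalParams(tc=0.25, tf=1e-12, ts=0.45, strd=0.70)
        smp = imu.spring_mass(tp, 70.0)
        assert smp.fzmax == pytest.approx(70.0 * 9.81 * np.pi / 2, rel=1e-9)

    def test_against_independent_evaluation(self):
        m, tc, tf = 70.0, 0.25, 0.10
        tp = imu.TemporalParams(tc=tc, tf=tf, ts=0.45, strd=0.70)
        smp = imu.spring_mass(tp, m)
        g = 9.81
        fz = m * g * (math.pi / 2.0) * (tf / tc + 1.0)
        dz = fz * tc * tc / (m * math.pi ** 2) - g * tc * tc / 8.0
        assert smp.fzmax == pytest.approx(fz, abs=1e-10)
        assert smp.dz == pytest.approx(dz, abs=1e-10)
        assert smp.kvert == pytest.approx(fz / dz / 1000.0, abs=1e-10)

    def test_definitional_identity(self, rng):
        for _ in range(20):
            tc = rng.uniform(0.15, 0.35)
            tf = rng.uniform(0.02, 0.2)
            tp = imu.TemporalParams(tc=tc, tf=tf, ts=0.5, strd=tc + 0.5)
            smp = imu.spring_mass(tp, rng.uniform(50, 100))
            assert smp.kvert * 1000.0 * smp.dz == pytest.approx(smp.fzmax, rel=1e-12)

    def test_mass_scale_covariance(self):
        tp = imu.TemporalParams(tc=0.25, tf=0.1, ts=0.45, strd=0.70)
        a, b = imu.spring_mass(tp, 70.0), imu.spring_mass(tp, 140.0)
        assert b.fzmax == pytest.approx(2 * a.fzmax)
        assert b.dz == pytest.approx(a.dz)  # dz is mass-free
        assert b.kvert == pytest.approx(2 * a.kvert)


class TestOrientationAndVelocity:
    def test_configured_fsa_recovered(self):
        cfg = SyntheticTrialConfig(speed=3.0, grade=0.0, duration=15.0, seed=9,
                                   fsa_deg=15.0, noise_sd_accel=0.0,
                                   noise_sd_gyro=0.0, step_variability=0.0)
        trial = generate_trial(cfg)
        filt = imu.lowpass_imu(trial.imu_left)
        cal = imu.apply_calibration(filt, imu.functional_calibration(filt))
        cycles = imu.segment_cycles(cal, skip_seconds=cfg.static_duration)
        fsa = imu.foot_orientation_and_fsa(cal, cycles)
        assert np.nanmax(np.abs(fsa[1:] - 15.0)) < 2.0

    def test_flat_foot_landing_near_zero(self):
        cfg = SyntheticTrialConfig(speed=3.0, grade=0.0, duration=15.0, seed=9,
                                   fsa_deg=0.5, noise_sd_accel=0.0,
                                   noise_sd_gyro=0.0, step_variability=0.0)
        trial = generate_trial(cfg)
        filt = imu.lowpass_imu(trial.imu_left)
        cal = imu.apply_calibration(filt, imu.functional_calibration(filt))
        cycles = imu.segment_cycles(cal, skip_seconds=cfg.static_duration)
        fsa = imu.foot_orientation_and_fsa(cal, cycles)
        assert np.nanmax(np.abs(fsa[1:])) < 1.5

    def test_first_cycle_has_no_anchor(self, clean_trial_processed):
        assert np.isnan(clean_trial_processed["fsa"][0])

    def test_velocity_zero_at_stance_anchors(self, clean_trial_processed):
        d = clean_trial_processed
        for cyc in d["cycles"][:-1]:
            v = d["vf"].values[cyc.midstance]
            assert np.linalg.norm(v) < 1e-9  # exact by construction

    def test_velocity_profile_matches_generator(self, clean_trial_processed):
        d = clean_trial_processed
        cfg = d["trial"].config
        speed = np.linalg.norm(d["vf"].values[d["valid"]], axis=1)
        # generator swing: quintic over stride length, peak = 1.875 L/swing
        L = cfg.speed * cfg.stride_duration
        swing = cfg.stride_duration - cfg.contact_time
        peak = 1.875 * L / swing
        assert speed.max() == pytest.approx(peak, rel=0.05)

    def test_midstance_speed_below_pipeline_tolerance(self, clean_trial_processed):
        d = clean_trial_processed
        for cyc in d["cycles"][1:-1]:
            assert np.linalg.norm(d["vf"].values[cyc.midstance]) < 0.05

    def test_stationary_sensor_zero_velocity(self):
        # still foot with gravity only: any anchored integration must stay 0
        n = int(512 * 6)
        vals = np.zeros((n, 6))
        vals[:, 2] = 9.81
        ts = _imu_series(vals)
        cycles = [imu.GaitCycle(100, 500, 900, 1400),
                  imu.GaitCycle(1400, 1800, 2200, 2700)]
        vf, valid = imu.foot_velocity(ts, cycles)
        assert np.abs(vf.values[valid]).max() < 1e-9

    def test_rotation_quaternions_stay_orthonormal(self, clean_trial_processed):
        d = clean_trial_processed
        gyr = d["cal"].values[:, 3:6]
        quats = imu._integrate_quaternions(gyr[:2000], 1 / 512.0)
        norms = np.linalg.norm(quats, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)
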