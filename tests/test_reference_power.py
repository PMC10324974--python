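import numpy as np
import pytest
from scipy.signal import correlate

from stridepower.reference_power import (G, SignalLengthError, StanceInterval,
                                         com_acceleration, detect_stances,
                                         filter_forces, grade_to_angle,
                                         step_power, trial_reference_power)
from stridepower.signal_io import TimeSeries, TrialMeta


def _series(fy, fz=None, fs=1000.0):
    fz = np.zeros_like(fy) if fz is None else fz
    return TimeSeries(fs=fs, channels=["Fy", "Fz"],
                      values=np.column_stack([fy, fz]))


def _meta(grade=0.0, mass=70.0, speed=3.0):
    return TrialMeta("p", mass=mass, height=175, age=30, leg_length=90,
                     speed=speed, grade=grade)


class TestFilterForces:
    def test_dc_gain_is_unity(self):
        ts = _series(np.full(2000, 123.4))
        out = filter_forces(ts)
        np.testing.assert_allclose(out.channel("Fy"), 123.4, rtol=1e-6)

    def test_passband_tone_amplitude_and_zero_lag(self):
        t = np.arange(4000) / 1000.0
        tone = np.sin(2 * np.pi * 5.0 * t)
        out = filter_forces(_series(tone)).channel("Fy")[500:-500]
        ref = tone[500:-500]
        assert np.abs(out).max() == pytest.approx(1.0, rel=0.01)
        xc = correlate(out, ref, mode="full")
        lag = int(np.argmax(xc)) - (len(ref) - 1)
        assert lag == 0  # zero-phase filtering

    def test_stopband_tone_attenuated(self):
        t = np.arange(4000) / 1000.0
        tone = np.sin(2 * np.pi * 100.0 * t)
        out = filter_forces(_series(tone)).channel("Fy")[500:-500]
        # 3rd-order Butterworth at 100 Hz (4x cutoff): single pass
        # |H| = 1/sqrt(1+(f/fc)^6) = -36 dB; applied twice > 20 dB easily
        assert 20 * np.log10(np.abs(out).max()) < -20.0

    def test_short_signal_raises(self):
        with pytest.raises(SignalLengthError):
            filter_forces(_series(np.zeros(10)))


class TestDetectStances:
    def test_zero_signal_gives_no_stances(self):
        assert detect_stances(np.zeros(5000)) == []

    def test_half_sine_pulse_detected_with_midstance_at_apex(self):
        fz = np.zeros(2000)
        fz[600:900] = 1500.0 * np.sin(np.pi * np.arange(300) / 300)
        stances = detect_stances(fz)
        assert len(stances) == 1
        apex = 600 + int(np.argmax(fz[600:900]))
        assert stances[0].midstance_index == apex

    def test_short_pulse_rejected(self):
        fz = np.zeros(1000)
        fz[100:130] = 1000.0  # above 20 N but only 30 samples
        assert detect_stances(fz) == []

    def test_weak_stance_without_midstance_discarded(self):
        fz = np.zeros(1000)
        fz[100:300] = 250.0  # never above 300 N
        assert detect_stances(fz) == []

    def test_event_ordering_enforced(self):
        with pytest.raises(ValueError):
            StanceInterval(ic_index=10, tc_index=100, midstance_index=5)


class TestComAcceleration:
    def test_level_no_force_is_zero(self):
        np.testing.assert_array_equal(
            com_acceleration(np.zeros(5), 70.0, 0.0, "level"), 0.0)

    def test_uphill_formula_against_independent_recomputation(self):
        theta = grade_to_angle(10.0)
        fy = np.array([200.0])
        got = com_acceleration(fy, 70.0, theta, "uphill")[0]
        # independent: a = F/m - g sin(arctan(0.1))
        expected = 200.0 / 70.0 - G * (0.1 / np.hypot(1.0, 0.1))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_downhill_mirrors_uphill(self, rng):
        theta = grade_to_angle(12.0)
        fy = rng.normal(scale=300.0, size=64)
        up = com_acceleration(fy, 70.0, theta, "uphill")
        down = com_acceleration(-fy, 70.0, theta, "downhill")
        np.testing.assert_allclose(down, -up, atol=1e-12)

    def test_level_continuity_of_both_equations(self, rng):
        fy = rng.normal(scale=300.0, size=64)
        up = com_acceleration(fy, 70.0, 0.0, "level")
        down = com_acceleration(fy, 70.0, 0.0, "downhill")
        np.testing.assert_array_equal(up, down)

    def test_bad_mass_rejected(self):
        with pytest.raises(ValueError):
            com_acceleration(np.zeros(3), -1.0, 0.0, "level")

    def test_offset_linearity(self, rng):
        fy = rng.normal(scale=300.0, size=128)
        base = com_acceleration(fy, 70.0, 0.2, "uphill")
        shifted = com_acceleration(fy + 35.0, 70.0, 0.2, "uphill")
        np.testing.assert_allclose(shifted - base, 0.5, atol=1e-12)


class TestStepPower:
    def test_zero_force_zero_power(self):
        cyc = _series(np.zeros(500))
        sp = step_power(cyc, _meta())
        np.testing.assert_allclose(sp.vy_trace, 3.0)
        assert sp.peak_power == 0.0

    def test_sinusoidal_stance_matches_closed_form(self):
        # Fy = A sin(2 pi t / tc) over one stance at theta = 0
        A, tc, m, v0 = 250.0, 0.25, 70.0, 3.0
        fs = 1000.0
        n = int(tc * fs)
        t = np.arange(n) / fs
        fy = A * np.sin(2 * np.pi * t / tc)
        sp = step_power(_series(fy), _meta(mass=m, speed=v0))
        # closed form: vy = v0 + (A/m)(tc/2pi)(1 - cos 2 pi t / tc)
        tt = np.linspace(0, tc, 200001)
        vy = v0 + (A / m) * (tc / (2 * np.pi)) * (1 - np.cos(2 * np.pi * tt / tc))
        py = vy * A * np.sin(2 * np.pi * tt / tc)
        assert sp.peak_power == pytest.approx(py.max(), rel=1e-3)

    def test_trapezoid_exact_for_linear_acceleration(self):
        # Fy linear in t -> ay linear -> trapezoidal vy exact (quadratic)
        fs, m, v0 = 1000.0, 70.0, 3.0
        t = np.arange(300) / fs
        fy = 400.0 * t
        sp = step_power(_series(fy), _meta(mass=m, speed=v0))
        exact = v0 + 0.5 * (400.0 / m) * t ** 2
        np.testing.assert_allclose(sp.vy_trace, exact, atol=1e-12)

    def test_downhill_sign_convention(self):
        tc, fs = 0.25, 1000.0
        t = np.arange(int(tc * fs)) / fs
        fy = -250.0 * np.sin(2 * np.pi * t / tc)  # braking-dominant
        sp = step_power(_series(fy), _meta(grade=-10.0))
        assert sp.condition == "downhill"
        assert sp.peak_power < 0
        assert sp.peak_power == pytest.approx(sp.py_trace.min())

    def test_too_short_cycle(self):
        with pytest.raises(SignalLengthError):
            step_power(_series(np.zeros(1)), _meta())


class TestTrialReferencePower:
    def test_constant_steps_give_constant_series(self, clean_trial):
        series, steps = trial_reference_power(clean_trial.force_plate,
                                              clean_trial.meta)
        peaks = np.array([s.peak_power for s in steps])
        assert np.ptp(peaks) / peaks.mean() < 0.01  # identical strides
        assert np.ptp(series.values) / series.values.mean() < 0.01

    def test_per_second_series_matches_bruteforce(self, clean_trial):
        series, steps = trial_reference_power(clean_trial.force_plate,
                                              clean_trial.meta)
        times = np.array([s.step_time for s in steps])
        peaks = np.array([s.peak_power for s in steps])
        last = None
        for sec, got in zip(series.seconds, series.values):
            mask = (times >= sec) & (times < sec + 1)
            if mask.any():
                last = peaks[mask].mean()
            if last is not None:
                assert got == pytest.approx(last)

    def test_empty_trial_warns(self):
        ts = _series(np.zeros(3000), np.zeros(3000))
        with pytest.warns(UserWarning, match="no stances"):
            series, steps = trial_reference_power(ts, _meta())
        assert len(series) == 0 and steps == []
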