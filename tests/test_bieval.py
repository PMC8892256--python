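"""BiEval engine: derivatives, segmentation, parameters, outlier fence."""

import math

import numpy as np
import pandas as pd
import pytest

from bicar.bieval import (
    MovementSegment,
    SegmentationConfig,
    error_parameter,
    force_parameters,
    kinematic_derivatives,
    segment_movements,
    session_report,
    smoothness_parameters,
    speed_parameters,
    time_parameters,
    torque_parameters,
    validate_outliers,
)
from bicar.game import ControllerConfig
from bicar.simulate import SessionLog, minimum_jerk_speed, simulate_session, healthy_profile

FS = 80.0
DT = 1.0 / FS


def _make_log(t, theta, theta_d, fl=None, fr=None, events=()):
    n = len(t)
    hold = 1.5
    samples = pd.DataFrame(
        {
            "t_s": t,
            "theta_rad": theta,
            "theta_d_rad": theta_d,
            "F_left_kgf": np.full(n, hold) if fl is None else fl,
            "F_right_kgf": np.full(n, hold) if fr is None else fr,
            "assist_level": np.zeros(n, dtype=int),
        }
    )
    meta = {
        "subject_id": "test",
        "session_date": "2024-01-01T10:00:00",
        "controller": {"tolerance": 0.10},
        "game": {"wagon_gain": 1.0 / math.radians(30.0)},
        "sensors": {},
    }
    return SessionLog(meta, samples, list(events))


def _minjerk_theta(t, t0, amplitude, duration):
    """Angle trace: rest, one minimum-jerk reach, rest."""
    tau = np.clip((t - t0) / duration, 0.0, 1.0)
    return amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


class TestDerivatives:
    def test_constant_angle_gives_zero_derivatives(self):
        th = np.full(400, 0.3)
        w, a, j = kinematic_derivatives(th, DT)
        assert np.allclose(w, 0) and np.allclose(a, 0) and np.allclose(j, 0)

    def test_linear_ramp_gives_constant_velocity(self):
        t = np.arange(0, 5, DT)
        w, a, j = kinematic_derivatives(0.4 * t, DT)
        inner = slice(30, -30)
        assert np.allclose(w[inner], 0.4, atol=1e-9)
        assert np.allclose(a[inner], 0.0, atol=1e-7)

    def test_sinusoid_peak_velocity_matches_analytic(self):
        t = np.arange(0, 12, DT)
        w, _, _ = kinematic_derivatives(np.sin(t), DT)
        # derivative cos(t) has unit peak; smoothing attenuates slightly
        assert np.abs(w[50:-50]).max() == pytest.approx(1.0, abs=0.01)

    def test_short_series_raises(self):
        with pytest.raises(ValueError):
            kinematic_derivatives(np.zeros(10), DT)


class TestSegmentation:
    def _reach_log(self, t_spawn=2.0, delay=0.7, amp=0.5, dur=2.0, horizon=8.0):
        t = np.arange(0.0, horizon, DT)
        theta = _minjerk_theta(t, t_spawn + delay, amp, dur)
        theta_d = np.where(t >= t_spawn, amp, 0.0)
        # consistent drive: press left (CCW) while moving
        speed = np.gradient(theta, DT)
        fl = 1.5 + 2.0 * speed / max(speed.max(), 1e-9)
        events = [(t_spawn, "spawn", {"crystal_x": -amp})]
        return _make_log(t, theta, theta_d, fl=fl, events=events)

    def test_reaction_time_recovered_from_known_onset(self):
        log = self._reach_log(t_spawn=2.0, delay=0.7)
        segs = segment_movements(log)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.completed
        # onset is the 5%-of-peak crossing of the minimum-jerk speed profile,
        # which lags the pulse start by ~0.06*duration
        expected_onset = 2.7 + 0.0595 * 2.0
        assert seg.T_i - seg.T_0 == pytest.approx(expected_onset - 2.0, abs=0.08)

    def test_landmarks_are_ordered(self):
        seg = segment_movements(self._reach_log())[0]
        assert seg.T_0 <= seg.T_i <= seg.T_d <= seg.T_f

    def test_unreached_target_marked_not_completed(self):
        log = self._reach_log(amp=0.5)
        log.samples["theta_d_rad"] = np.where(
            log.samples["t_s"] >= 2.0, 1.2, 0.0
        )  # target far beyond the actual motion
        segs = segment_movements(log)
        assert len(segs) == 1 and not segs[0].completed and segs[0].T_d is None

    def test_landmark_order_on_simulated_session(self, healthy_log):
        for seg in segment_movements(healthy_log):
            if seg.completed:
                assert seg.T_0 <= seg.T_i <= seg.T_d <= seg.T_f


class TestTimeParameters:
    def test_single_segment_arithmetic(self):
        seg = MovementSegment(
            T_0=0.0, T_i=0.5, T_d=2.0, T_f=3.0, direction=1, theta_d=0.3,
            t=np.arange(0, 3, DT), theta=np.zeros(240), theta_d_series=np.zeros(240),
            omega=np.zeros(240), jerk=np.zeros(240),
            F_left=np.zeros(240), F_right=np.zeros(240), completed=True,
        )
        tr, tm = time_parameters([seg])
        assert tr == pytest.approx(0.5) and tm == pytest.approx(2.5)

    def test_outlier_segment_excluded_from_means(self):
        def seg(tm):
            return MovementSegment(
                T_0=0.0, T_i=0.5, T_d=1.0, T_f=0.5 + tm, direction=1, theta_d=0.3,
                t=np.arange(0, 1, DT), theta=np.zeros(80), theta_d_series=np.zeros(80),
                omega=np.zeros(80), jerk=np.zeros(80),
                F_left=np.zeros(80), F_right=np.zeros(80), completed=True,
            )
        segs = [seg(x) for x in (2.4, 2.5, 2.6, 2.5, 25.0)]
        _, tm = time_parameters(segs)
        assert tm == pytest.approx(2.5, abs=0.01)


def _motion_segment(t, theta, omega, jerk=None, theta_d_series=None, direction=1):
    n = len(t)
    return MovementSegment(
        T_0=t[0], T_i=t[0], T_d=t[-1], T_f=t[-1], direction=direction, theta_d=0.0,
        t=t, theta=theta,
        theta_d_series=np.zeros(n) if theta_d_series is None else theta_d_series,
        omega=omega, jerk=np.zeros(n) if jerk is None else jerk,
        F_left=np.zeros(n), F_right=np.zeros(n), completed=True,
    )


class TestSpeedParameters:
    def test_constant_rotation_mean_equals_peak(self):
        t = np.arange(0, 2, DT)
        seg = _motion_segment(t, 0.3 * t, np.full_like(t, 0.3))
        wm, wp = speed_parameters(seg)
        assert wm == pytest.approx(0.3) and wp == pytest.approx(0.3)

    def test_triangular_profile_mean_is_half_peak(self):
        t = np.arange(0, 2, DT)
        v = 0.8
        omega = v * (1 - np.abs(t - 1.0))
        seg = _motion_segment(t, np.cumsum(omega) * DT, omega)
        wm, wp = speed_parameters(seg)
        assert wp == pytest.approx(v, abs=1e-9)
        assert wm == pytest.approx(v / 2, abs=0.01)

    def test_peak_at_least_mean(self, healthy_log):
        for seg in segment_movements(healthy_log):
            if seg.completed:
                wm, wp = speed_parameters(seg)
                assert wp >= wm >= 0


class TestSmoothness:
    def test_single_minimum_jerk_pulse_has_one_peak(self):
        t = np.arange(0, 2, DT)
        omega = 0.5 * np.asarray(minimum_jerk_speed(t / 2.0))
        seg = _motion_segment(t, np.cumsum(omega) * DT, omega)
        _, n_p = smoothness_parameters(seg)
        assert n_p == 1

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_k_separated_pulses_count_k_peaks(self, k):
        t = np.arange(0, k * 1.0, DT)
        omega = np.zeros_like(t)
        for j in range(k):
            tau = np.clip((t - j * 1.0) / 0.8, 0, 1)
            omega += 0.5 * np.asarray(minimum_jerk_speed(tau))
        seg = _motion_segment(t, np.cumsum(omega) * DT, omega)
        _, n_p = smoothness_parameters(seg)
        assert n_p == k

    def test_peak_count_invariant_to_amplitude_scaling(self):
        t = np.arange(0, 3, DT)
        omega = np.abs(np.sin(3 * t)) + 0.1
        for scale in (1.0, 7.5):
            seg = _motion_segment(t, np.cumsum(scale * omega) * DT, scale * omega)
            assert smoothness_parameters(seg)[1] == smoothness_parameters(
                _motion_segment(t, np.cumsum(omega) * DT, omega)
            )[1]

    def test_normalized_jerk_positive_and_zero_peak_raises(self):
        t = np.arange(0, 2, DT)
        omega = np.asarray(minimum_jerk_speed(t / 2.0))
        jerk = np.gradient(np.gradient(omega, DT), DT)
        seg = _motion_segment(t, np.cumsum(omega) * DT, omega, jerk=jerk)
        jn, _ = smoothness_parameters(seg)
        assert jn > 0
        still = _motion_segment(t, np.zeros_like(t), np.zeros_like(t))
        with pytest.raises(ValueError):
            smoothness_parameters(still)


class TestErrorParameter:
    def test_perfect_tracking_gives_zero(self):
        t = np.arange(0, 2, DT)
        th = 0.2 * t
        seg = _motion_segment(t, th, np.zeros_like(t), theta_d_series=th)
        assert error_parameter(seg) == 0.0

    def test_constant_offset_gives_its_magnitude(self):
        t = np.arange(0, 2, DT)
        seg = _motion_segment(
            t, np.full_like(t, 0.25), np.zeros_like(t),
            theta_d_series=np.full_like(t, 0.10),
        )
        assert error_parameter(seg) == pytest.approx(0.15, abs=1e-12)

    def test_sinusoidal_error_rms_is_amplitude_over_sqrt2(self):
        t = np.arange(0, 2 * np.pi, DT)  # whole periods of sin(t)
        e = 0.3
        seg = _motion_segment(
            t, e * np.sin(t), np.zeros_like(t), theta_d_series=np.zeros_like(t)
        )
        assert error_parameter(seg) == pytest.approx(e / math.sqrt(2), abs=1e-3)


class TestForceParameters:
    def _log_with_forces(self, fl, fr):
        n = len(fl)
        t = np.arange(n) * DT
        return _make_log(t, np.zeros(n), np.zeros(n), fl=fl, fr=fr)

    @staticmethod
    def _pulse_train(n, at, height):
        f = np.full(n, 1.5)
        for c in at:
            tau = np.clip((np.arange(n) - c) / 40.0 + 0.5, 0, 1)
            f += height * np.asarray(minimum_jerk_speed(tau)) / 1.875
        return f

    def test_identical_sides_have_zero_asymmetry(self):
        f = self._pulse_train(2000, [300, 900, 1500], 2.0)
        _, _, delta = force_parameters(self._log_with_forces(f, f.copy()))
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_sign_positive_when_left_peaks_higher(self):
        fl = self._pulse_train(2000, [300, 900, 1500], 1.5)  # peaks at 3.0 kgf
        fr = self._pulse_train(2000, [300, 900, 1500], 0.5)  # peaks at 2.0 kgf
        fpl, fpr, delta = force_parameters(self._log_with_forces(fl, fr))
        assert fpl == pytest.approx(3.0, abs=0.05)
        assert fpr == pytest.approx(2.0, abs=0.05)
        assert delta == pytest.approx(1.0, abs=0.1)

    def test_flat_side_marked_undefined(self):
        fl = self._pulse_train(2000, [300], 2.0)
        fr = np.full(2000, 1.5)
        fpl, fpr, delta = force_parameters(self._log_with_forces(fl, fr))
        assert fpr is None and delta is None and fpl is not None


class TestTorqueParameters:
    def test_symmetric_hold_gives_zero_torques(self):
        t = np.arange(0, 10, DT)
        log = _make_log(t, np.zeros_like(t), np.zeros_like(t))
        taus = torque_parameters(log, [])
        assert all(v is None for v in taus.values())

    def test_ccw_left_press_is_productive(self, geom):
        t = np.arange(0, 6, DT)
        theta = _minjerk_theta(t, 1.0, 0.5, 2.0)
        fl = 1.5 + 1.0 * np.asarray(minimum_jerk_speed((t - 1.0) / 2.0)) / 1.875
        fr = 1.5 - 0.4 * np.asarray(minimum_jerk_speed((t - 1.0) / 2.0)) / 1.875
        theta_d = np.where(t >= 0.5, 0.5, 0.0)
        log = _make_log(t, theta, theta_d, fl=fl, fr=fr,
                        events=[(0.5, "spawn", {"crystal_x": -0.5})])
        segs = segment_movements(log)
        taus = torque_parameters(log, segs, geom)
        assert taus["tau_p_left"] is not None and taus["tau_p_left"] > 0
        assert taus["tau_total"] is not None and taus["tau_total"] > 0
        assert taus["delta_tau"] is not None


class TestOutlierValidation:
    def test_iqr_fence_discards_extreme_value(self):
        kept, discarded = validate_outliers([2.4, 2.5, 2.6, 2.5, 25.0])
        assert discarded == [25.0]
        assert 25.0 not in kept

    def test_identical_values_all_kept(self):
        kept, discarded = validate_outliers([3.0] * 6)
        assert kept == [3.0] * 6 and discarded == []

    def test_small_samples_never_discarded(self):
        kept, discarded = validate_outliers([1.0, 100.0])
        assert discarded == [] and kept == [1.0, 100.0]

    def test_clean_sessions_discard_at_most_quarter(self, healthy_log):
        rep = session_report(healthy_log)
        assert rep.n_segments_discarded <= 0.25 * rep.n_segments_used


class TestSessionReport:
    def test_report_is_deterministic(self, healthy_log):
        a = session_report(healthy_log)
        b = session_report(healthy_log)
        assert a == b

    def test_empty_motion_log_marks_parameters_and_keeps_score(self):
        t = np.arange(0, 10, DT)
        log = _make_log(
            t, np.zeros_like(t), np.zeros_like(t),
            events=[(0.5, "spawn", {"crystal_x": 0.9}), (7.5, "lost", {})],
        )
        rep = session_report(log)
        assert rep.losses == 1 and rep.score == 0
        assert rep.T_m_s is None and rep.omega_m_rad_s is None

    def test_score_and_losses_come_from_events(self, stroke_log):
        rep = session_report(stroke_log)
        assert rep.score == stroke_log.metadata["score"]
        assert rep.losses == stroke_log.metadata["losses"]
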