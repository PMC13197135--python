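"""Kinematics chain: gravity cancellation, SG smoothing, ZUPT, integration."""

import numpy as np
import pytest

import esotransit as et
from esotransit.kinematics import (
    SmoothingParams,
    ZuptParams,
    compensate_gravity,
    compute_kinematics,
    detect_quasistatic,
    estimate_distance_uncertainty,
    integrate_displacement,
    integrate_velocity,
    smooth,
)
from esotransit.orientation import FilterParams, OrientationTrack, estimate_orientation


def _gt_track(log, gt):
    return OrientationTrack(times=log.times, quaternions=gt.true_quaternion)


class TestCompensateGravity:
    def test_static_zero_noise_cancels_exactly(self, static_log):
        log, gt = static_log
        a = compensate_gravity(log, _gt_track(log, gt))
        assert np.max(np.abs(a)) < 1e-6

    def test_matches_analytic_field_with_true_quaternions(self, seated_noiseless):
        _, log, gt = seated_noiseless
        a = compensate_gravity(log, _gt_track(log, gt))
        assert np.max(np.abs(a - gt.true_linear_accel)) < 1e-6

    def test_noisy_static_mean_within_clt_bound(self):
        sc = et.build_scenario(
            "stationary_banana",
            {
                "seed": 9,
                "cardiac_amplitude_m_s2": 0.0,
                "duration_s": 12.0,
                "noise": {
                    "accel_sigma": 0.05,
                    "gyro_sigma": 0.0,
                    "mag_sigma": 0.0,
                    "pressure_sigma": 0.0,
                },
            },
        )
        log, gt = et.generate_swallow(sc)
        a = compensate_gravity(log, _gt_track(log, gt))
        bound = 3 * 0.05 / np.sqrt(log.n_samples)
        assert np.all(np.abs(a.mean(axis=0)) < bound)

    def test_misaligned_lengths_rejected(self, static_log):
        log, gt = static_log
        track = OrientationTrack(times=log.times[:-1], quaternions=gt.true_quaternion[:-1])
        with pytest.raises(ValueError):
            compensate_gravity(log, track)


class TestSavitzkyGolay:
    def test_polynomial_reproduced_exactly(self):
        t = np.linspace(0, 5, 251)
        sig = 2.0 - 0.5 * t + 0.3 * t**2 - 0.04 * t**3
        out = smooth(sig, SmoothingParams(), 50.0)
        assert np.allclose(out, sig, atol=1e-9)

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=2000)
        y = smooth(x, SmoothingParams(), 50.0)
        assert np.var(y) < np.var(x)

    def test_impulse_response_preserves_dc(self):
        x = np.zeros(101)
        x[50] = 1.0
        y = smooth(x, SmoothingParams(), 50.0)
        assert np.sum(y) == pytest.approx(1.0, abs=1e-9)

    def test_window_shorter_than_signal_required(self):
        with pytest.raises(ValueError):
            smooth(np.zeros(5), SmoothingParams(), 50.0)


class TestQuasistaticDetection:
    def test_fully_static_log_is_one_segment(self, static_log):
        log, gt = static_log
        a = compensate_gravity(log, _gt_track(log, gt))
        segs = detect_quasistatic(a, log.gyro, log.times)
        assert len(segs) == 1
        s, e = segs[0]
        assert s <= 0.5 and e >= log.times[-1] - 0.5

    def test_seated_holds_detected_but_not_transit_interior(self, seated):
        _, log, gt = seated
        track = estimate_orientation(log)
        a = smooth(compensate_gravity(log, track), SmoothingParams(), 50.0)
        segs = detect_quasistatic(a, log.gyro, log.times)
        t_oral = gt.event_times["oral_initiation"]
        t_gastric = gt.event_times["gastric_entry"]
        assert any(s <= 0.5 and e >= t_oral - 0.6 for s, e in segs)  # oral hold
        assert any(e >= log.times[-1] - 0.5 for s, e in segs)  # gastric phase
        interior = [
            (s, e) for s, e in segs if s > t_oral + 1.0 and e < t_gastric - 1.0
        ]
        assert interior == []

    def test_supine_programmed_holds_found(self, supine):
        _, log, gt = supine
        a = smooth(
            compensate_gravity(log, _gt_track(log, gt)), SmoothingParams(), 50.0
        )
        segs = detect_quasistatic(a, log.gyro, log.times)
        t_entry = gt.event_times["esophageal_entry"]
        t_gastric = gt.event_times["gastric_entry"]
        interior = [(s, e) for s, e in segs if s > t_entry and e < t_gastric]
        assert len(interior) >= 3


class TestIntegration:
    def test_zero_accel_gives_zero_velocity(self):
        t = np.arange(500) / 50.0
        v = integrate_velocity(np.zeros((500, 3)), [(0.0, 1.0), (9.0, 9.98)], t)
        assert np.all(v == 0.0)

    def test_constant_bias_removed_by_end_anchors(self):
        """Closed-form ramp-subtraction oracle: a constant accelerometer bias
        integrates to a linear velocity ramp, which anchors at both ends
        remove almost entirely."""
        b, T, fs = 0.1, 10.0, 50.0
        t = np.arange(int(T * fs)) / fs
        a = np.zeros((len(t), 3))
        a[:, 0] = b
        v_raw = integrate_velocity(a, [], t, warnings_out=[])
        assert np.max(np.abs(v_raw)) == pytest.approx(b * t[-1], rel=1e-6)
        v = integrate_velocity(a, [(0.0, 1.0), (T - 1.0, t[-1])], t)
        assert np.max(np.abs(v)) < 0.05 * b * T

    def test_no_segments_records_warning(self):
        t = np.arange(200) / 50.0
        warnings_out = []
        integrate_velocity(np.ones((200, 3)), [], t, warnings_out)
        assert warnings_out and "drift" in warnings_out[0]

    def test_zero_velocity_gives_zero_displacement(self):
        t = np.arange(100) / 50.0
        d, path = integrate_displacement(np.zeros((100, 3)), t)
        assert np.all(d == 0.0) and path == 0.0

    def test_triangular_profile_closed_form_area(self):
        """Triangular speed profile: path = v_p * T / 2."""
        T, fs, v_p = 4.0, 50.0, 12.0
        t = np.arange(int(T * fs) + 1) / fs
        speed = v_p * (1.0 - np.abs(t - T / 2) / (T / 2))
        v = np.zeros((len(t), 3))
        v[:, 2] = -speed
        d, path = integrate_displacement(v, t)
        assert path == pytest.approx(v_p * T / 2, rel=0.01)

    def test_velocity_zero_at_every_anchor_midpoint(self, seated):
        _, log, _ = seated
        track = estimate_orientation(log)
        kin = compute_kinematics(log, track, uncertainty_K=None)
        for s, e in kin.zupt_segments:
            i = int(np.argmin(np.abs(log.times - 0.5 * (s + e))))
            assert np.allclose(kin.velocity_earth[i], 0.0, atol=1e-9)
        assert kin.path_length_cm >= kin.net_displacement_cm


class TestPipelineProperties:
    def test_noise_free_pipeline_discretization_bound(self, seated_noiseless):
        """True quaternions, no smoothing: path within 0.5 cm of truth."""
        _, log, gt = seated_noiseless
        a = compensate_gravity(log, _gt_track(log, gt))
        segs = detect_quasistatic(a, log.gyro, log.times)
        v = integrate_velocity(a, segs, log.times) * 100.0
        _, path = integrate_displacement(v, log.times, smoothing=None)
        assert path == pytest.approx(gt.true_path_length_cm, abs=0.5)

    def test_path_invariant_under_yaw_rotation(self):
        """Rotating the whole problem 30° about vertical leaves path length
        unchanged: exactly for the kinematics chain (true orientation), and
        nearly so through the full filter (whose magnetometer reference is
        re-projected from the running estimate, breaking exact equivariance
        at the tracking-error level)."""
        kin_paths, full_paths = [], []
        for yaw in (0.0, 30.0):
            sc = et.build_scenario(
                "seated_reference",
                {
                    "seed": 1,
                    "yaw_deg": yaw,
                    "cardiac_amplitude_m_s2": 0.0,
                    "noise": {
                        "accel_sigma": 0.0,
                        "gyro_sigma": 0.0,
                        "mag_sigma": 0.0,
                        "pressure_sigma": 0.0,
                    },
                },
            )
            log, gt = et.generate_swallow(sc)
            kin = compute_kinematics(log, _gt_track(log, gt), uncertainty_K=None)
            kin_paths.append(kin.path_length_cm)
            full = compute_kinematics(log, estimate_orientation(log), uncertainty_K=None)
            full_paths.append(full.path_length_cm)
        assert abs(kin_paths[0] - kin_paths[1]) < 0.1
        assert abs(full_paths[0] - full_paths[1]) < 1.0

    def test_seated_peak_speed_recovered(self, seated):
        _, log, gt = seated
        track = estimate_orientation(log)
        kin = compute_kinematics(log, track, uncertainty_K=None)
        true_peak = np.max(np.linalg.norm(gt.true_velocity, axis=1))
        assert kin.peak_speed_cm_s == pytest.approx(true_peak, rel=0.10)

    def test_zupt_reduces_gyro_bias_drift_at_least_threefold(self):
        """Supine preset with a 0.01 rad/s gyro bias: ZUPT-corrected path
        error is under a third of the uncorrected one."""
        sc = et.build_scenario(
            "supine_reference", {"seed": 3, "noise": {"gyro_bias": [0.01, 0.0, 0.0]}}
        )
        log, gt = et.generate_swallow(sc)
        track = estimate_orientation(log)
        a = smooth(compensate_gravity(log, track), SmoothingParams(), 50.0)
        segs = detect_quasistatic(a, log.gyro, log.times)
        v_corr = integrate_velocity(a, segs, log.times) * 100.0
        _, path_corr = integrate_displacement(v_corr, log.times, SmoothingParams())
        v_raw = integrate_velocity(a, [], log.times, warnings_out=[]) * 100.0
        _, path_raw = integrate_displacement(v_raw, log.times, SmoothingParams())
        truth = gt.true_path_length_cm
        assert abs(path_corr - truth) < abs(path_raw - truth) / 3.0


class TestDistanceUncertainty:
    def test_zero_noise_spread_is_degenerate(self, seated_noiseless):
        _, log, gt = seated_noiseless
        track = _gt_track(log, gt)
        a = compensate_gravity(log, track)
        segs = detect_quasistatic(a, log.gyro, log.times)
        unc = estimate_distance_uncertainty(log, track, segs, K=20, seed=0)
        assert unc < 0.5

    def test_uncertainty_grows_with_accel_noise(self):
        uncs = []
        for sigma in (0.05, 0.15):
            sc = et.build_scenario(
                "seated_reference", {"seed": 2, "noise": {"accel_sigma": sigma}}
            )
            log, _ = et.generate_swallow(sc)
            track = estimate_orientation(log)
            a = smooth(compensate_gravity(log, track), SmoothingParams(), 50.0)
            segs = detect_quasistatic(a, log.gyro, log.times)
            uncs.append(estimate_distance_uncertainty(log, track, segs, K=20, seed=0))
        assert uncs[1] > uncs[0]

    def test_requires_segments_and_enough_replicates(self, seated):
        _, log, _ = seated
        track = estimate_orientation(log)
        with pytest.raises(ValueError):
            estimate_distance_uncertainty(log, track, [], K=20, seed=0)
        with pytest.raises(ValueError):
            estimate_distance_uncertainty(log, track, [(0.0, 1.0)], K=5, seed=0)
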