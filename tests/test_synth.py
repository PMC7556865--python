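"""Generator contracts: determinism, exact kinematics, calibration,
pulsatility algebra and streak geometry."""

import numpy as np
import pytest

from oculoflow.core import ParameterError
from oculoflow.synth import (SimulationConfig, VesselSimConfig,
                             apply_eye_motion, apply_scan_distortion,
                             simulate_cell_video, simulate_vessel_kymograph)
from oculoflow import _sinusoid


class TestCellVideo:
    def test_identical_seeds_give_bit_identical_outputs(self):
        cfg = SimulationConfig(n_frames=8, n_cells=4, eye_motion_sigma_px=2,
                               motion_model="random_walk", step_sigma_um=0.4,
                               rng_seed=11)
        s1, t1 = simulate_cell_video(cfg)
        s2, t2 = simulate_cell_video(cfg)
        assert np.array_equal(s1.frames, s2.frames)
        assert np.array_equal(t1.positions_um, t2.positions_um)
        assert np.array_equal(t1.eye_shifts_px, t2.eye_shifts_px)

    def test_empty_field_has_no_cells_and_background_only(self):
        cfg = SimulationConfig(n_frames=3, n_cells=0, noise_sigma=0.0,
                               rng_seed=0)
        stack, truth = simulate_cell_video(cfg)
        assert truth.n_cells == 0
        # without noise or motion all frames equal the static background
        assert np.array_equal(stack.frames[0], stack.frames[1])

    def test_stationary_cells_have_zero_true_displacement(self):
        cfg = SimulationConfig(n_frames=20, n_cells=5, rng_seed=3)
        _, truth = simulate_cell_video(cfg)
        for c in range(truth.n_cells):
            assert truth.displacement_um(c, 0, -1) == 0.0

    def test_drift_displacement_is_exactly_speed_times_time(self):
        # 0.1 µm/s for 100 s -> 10 µm, exact kinematics for interior cells
        cfg = SimulationConfig(frame_shape=(256, 256), field_size_deg=7.53,
                               n_frames=11, frame_rate=0.1, n_cells=3,
                               motion_model="drift",
                               drift_velocity_um_s=(0.1, 0.0), rng_seed=5)
        _, truth = simulate_cell_video(cfg)
        h_um = cfg.field_um[0]
        for c in range(3):
            # the exact-kinematics invariant holds away from the clamping
            # boundary; all three cells start interior for this seed
            assert truth.positions_um[0, c, 0] < h_um - 20.0
            assert truth.displacement_um(c, 0, 10) == pytest.approx(10.0,
                                                                    abs=1e-9)

    def test_um_per_px_calibration_from_field_size(self):
        cfg = SimulationConfig(field_size_deg=5.0, um_per_deg=34.0,
                               frame_shape=(170, 170))
        assert cfg.um_per_px == pytest.approx(1.0)
        assert cfg.field_um == (pytest.approx(170.0), pytest.approx(170.0))

    def test_random_walk_msd_matches_monte_carlo(self):
        # mean squared displacement over N steps ~ 2 N sigma^2 (2-D walk,
        # per-axis sigma); Monte-Carlo oracle with independent draws
        sigma, n_steps, n_cells = 0.3, 100, 500
        cfg = SimulationConfig(frame_shape=(256, 256), field_size_deg=7.53,
                               n_frames=n_steps + 1, n_cells=n_cells,
                               motion_model="random_walk",
                               step_sigma_um=sigma, min_separation_um=1.0,
                               rng_seed=21)
        _, truth = simulate_cell_video(cfg)
        sq = [truth.displacement_um(c, 0, -1) ** 2
              for c in range(truth.n_cells)]
        rng = np.random.default_rng(12345)
        oracle = rng.normal(0, sigma, (20000, n_steps, 2)).sum(axis=1)
        oracle_msd = (oracle ** 2).sum(axis=1)
        se = np.std(sq, ddof=1) / np.sqrt(n_cells)
        assert abs(np.mean(sq) - oracle_msd.mean()) < 3 * se
        assert np.mean(sq) == pytest.approx(2 * n_steps * sigma ** 2,
                                            rel=0.15)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ParameterError):
            SimulationConfig(frame_shape=(0, 10))
        with pytest.raises(ParameterError):
            SimulationConfig(noise_sigma=-1)
        with pytest.raises(ParameterError):
            SimulationConfig(motion_model="teleport")


class TestEyeMotion:
    def test_zero_sigma_is_identity(self):
        cfg = SimulationConfig(n_frames=4, n_cells=2, rng_seed=1)
        stack, _ = simulate_cell_video(cfg)
        out, shifts = apply_eye_motion(stack, 0.0, np.random.default_rng(0))
        assert np.array_equal(out.frames, stack.frames)
        assert not shifts.any()

    def test_shifts_reproducible_with_fixed_seed(self):
        cfg = SimulationConfig(n_frames=6, n_cells=2, rng_seed=1)
        stack, _ = simulate_cell_video(cfg)
        _, s1 = apply_eye_motion(stack, 3.0, np.random.default_rng(42))
        _, s2 = apply_eye_motion(stack, 3.0, np.random.default_rng(42))
        assert np.array_equal(s1, s2)

    def test_shifts_are_negation_of_registration_estimate(self):
        from oculoflow.registration import estimate_shift
        cfg = SimulationConfig(n_frames=5, n_cells=3, rng_seed=2)
        stack, _ = simulate_cell_video(cfg)
        moved, shifts = apply_eye_motion(stack, 3.0,
                                         np.random.default_rng(7))
        for i in range(1, stack.n_frames):
            est = estimate_shift(moved.frames[i], stack.frames[i])
            assert np.array_equal(est, -shifts[i])


class TestScanDistortion:
    def test_zero_amplitude_is_identity(self):
        frame = np.random.default_rng(0).random((32, 48))
        assert np.array_equal(apply_scan_distortion(frame, 0.0), frame)

    def test_mapping_is_monotone_and_centre_fixed(self):
        x = _sinusoid.scan_positions(101, 0.7)
        assert np.all(np.diff(x) > 0)
        assert x[50] == pytest.approx(50.0)  # odd symmetry about the centre
        assert x[0] == pytest.approx(0.0)
        assert x[-1] == pytest.approx(100.0)

    def test_column_ramp_round_trip(self):
        from oculoflow.registration import desinusoid_frame
        ramp = np.tile(np.arange(64, dtype=float), (8, 1))
        rt = desinusoid_frame(apply_scan_distortion(ramp, 0.5), 0.5)
        assert np.abs(rt - ramp).max() < 0.5

    def test_amplitude_out_of_range_raises(self):
        frame = np.zeros((4, 4))
        with pytest.raises(ParameterError):
            apply_scan_distortion(frame, 1.5)
        with pytest.raises(ParameterError):
            apply_scan_distortion(frame, -0.1)


class TestVesselKymograph:
    def test_zero_velocity_streaks_are_horizontal(self):
        cfg = VesselSimConfig(true_velocity_mm_s=0.0, duration_s=0.2,
                              rng_seed=4)
        _, truth = simulate_vessel_kymograph(cfg)
        t = np.linspace(0, 0.2, 50)
        for t0, x0 in truth.streak_entries[:10]:
            x = truth.streak_position_um(t0, x0, t)
            assert np.ptp(x) == 0.0

    def test_velocity_sign_mirrors_streak_slope(self):
        t = np.linspace(0, 0.01, 20)
        for v0 in (8.0, 20.0):
            pos = simulate_vessel_kymograph(
                VesselSimConfig(true_velocity_mm_s=v0, rng_seed=1))[1]
            neg = simulate_vessel_kymograph(
                VesselSimConfig(true_velocity_mm_s=-v0, rng_seed=1))[1]
            up = np.diff(pos.streak_position_um(0.0, 20.0, t))
            dn = np.diff(neg.streak_position_um(0.0, 40.0, t))
            assert np.all(up > 0) and np.all(dn < 0)
            assert np.allclose(up, -dn)

    def test_truth_streak_regression_slope_equals_velocity(self):
        # least-squares slope of the noiseless (t, x) truth samples
        cfg = VesselSimConfig(true_velocity_mm_s=12.0, duration_s=0.3,
                              rng_seed=9)
        _, truth = simulate_vessel_kymograph(cfg)
        t0, x0 = truth.streak_entries[3]
        t = t0 + np.arange(40) / cfg.line_rate_hz
        x = truth.streak_position_um(t0, x0, t)
        slope_um_s = np.polyfit(t, x, 1)[0]
        assert slope_um_s * 1e-3 == pytest.approx(12.0, abs=1e-9)

    def test_pulsatile_velocity_averages_to_v0_over_whole_cycles(self):
        cfg = VesselSimConfig(true_velocity_mm_s=10.0,
                              pulsatility_fraction=0.3, duration_s=0.5,
                              rng_seed=2)
        _, truth = simulate_vessel_kymograph(cfg)
        cycles = 2
        span = cycles / truth.cardiac_freq_hz
        # displacement over an integer number of cycles / time = V0 exactly
        x1 = truth.streak_position_um(0.0, 0.0, np.array([span]))[0]
        assert x1 / span * 1e-3 == pytest.approx(10.0, abs=1e-12)

    def test_unresolvable_streaks_rejected(self):
        with pytest.raises(ParameterError):
            VesselSimConfig(true_velocity_mm_s=50.0, line_rate_hz=15000.0)
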