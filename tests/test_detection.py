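"""Detection contracts: label maps, both detector kinds, thresholding,
counting and density conversion."""

import numpy as np
import pytest

from conftest import CELL_D_PX, UM_PER_PX, detector_f1, make_annotated_frames
from oculoflow.core import ParameterError, ProbabilityMap
from oculoflow.detection import (DetectorConfig, DetectorModel, cell_density,
                                 count_cells, detect_centroids,
                                 make_label_map, predict_probability_map,
                                 train_detector)
from oculoflow.synth import SimulationConfig, simulate_cell_video


class TestLabelMap:
    def test_no_centroids_gives_zero_map(self):
        assert not make_label_map([], (32, 32), 6.0).any()

    def test_single_centroid_is_argmax(self):
        m = make_label_map([(10, 20)], (32, 32), 6.0)
        assert np.unravel_index(np.argmax(m), m.shape) == (10, 20)
        assert m.max() == pytest.approx(1.0)

    def test_two_centroids_three_sigma_apart_keep_both_maxima(self):
        sigma = 3.0
        m = make_label_map([(16, 10), (16, 10 + 9)], (32, 32),
                           radius_px=2 * sigma)
        assert m.max() <= 1.0
        # direct evaluation: both stamped positions are local maxima
        for c in (10, 19):
            patch = m[14:19, c - 2:c + 3]
            assert patch.max() == m[16, c]

    def test_out_of_bounds_centroid_raises(self):
        with pytest.raises(ParameterError):
            make_label_map([(40, 5)], (32, 32), 6.0)


class TestDetectors:
    def test_learned_detector_reaches_f1_on_held_out_frames(
            self, learned_detector, heldout_set):
        f1 = detector_f1(learned_detector, *heldout_set)
        assert f1 >= 0.90

    def test_classical_detector_reaches_same_f1_bar(
            self, classical_detector, heldout_set):
        f1 = detector_f1(classical_detector, *heldout_set)
        assert f1 >= 0.90

    def test_training_is_deterministic(self, training_set, learned_detector):
        frames, centroids = training_set
        targets = [make_label_map(c, frames[0].shape, CELL_D_PX / 2)
                   for c in centroids]
        again = train_detector(frames, targets,
                               DetectorConfig(cell_diameter_px=CELL_D_PX))
        assert np.array_equal(again.weights, learned_detector.weights)
        assert again.calib_center == learned_detector.calib_center

    def test_identical_frames_give_identical_maps(self, learned_detector):
        cfg = SimulationConfig(n_frames=1, n_cells=3, rng_seed=77)
        stack, _ = simulate_cell_video(cfg)
        m1 = predict_probability_map(learned_detector, stack.frames[0])
        m2 = predict_probability_map(learned_detector, stack.frames[0])
        assert np.array_equal(m1.values, m2.values)

    def test_prediction_invariant_to_intensity_offset(self, learned_detector,
                                                      classical_detector):
        cfg = SimulationConfig(n_frames=1, n_cells=3, rng_seed=78)
        stack, _ = simulate_cell_video(cfg)
        for model in (learned_detector, classical_detector):
            m1 = predict_probability_map(model, stack.frames[0])
            m2 = predict_probability_map(model, stack.frames[0] + 50.0)
            assert np.allclose(m1.values, m2.values)

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_pure_background_stays_below_half(self, learned_detector,
                                              classical_detector, seed):
        cfg = SimulationConfig(n_frames=1, n_cells=0, rng_seed=seed)
        stack, _ = simulate_cell_video(cfg)
        for model in (learned_detector, classical_detector):
            pmap = predict_probability_map(model, stack.frames[0])
            assert pmap.values.max() < 0.5

    def test_high_contrast_cell_peaks_near_truth(self, learned_detector):
        cfg = SimulationConfig(n_frames=1, n_cells=1, rng_seed=123)
        stack, truth = simulate_cell_video(cfg)
        pmap = predict_probability_map(learned_detector, stack.frames[0])
        peak = np.unravel_index(np.argmax(pmap.values), pmap.values.shape)
        true_px = truth.frame_positions(0)[0] / cfg.um_per_px
        assert np.hypot(peak[0] - true_px[0], peak[1] - true_px[1]) <= 3.0

    def test_model_save_load_round_trip(self, learned_detector, tmp_path):
        path = tmp_path / "model.pkl"
        learned_detector.save(path)
        loaded = DetectorModel.load(path)
        assert np.array_equal(loaded.weights, learned_detector.weights)
        assert (tmp_path / "model.pkl.json").exists()

    def test_empty_training_set_raises(self):
        with pytest.raises(ParameterError):
            train_detector([], [], DetectorConfig(kind="learned"))


def disk_map(shape, centre, radius, value=0.95):
    rr, cc = np.indices(shape)
    values = np.where(np.hypot(rr - centre[0], cc - centre[1]) <= radius,
                      value, 0.0)
    return ProbabilityMap(values, um_per_px=1.0)


class TestDetectCentroids:
    def test_all_zero_map_gives_no_detections(self):
        assert detect_centroids(ProbabilityMap(np.zeros((32, 32)))) == []

    def test_single_disk_centroid_recovered(self):
        pmap = disk_map((100, 100), (50, 60), radius=4)
        dets = detect_centroids(pmap, min_area_px=2)
        assert len(dets) == 1
        assert dets[0].row_um == pytest.approx(50, abs=0.5)
        assert dets[0].col_um == pytest.approx(60, abs=0.5)

    def test_disks_split_by_subthreshold_line_stay_separate(self):
        values = np.zeros((40, 40))
        values[10:20, 5:15] = 0.95
        values[10:20, 16:26] = 0.95
        values[10:20, 15] = 0.5  # subthreshold separator
        dets = detect_centroids(ProbabilityMap(values), min_area_px=2)
        assert len(dets) == 2

    def test_raising_threshold_never_increases_detections(self,
                                                          learned_detector):
        cfg = SimulationConfig(n_frames=1, n_cells=5, rng_seed=55)
        stack, _ = simulate_cell_video(cfg)
        pmap = predict_probability_map(learned_detector, stack.frames[0])
        counts = [len(detect_centroids(pmap, threshold=t, min_area_px=2))
                  for t in (0.5, 0.7, 0.9, 0.95, 0.99)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_min_area_filters_single_pixel_noise(self):
        values = np.zeros((32, 32))
        values[5, 5] = 0.99  # single-pixel spike
        values[20:24, 20:24] = 0.95
        dets = detect_centroids(ProbabilityMap(values), min_area_px=3)
        assert len(dets) == 1
        assert dets[0].area_px == 16


class TestCountsAndDensity:
    def test_constant_counts_average_to_constant(self):
        assert count_cells([5] * 25) == 5.0

    def test_alternating_counts_average(self):
        counts = [4 if i % 2 == 0 else 6 for i in range(25)]
        assert count_cells(counts) == pytest.approx(4.96)

    def test_too_few_frames_needs_explicit_override(self):
        with pytest.raises(ParameterError):
            count_cells([5] * 10)
        assert count_cells([5] * 10, allow_short=True) == 5.0

    def test_density_unit_convention(self):
        # 5 cells in a 170x170 µm field = 173.0 cells/mm²
        assert cell_density(5, (170.0, 170.0)) == pytest.approx(173.0,
                                                                abs=0.05)
        assert cell_density(0, (170.0, 170.0)) == 0.0

    def test_doubling_field_dimensions_quarters_density(self):
        d1 = cell_density(7, (100.0, 120.0))
        d2 = cell_density(7, (200.0, 240.0))
        assert d1 == pytest.approx(4 * d2)

    def test_zero_area_raises(self):
        with pytest.raises(ParameterError):
            cell_density(5, (0.0, 170.0))


class TestDetectorAgnosticism:
    def test_both_detectors_give_similar_counts(self, learned_detector,
                                                classical_detector):
        frames, centroids = make_annotated_frames(6, seed0=4000)
        counts = {}
        for name, model in (("learned", learned_detector),
                            ("classical", classical_detector)):
            n = sum(len(detect_centroids(predict_probability_map(
                model, f, um_per_px=UM_PER_PX))) for f in frames)
            counts[name] = n
        true_n = sum(len(c) for c in centroids)
        assert abs(counts["learned"] - true_n) <= 0.1 * true_n
        assert abs(counts["classical"] - true_n) <= 0.1 * true_n
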