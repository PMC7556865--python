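"""Tracking contracts: linking fidelity against truth identities, QC
flagging, and the displacement / confinement-ratio geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oculoflow.core import Detection, ParameterError, Track
from oculoflow.tracking import (confinement_ratio, displacement,
                                link_detections, motility_table,
                                normalize_traces, path_length, qc_tracks)


def detections_from_paths(paths_um, frame_interval=0.2):
    """paths_um: (n_frames, n_cells, 2) -> flat detection list."""
    dets = []
    n_frames, n_cells, _ = paths_um.shape
    for f in range(n_frames):
        for c in range(n_cells):
            dets.append(Detection(f, paths_um[f, c, 0], paths_um[f, c, 1],
                                  5, 1.0))
    return dets


class TestLinking:
    def test_single_cell_yields_single_complete_track(self):
        path = np.cumsum(np.full((30, 1, 2), 0.1), axis=0) + 50
        tracks = link_detections(detections_from_paths(path))
        assert len(tracks) == 1
        assert tracks[0].n_samples == 30

    def test_two_distant_cells_never_swap(self):
        rng = np.random.default_rng(0)
        steps = rng.normal(0, 0.5, (40, 2, 2))
        path = np.cumsum(steps, axis=0)
        path[:, 0] += (20, 20)
        path[:, 1] += (150, 150)  # >> 5x max_link_dist apart
        tracks = link_detections(detections_from_paths(path),
                                 max_link_dist_um=13.0)
        assert len(tracks) == 2
        for t in tracks:
            # each track stays near its own cell: no identity swaps
            assert np.ptp(t.rows_um) < 30

    def test_random_walk_cohort_links_match_truth_identities(self):
        # 20 cells, spacing >> per-frame step: >=95% of links correct
        rng = np.random.default_rng(1)
        n_frames, n_cells, step = 50, 20, 0.4
        start = np.stack(np.meshgrid(np.arange(4), np.arange(5)),
                         -1).reshape(-1, 2) * 40.0 + 20
        path = start[None] + np.cumsum(
            rng.normal(0, step, (n_frames, n_cells, 2)), axis=0)
        tracks = link_detections(detections_from_paths(path),
                                 max_link_dist_um=13.0)
        assert len(tracks) == n_cells
        correct = 0
        total = 0
        for t in tracks:
            # identity of the truth cell this track started on
            cid = int(np.argmin(np.hypot(*(start - t.positions()[0]).T)))
            truth_path = path[:, cid, :]
            correct += int(np.allclose(t.positions(),
                                       truth_path[:t.n_samples], atol=1e-9))
            total += 1
        assert correct / total >= 0.95

    def test_gap_tolerance_bridges_missing_frame(self):
        path = np.cumsum(np.full((10, 1, 2), 0.2), axis=0) + 30
        dets = [d for d in detections_from_paths(path) if d.frame_index != 5]
        no_gap = link_detections(dets, max_gap_frames=0)
        with_gap = link_detections(dets, max_gap_frames=1)
        assert len(no_gap) == 2
        assert len(with_gap) == 1


class TestQC:
    def test_constant_velocity_track_accepted(self):
        t = Track(0, np.arange(20.0), np.arange(20) * 0.5, np.zeros(20))
        assert qc_tracks([t])[0].qc_status == "accepted"

    def test_artificial_jump_is_flagged(self):
        rows = np.arange(20) * 0.5
        rows[10] += 20 * np.median(np.diff(rows))  # 20x median step
        t = Track(0, np.arange(20.0), rows, np.zeros(20))
        assert qc_tracks([t])[0].qc_status == "flagged"

    def test_few_correct_tracks_flagged_in_clean_simulation(self):
        rng = np.random.default_rng(2)
        start = np.stack(np.meshgrid(np.arange(4), np.arange(5)),
                         -1).reshape(-1, 2) * 40.0 + 20
        path = start[None] + np.cumsum(rng.normal(0, 0.4, (50, 20, 2)),
                                       axis=0)
        tracks = qc_tracks(link_detections(detections_from_paths(path)))
        flagged = sum(t.qc_status == "flagged" for t in tracks)
        assert flagged / len(tracks) <= 0.05

    def test_jump_factor_must_exceed_one(self):
        with pytest.raises(ParameterError):
            qc_tracks([], jump_factor=1.0)


class TestMotilityMetrics:
    def test_stationary_cell_has_zero_displacement(self):
        t = Track(0, np.arange(0, 101, 10.0), np.full(11, 5.0),
                  np.full(11, 7.0))
        assert displacement(t, 100.0) == 0.0

    def test_drift_displacement_recovers_speed_times_window(self):
        times = np.arange(0, 101, 1.0)
        t = Track(0, times, 0.1 * times, np.zeros_like(times))
        assert displacement(t, 100.0) == pytest.approx(10.0)

    def test_short_track_needs_explicit_override(self):
        t = Track(0, np.arange(0, 50, 10.0), np.arange(5.0), np.zeros(5))
        with pytest.raises(ParameterError):
            displacement(t, 100.0)
        with pytest.warns(UserWarning):
            d = displacement(t, 100.0, allow_short=True)
        assert d == pytest.approx(4.0)

    def test_confinement_straight_line_is_one(self):
        t = Track(0, np.arange(5) * 25.0, np.arange(5) * 2.0, np.zeros(5))
        assert confinement_ratio(t) == pytest.approx(1.0, abs=1e-9)

    def test_confinement_closed_loop_is_zero(self):
        t = Track(0, np.arange(5) * 25.0, np.array([0, 10, 10, 0, 0.0]),
                  np.array([0, 0, 10, 10, 0.0]))
        assert confinement_ratio(t) == pytest.approx(0.0, abs=1e-12)

    def test_confinement_l_path_is_sqrt2_over_2(self):
        t = Track(0, np.arange(3) * 50.0, np.array([0, 10, 10.0]),
                  np.array([0, 0, 10.0]))
        assert confinement_ratio(t) == pytest.approx(np.sqrt(2) / 2,
                                                     abs=1e-12)

    def test_zero_path_length_is_undefined_not_zero(self):
        t = Track(0, np.arange(0, 101, 10.0), np.full(11, 5.0),
                  np.full(11, 7.0))
        assert np.isnan(confinement_ratio(t, 100.0))

    def test_random_walk_mean_displacement_matches_monte_carlo(self):
        # truth-path cohort vs an independent Monte-Carlo expectation
        sigma, n_steps, n_cells = 0.3, 500, 500
        rng = np.random.default_rng(3)
        steps = rng.normal(0, sigma, (n_cells, n_steps, 2))
        ends = steps.sum(axis=1)
        disp = np.hypot(ends[:, 0], ends[:, 1])
        oracle_rng = np.random.default_rng(999)
        oracle = oracle_rng.normal(0, sigma, (50000, n_steps, 2)).sum(axis=1)
        oracle_mean = np.hypot(oracle[:, 0], oracle[:, 1]).mean()
        se = disp.std(ddof=1) / np.sqrt(n_cells)
        assert abs(disp.mean() - oracle_mean) < 3 * se


class TestNormalizeTraces:
    def test_first_point_is_origin(self):
        t = Track(0, np.arange(4.0), np.array([3, 4, 5, 6.0]),
                  np.array([7, 7, 8, 9.0]))
        trace = normalize_traces([t])[0]
        assert tuple(trace[0]) == (0.0, 0.0)

    def test_translation_invariance(self):
        times = np.arange(5.0)
        t1 = Track(0, times, np.arange(5.0), np.arange(5.0) * 2)
        t2 = Track(1, times, np.arange(5.0) + 40, np.arange(5.0) * 2 - 17)
        n1, n2 = normalize_traces([t1, t2])
        assert np.allclose(n1, n2)

    def test_max_radius_equals_max_displacement_from_start(self):
        rng = np.random.default_rng(4)
        rows = np.cumsum(rng.normal(0, 1, 30))
        cols = np.cumsum(rng.normal(0, 1, 30))
        t = Track(0, np.arange(30.0), rows, cols)
        trace = normalize_traces([t])[0]
        radius = np.hypot(trace[:, 0], trace[:, 1]).max()
        direct = max(np.hypot(rows[i] - rows[0], cols[i] - cols[0])
                     for i in range(30))
        assert radius == pytest.approx(direct)


class TestMetricInvariance:
    def _metrics(self, paths):
        tracks = link_detections(detections_from_paths(paths))
        table = motility_table(tracks, window_s=5.0, allow_short=True)
        return (table.displacement_um.to_numpy(),
                table.confinement_ratio.to_numpy())

    def test_metrics_invariant_under_translation_and_rotation(self):
        rng = np.random.default_rng(5)
        paths = np.cumsum(rng.normal(0, 0.5, (25, 6, 2)), axis=0)
        paths += np.array([[60, 60]]) + np.arange(6)[None, :, None] * 25
        d0, c0 = self._metrics(paths)
        translated = paths + np.array([17.0, -4.0])
        rotated = np.stack([-paths[..., 1], paths[..., 0]], axis=-1) + 300
        for other in (translated, rotated):
            d1, c1 = self._metrics(other)
            assert np.allclose(np.sort(d0), np.sort(d1))
            assert np.allclose(np.sort(c0), np.sort(c1), equal_nan=True)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=3, max_size=12))
    def test_confinement_ratio_never_exceeds_one(self, points):
        rows = np.array([p[0] for p in points])
        cols = np.array([p[1] for p in points])
        steps = np.hypot(np.diff(rows), np.diff(cols))
        if steps.sum() == 0:
            return
        t = Track(0, np.arange(len(points), dtype=float), rows, cols)
        ratio = confinement_ratio(t, window_s=len(points) - 1.0)
        assert ratio <= 1.0 + 1e-9
        assert path_length(t, window_s=len(points) - 1.0) >= displacement(
            t, window_s=len(points) - 1.0) - 1e-9
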