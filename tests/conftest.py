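"""Shared fixtures: synthetic frame sets and a session-scoped trained
detector (training is deterministic, so one model serves every test)."""

from __future__ import annotations

import numpy as np
import pytest

from oculoflow.detection import DetectorConfig, make_label_map, train_detector
from oculoflow.synth import SimulationConfig, simulate_cell_video

# all detection tests run at 1 µm/px (170 µm field over 170 px ~ the 5°
# field); cells are 13 µm = 13 px
UM_PER_PX = 1.0
CELL_D_PX = 13.0


def make_annotated_frames(n_frames: int, seed0: int, n_cells: int = 5,
                          shape: tuple[int, int] = (128, 128)):
    """Single-frame simulations with truth centroids in pixels."""
    frames, centroids = [], []
    for s in range(n_frames):
        cfg = SimulationConfig(frame_shape=shape, n_frames=1,
                               n_cells=n_cells, rng_seed=seed0 + s)
        stack, truth = simulate_cell_video(cfg)
        frames.append(stack.frames[0])
        centroids.append(truth.frame_positions(0) / cfg.um_per_px)
    return frames, centroids


@pytest.fixture(scope="session")
def training_set():
    return make_annotated_frames(20, seed0=100)


@pytest.fixture(scope="session")
def heldout_set():
    return make_annotated_frames(10, seed0=900)


@pytest.fixture(scope="session")
def learned_detector(training_set):
    frames, centroids = training_set
    targets = [make_label_map(c, frames[0].shape, radius_px=CELL_D_PX / 2)
               for c in centroids]
    return train_detector(frames, targets,
                          DetectorConfig(cell_diameter_px=CELL_D_PX))


@pytest.fixture(scope="session")
def classical_detector():
    return train_detector([], [], DetectorConfig(kind="classical",
                                                 cell_diameter_px=CELL_D_PX))


def detector_f1(model, frames, centroids, um_per_px=UM_PER_PX,
                radius_px=5.0):
    """Held-out F1 at the given match radius (greedy nearest-first)."""
    from oculoflow.detection import (detect_centroids, f1_score,
                                     match_detections,
                                     predict_probability_map)
    tp = fp = fn = 0
    for frame, cents in zip(frames, centroids):
        pmap = predict_probability_map(model, frame, um_per_px=um_per_px)
        dets = detect_centroids(pmap)
        a, b, c = match_detections(dets, np.asarray(cents) * um_per_px,
                                   radius_um=radius_px * um_per_px)
        tp, fp, fn = tp + a, fp + b, fn + c
    return f1_score(tp, fp, fn)
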