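"""Simulate a jittered retinal video, undo the scan distortion and eye
motion, and average frames.

Builds a 6-second synthetic video with cells, eye-motion jitter and
sinusoidal fast-axis distortion, then runs the correction chain and reports
how well the known shifts were recovered.
"""

import numpy as np

from oculoflow import (SimulationConfig, desinusoid_video, register_video,
                       simulate_cell_video, temporal_average)

config = SimulationConfig(
    n_frames=150,            # 6 s at 25 fps
    n_cells=6,
    eye_motion_sigma_px=3.0,
    scan_distortion_amplitude=0.2,
    noise_sigma=0.02,
    rng_seed=11,
)
stack, truth = simulate_cell_video(config)
print(f"simulated {stack.n_frames} frames at {config.um_per_px:.3f} um/px, "
      f"{truth.n_cells} cells")

stack = desinusoid_video(stack, config.scan_distortion_amplitude)
registered, shifts = register_video(stack, reference_index=0)
needed = -(truth.eye_shifts_px - truth.eye_shifts_px[0])
exact = np.all(shifts == needed, axis=1).mean()
print(f"eye-motion shifts recovered exactly for {100 * exact:.1f}% of "
      f"frames (sigma = 3 px jitter)")

averaged = temporal_average(registered, window=5)
print(f"5-frame averaging: {registered.n_frames} -> {averaged.n_frames} "
      f"frames, one every {averaged.frame_interval_s:.2f} s")
# near-100% exact recovery means detection runs on a stabilised scene;
# the averaged frames are what the cell detector consumes.
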