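"""Fast-axis sinusoidal scan mapping shared by the simulator and corrector.

A resonant scanner samples uniformly in time while the beam position follows
a sinusoid, so recorded columns correspond to non-uniform spatial positions.
The normalised mapping used here mixes linear and sinusoidal sampling:

    g(u) = (1 - a) * u + a * sin(pi * u / 2),   u in [-1, 1]

with amplitude ``a`` in [0, 1]. g is odd (the centre column maps to the
centre column), monotone increasing, and fixes the end points, so it is
invertible on the field.
"""

from __future__ import annotations

import numpy as np

from .core import ParameterError


def _check_amplitude(amplitude: float) -> float:
    amplitude = float(amplitude)
    if not 0.0 <= amplitude <= 1.0:
        raise ParameterError("scan distortion amplitude must lie in [0, 1]")
    return amplitude


def scan_positions(n_cols: int, amplitude: float) -> np.ndarray:
    """Spatial source position (in pixels) of each recorded column."""
    amplitude = _check_amplitude(amplitude)
    u = (2.0 * np.arange(n_cols) - (n_cols - 1)) / (n_cols - 1)
    g = (1.0 - amplitude) * u + amplitude * np.sin(np.pi * u / 2.0)
    return (g + 1.0) * (n_cols - 1) / 2.0


def distort(frame: np.ndarray, amplitude: float) -> np.ndarray:
    """Resample a uniformly sampled frame the way the scanner records it."""
    frame = np.asarray(frame, dtype=float)
    if _check_amplitude(amplitude) == 0.0:
        return frame.copy()
    x_src = scan_positions(frame.shape[1], amplitude)
    cols = np.arange(frame.shape[1], dtype=float)
    out = np.empty_like(frame)
    for i, row in enumerate(frame):
        out[i] = np.interp(x_src, cols, row)
    return out


def correct(frame: np.ndarray, amplitude: float) -> np.ndarray:
    """Inverse of :func:`distort`: resample back to uniform spatial sampling."""
    frame = np.asarray(frame, dtype=float)
    if _check_amplitude(amplitude) == 0.0:
        return frame.copy()
    x_src = scan_positions(frame.shape[1], amplitude)  # monotone increasing
    cols = np.arange(frame.shape[1], dtype=float)
    out = np.empty_like(frame)
    for i, row in enumerate(frame):
        out[i] = np.interp(cols, x_src, row)
    return out
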