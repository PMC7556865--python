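"""Eye-motion correction, de-sinusoiding and temporal averaging.

Residual eye motion in an anesthetised mouse is small and translational, so
frames are aligned to a reference by FFT cross-correlation with optional
sub-pixel (parabolic) refinement. Out-of-field pixels created by the shift
are filled with NaN sentinels and excluded from all downstream averages,
avoiding edge-darkening bias.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from . import _sinusoid
from .core import DegenerateInputError, ParameterError, VideoStack


def desinusoid_frame(frame: np.ndarray, amplitude: float) -> np.ndarray:
    """Undo the fast-axis sinusoidal scan distortion (uniform resampling).

    Exact inverse of :func:`oculoflow.synth.apply_scan_distortion` up to
    linear-interpolation error; ``amplitude=0`` is the identity. Note the
    mapping is not idempotent — correcting twice over-warps the image.
    """
    return _sinusoid.correct(frame, amplitude)


def desinusoid_video(stack: VideoStack, amplitude: float) -> VideoStack:
    """De-sinusoid every frame and advance the stack stage."""
    frames = np.stack([desinusoid_frame(f, amplitude) for f in stack.frames])
    return stack.advance_stage("desinusoided", frames=frames)


def estimate_shift(frame: np.ndarray, reference: np.ndarray,
                   upsample_factor: int = 1,
                   smooth_sigma_px: float = 5.0) -> np.ndarray:
    """Translation (drow, dcol) to apply to ``frame`` to align it to
    ``reference``, from the cross-correlation peak.

    Both images are low-passed (``smooth_sigma_px``) before correlation so
    the estimate anchors on the static coarse tissue background rather than
    on sparse bright cells — a few cells drifting coherently must read as
    cell motion, not as eye motion. With ``upsample_factor > 1`` the peak
    is refined to sub-pixel precision; the default integer estimate is
    exact for integer shifts of a textured scene.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise ParameterError("frame and reference must have the same shape")
    for name, img in (("frame", frame), ("reference", reference)):
        if np.nanstd(img) == 0:
            raise DegenerateInputError(f"{name} has zero variance")
    if smooth_sigma_px > 0:
        # periodic smoothing: consistent with the FFT correlation's own
        # periodicity, so integer shifts stay exactly recoverable
        frame = ndimage.gaussian_filter(frame, smooth_sigma_px, mode="wrap")
        reference = ndimage.gaussian_filter(reference, smooth_sigma_px,
                                            mode="wrap")
    shift, _, _ = phase_cross_correlation(
        reference, frame, upsample_factor=upsample_factor,
        normalization=None)
    return np.asarray(shift, dtype=float)


def _apply_shift(frame: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Translate a frame, filling out-of-field pixels with NaN."""
    if np.allclose(shift, np.rint(shift)):
        dr, dc = (int(round(s)) for s in shift)
        out = np.full_like(frame, np.nan)
        rows, cols = frame.shape
        r0, r1 = max(0, dr), min(rows, rows + dr)
        c0, c1 = max(0, dc), min(cols, cols + dc)
        out[r0:r1, c0:c1] = frame[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
        return out
    return ndimage.shift(frame, shift, order=1, mode="constant",
                         cval=np.nan)


def select_reference_frame(stack: VideoStack) -> int:
    """Median-sharpness frame within the first second of the stack.

    Robust to transient blinks or media opacity at either sharpness extreme.
    """
    n = min(stack.n_frames,
            max(1, int(round(1.0 / stack.frame_interval_s))))
    sharp = np.empty(n)
    for i in range(n):
        gy, gx = np.gradient(stack.frames[i])
        sharp[i] = np.nanvar(np.hypot(gy, gx))
    order = np.argsort(sharp, kind="stable")
    return int(order[len(order) // 2])


def register_video(
    stack: VideoStack,
    reference_index: int | None = None,
    upsample_factor: int = 1,
) -> tuple[VideoStack, np.ndarray]:
    """Align every frame to a reference frame by translation.

    Returns the registered stack (stage ``registered``, NaN out-of-field
    fill) and the per-frame ``(drow, dcol)`` shifts that were applied.
    """
    if stack.stage not in ("raw", "desinusoided"):
        raise ParameterError(
            f"cannot register a stack at stage {stack.stage!r}")
    if reference_index is None:
        reference_index = select_reference_frame(stack)
    if not 0 <= reference_index < stack.n_frames:
        raise ParameterError("reference index out of range")
    reference = stack.frames[reference_index]
    shifts = np.zeros((stack.n_frames, 2))
    frames = np.empty_like(stack.frames)
    for i, frame in enumerate(stack.frames):
        if i == reference_index:
            frames[i] = frame
            continue
        shifts[i] = estimate_shift(frame, reference,
                                   upsample_factor=upsample_factor)
        frames[i] = (_apply_shift(frame, shifts[i])
                     if np.any(shifts[i]) else frame)
    return stack.advance_stage("registered", frames=frames), shifts


def temporal_average(stack: VideoStack, window: int,
                     stride: int | None = None) -> VideoStack:
    """Running mean of ``window`` consecutive registered frames.

    Sentinel (NaN) pixels are excluded from each mean. Output timestamps are
    the centre times of each window; the number of output frames is
    ``floor((n - window) / stride) + 1``. ``stride`` defaults to ``window``
    (non-overlapping blocks, as used for the 5-frame pre-processing before
    detection); use ``stride=1`` for display-style running averages.
    """
    if stack.stage != "registered":
        raise ParameterError("temporal_average requires a registered stack")
    n = stack.n_frames
    if not 1 <= window <= n:
        raise ParameterError(f"window must lie in [1, {n}]")
    if stride is None:
        stride = window
    if stride < 1:
        raise ParameterError("stride must be >= 1")
    starts = np.arange(0, n - window + 1, stride)
    frames = np.empty((len(starts),) + stack.frame_shape)
    times = np.empty(len(starts))
    for j, s in enumerate(starts):
        block = stack.frames[s:s + window]
        valid = np.isfinite(block)
        n_valid = valid.sum(axis=0)
        total = np.where(valid, block, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frames[j] = np.where(n_valid > 0, total / n_valid, np.nan)
        times[j] = stack.timestamps[s:s + window].mean()
    return stack.advance_stage(
        "averaged", frames=frames, average_window=window,
        frame_interval_s=stack.frame_interval_s * stride,
        timestamps=times)
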