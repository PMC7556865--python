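"""Core data containers shared across the pipeline.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)``;
* physical coordinates are micrometres (µm), times are seconds from the
  first frame;
* video stacks are ``(n_frames, rows, cols)`` float arrays, kymographs are
  ``(space rows, time cols)`` with time running left to right;
* missing / out-of-field pixels are NaN sentinels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Allowed processing stages of a video stack, in order.
STAGES = ("raw", "desinusoided", "registered", "averaged")


class ParameterError(ValueError):
    """Invalid configuration or operation parameter."""


class DegenerateInputError(ValueError):
    """Input carries no usable signal (e.g. a constant frame)."""


class MeasurementError(RuntimeError):
    """A measurement could not be formed from the data (not a code bug)."""


@dataclass
class VideoStack:
    """Calibrated frame sequence.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity frames (float). NaN marks out-of-field pixels.
    um_per_px : float
        Spatial calibration, micrometres per pixel (isotropic).
    frame_interval_s : float
        Time between consecutive frames (1/25 s for 25 fps acquisition).
    stage : str
        One of :data:`STAGES`; transitions are forward-only.
    average_window : int, optional
        Number of raw frames averaged into each frame (set by
        :func:`oculoflow.registration.temporal_average`).
    timestamps : ndarray, optional
        Per-frame times in seconds; defaults to ``arange(T) * interval``.
    """

    frames: np.ndarray
    um_per_px: float
    frame_interval_s: float = 1.0 / 25.0
    stage: str = "raw"
    average_window: Optional[int] = None
    timestamps: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ParameterError("frames must be a (T, H, W) array")
        if self.um_per_px <= 0:
            raise ParameterError("um_per_px must be positive")
        if self.frame_interval_s <= 0:
            raise ParameterError("frame_interval_s must be positive")
        if self.stage not in STAGES:
            raise ParameterError(f"unknown stage {self.stage!r}")
        if self.timestamps is None:
            self.timestamps = np.arange(self.n_frames) * self.frame_interval_s
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (self.n_frames,):
                raise ParameterError("timestamps must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def advance_stage(self, new_stage: str, **updates) -> "VideoStack":
        """Return a copy at ``new_stage``; stages only move forward."""
        if STAGES.index(new_stage) < STAGES.index(self.stage):
            raise ParameterError(
                f"stage transition {self.stage} -> {new_stage} goes backwards"
            )
        return replace(self, stage=new_stage, **updates)


@dataclass
class Kymograph:
    """Space-time line-scan image.

    Rows are positions across the scan (µm/px), columns are successive
    line scans (1 / ``line_rate_hz`` apart). Moving cells appear as slanted
    streaks whose slope (rows per column) encodes velocity.
    """

    image: np.ndarray
    um_per_px: float
    line_rate_hz: float
    vessel_id: str = "vessel"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ParameterError("kymograph image must be 2-D")
        if self.um_per_px <= 0 or self.line_rate_hz <= 0:
            raise ParameterError("um_per_px and line_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.image.shape[1] / self.line_rate_hz


@dataclass
class ProbabilityMap:
    """Per-frame cell probability heat map, values in [0, 1].

    ``response`` optionally carries the detector's unbounded localisation
    map (the raw regression / matched-filter output). Probabilities can
    saturate at 1 over a cell's core, so centroids are weighted by the
    response when present to retain sub-pixel accuracy.
    """

    values: np.ndarray
    frame_index: int = 0
    um_per_px: float = 1.0
    response: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("probability map must be 2-D")
        if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 1:
            raise ParameterError("probability values must lie in [0, 1]")
        if self.response is not None:
            self.response = np.asarray(self.response, dtype=float)
            if self.response.shape != self.values.shape:
                raise ParameterError("response must match values in shape")


@dataclass
class Detection:
    """One detected cell in one frame (centroid in µm)."""

    frame_index: int
    row_um: float
    col_um: float
    area_px: int
    peak_prob: float
    cell_id: Optional[int] = None


@dataclass
class Track:
    """Time-ordered linkage of detections belonging to one cell."""

    cell_id: int
    times_s: np.ndarray
    rows_um: np.ndarray
    cols_um: np.ndarray
    qc_status: str = "accepted"  # accepted | flagged | rejected

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.rows_um = np.asarray(self.rows_um, dtype=float)
        self.cols_um = np.asarray(self.cols_um, dtype=float)
        if not (len(self.times_s) == len(self.rows_um) == len(self.cols_um)):
            raise ParameterError("track sample arrays must have equal length")
        if len(self.times_s) >= 2 and not np.all(np.diff(self.times_s) > 0):
            raise ParameterError("track times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.times_s)

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])

    def positions(self) -> np.ndarray:
        """(n, 2) array of (row_um, col_um)."""
        return np.column_stack([self.rows_um, self.cols_um])


@dataclass
class MotionContrastImage:
    """Per-pixel temporal-variation map (std / mean). Flow is bright."""

    image: np.ndarray
    um_per_px: float
    source_window: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if np.nanmin(self.image) < 0:
            raise ParameterError("motion contrast must be non-negative")


@dataclass
class VesselMeasurement:
    """Velocity, diameter and flow for one vessel at one timepoint."""

    vessel_id: str
    vessel_type: str  # "arteriole" | "venule"
    timepoint: str
    velocity_mm_s: float
    diameter_um: float
    flow_nl_s: float
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.vessel_type not in ("arteriole", "venule"):
            raise ParameterError("vessel_type must be 'arteriole' or 'venule'")
        if self.diameter_um <= 0:
            raise ParameterError("diameter must be positive")


#: Canonical ordering of the longitudinal study timepoints.
TIMEPOINTS = ("baseline", "6h", "24h", "72h", "10d")


@dataclass
class LongitudinalSeries:
    """Ordered per-timepoint measurements for one vessel."""

    vessel_id: str
    vessel_type: str
    measurements: Sequence[VesselMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [m.timepoint for m in self.measurements]
        if labels and labels[0] != "baseline":
            raise ParameterError("first timepoint must be 'baseline'")

    @property
    def baseline(self) -> VesselMeasurement:
        return self.measurements[0]
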