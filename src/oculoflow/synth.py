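"""Synthetic scanning-ophthalmoscope data with exact ground truth.

Emulates the observable content of label-free retinal videos — translucent
immune cells rendered as phase-contrast-like blobs (dark core, bright
annulus) drifting or wandering over a textured background, residual eye
motion between frames, sinusoidal fast-axis scan distortion, sensor noise —
and single-vessel line-scan kymographs in which passing blood cells leave
slanted streaks whose slope encodes velocity, with cardiac pulsatility.

Every generator records exact ground truth (sub-pixel cell centres per
frame, applied eye-motion shifts, streak velocities, lumen width) so each
downstream stage can be scored against truth without any external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from . import _sinusoid
from .core import Kymograph, ParameterError, VideoStack

# Default visual-angle scale: field sizes of 2-5 degrees correspond to
# 68-170 µm of retina, i.e. 34 µm per degree.
UM_PER_DEG = 34.0

MOTION_MODELS = ("stationary", "drift", "random_walk")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of a synthetic cell video.

    ``um_per_px`` is derived from the field size: a field of
    ``field_size_deg`` degrees spans ``field_size_deg * um_per_deg`` µm
    across ``frame_shape[1]`` columns.
    """

    field_size_deg: float = 3.76
    um_per_deg: float = UM_PER_DEG
    frame_shape: tuple[int, int] = (128, 128)
    frame_rate: float = 25.0
    n_frames: int = 100
    cell_diameter_um: float = 13.0
    n_cells: int = 5
    motion_model: str = "stationary"
    drift_velocity_um_s: tuple[float, float] = (0.0, 0.0)
    step_sigma_um: float = 0.0
    eye_motion_sigma_px: float = 0.0
    scan_distortion_amplitude: float = 0.0
    noise_sigma: float = 0.02
    cell_contrast: float = 0.35
    background_texture: float = 0.05
    min_separation_um: Optional[float] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.frame_shape
        if rows <= 0 or cols <= 0:
            raise ParameterError("frame dimensions must be positive")
        if self.field_size_deg <= 0 or self.um_per_deg <= 0:
            raise ParameterError("field size and scale must be positive")
        if self.n_frames <= 0:
            raise ParameterError("n_frames must be positive")
        if self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")
        if self.motion_model not in MOTION_MODELS:
            raise ParameterError(f"unknown motion model {self.motion_model!r}")
        for name in ("step_sigma_um", "eye_motion_sigma_px", "noise_sigma",
                     "background_texture"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.scan_distortion_amplitude <= 1.0:
            raise ParameterError("scan distortion amplitude must lie in [0, 1]")

    @property
    def um_per_px(self) -> float:
        return self.field_size_deg * self.um_per_deg / self.frame_shape[1]

    @property
    def field_um(self) -> tuple[float, float]:
        """(height, width) of the field in µm."""
        rows, cols = self.frame_shape
        return (rows * self.um_per_px, cols * self.um_per_px)


@dataclass
class GroundTruthCells:
    """Exact per-frame cell centres (µm), recorded before eye motion/noise."""

    positions_um: np.ndarray  # (n_frames, n_cells, 2) as (row, col)
    cell_ids: np.ndarray
    times_s: np.ndarray
    eye_shifts_px: Optional[np.ndarray] = None  # (n_frames, 2) applied shifts

    @property
    def n_cells(self) -> int:
        return self.positions_um.shape[1]

    @property
    def n_frames(self) -> int:
        return self.positions_um.shape[0]

    def displacement_um(self, cell: int, frame0: int = 0,
                        frame1: int = -1) -> float:
        """Euclidean displacement of one cell between two frames."""
        d = self.positions_um[frame1, cell] - self.positions_um[frame0, cell]
        return float(np.hypot(*d))

    def path_length_um(self, cell: int) -> float:
        steps = np.diff(self.positions_um[:, cell, :], axis=0)
        return float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))

    def frame_positions(self, frame: int) -> np.ndarray:
        """(n_cells, 2) centres in µm at one frame."""
        return self.positions_um[frame]

    def to_dataframe(self) -> pd.DataFrame:
        n_f, n_c, _ = self.positions_um.shape
        return pd.DataFrame({
            "frame": np.repeat(np.arange(n_f), n_c),
            "cell_id": np.tile(self.cell_ids, n_f),
            "row_um": self.positions_um[:, :, 0].ravel(),
            "col_um": self.positions_um[:, :, 1].ravel(),
        })


# ---------------------------------------------------------------------------
# cell video
# ---------------------------------------------------------------------------

def cell_profile(r: np.ndarray, diameter_px: float) -> np.ndarray:
    """Radial phase-contrast-like profile: dark core, bright annulus.

    Difference of Gaussians, negative at the centre and positive in a ring
    peaking near a quarter diameter; unit scale (multiply by contrast).
    """
    sigma_in = diameter_px / 8.0
    sigma_out = diameter_px / 4.0
    return (np.exp(-r ** 2 / (2 * sigma_out ** 2))
            - 2.0 * np.exp(-r ** 2 / (2 * sigma_in ** 2)))


def make_background(shape: tuple[int, int], texture_amp: float,
                    rng: np.random.Generator,
                    correlation_px: float = 8.0) -> np.ndarray:
    """Band-limited texture emulating out-of-focus backscatter, mean 1.

    The correlation length is coarse relative to a cell so the texture gives
    registration something to lock onto without mimicking cell-scale blobs.
    """
    bg = np.ones(shape)
    if texture_amp > 0:
        tex = ndimage.gaussian_filter(rng.standard_normal(shape),
                                      sigma=correlation_px)
        sd = tex.std()
        if sd > 0:
            bg += texture_amp * tex / sd
    return bg


def _initial_positions(config: SimulationConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Random cell centres (µm) with a minimum pairwise separation."""
    h_um, w_um = config.field_um
    margin = config.cell_diameter_um / 2.0
    min_sep = (config.min_separation_um if config.min_separation_um is not None
               else 1.6 * config.cell_diameter_um)
    if h_um <= 2 * margin or w_um <= 2 * margin:
        raise ParameterError("field too small for the configured cell size")
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < config.n_cells:
        cand = np.array([rng.uniform(margin, h_um - margin),
                         rng.uniform(margin, w_um - margin)])
        if all(np.hypot(*(cand - p)) >= min_sep for p in placed):
            placed.append(cand)
        attempts += 1
        if attempts > 20000:
            raise ParameterError(
                "could not place cells at the requested density/separation")
    return (np.array(placed) if placed
            else np.empty((0, 2)))


def _trajectories(config: SimulationConfig, start_um: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """(n_frames, n_cells, 2) true centres in µm, clamped at field edges."""
    n_f, n_c = config.n_frames, config.n_cells
    dt = 1.0 / config.frame_rate
    pos = np.empty((n_f, n_c, 2))
    pos[0] = start_um
    if config.motion_model == "stationary":
        pos[:] = start_um[None, :, :]
    elif config.motion_model == "drift":
        v = np.asarray(config.drift_velocity_um_s, dtype=float)
        t = np.arange(n_f)[:, None, None] * dt
        pos = start_um[None, :, :] + v[None, None, :] * t
    else:  # random_walk
        steps = rng.normal(0.0, config.step_sigma_um, size=(n_f - 1, n_c, 2))
        pos[1:] = start_um[None, :, :] + np.cumsum(steps, axis=0)
    h_um, w_um = config.field_um
    pos[..., 0] = np.clip(pos[..., 0], 0.0, h_um - config.um_per_px)
    pos[..., 1] = np.clip(pos[..., 1], 0.0, w_um - config.um_per_px)
    return pos


def render_cells(frame: np.ndarray, centres_um: np.ndarray, um_per_px: float,
                 diameter_um: float, contrast: float) -> None:
    """Stamp cell profiles onto ``frame`` in place (centres in µm)."""
    d_px = diameter_um / um_per_px
    half = int(np.ceil(1.5 * d_px))
    rows, cols = frame.shape
    for r_um, c_um in np.atleast_2d(centres_um):
        r_px, c_px = r_um / um_per_px, c_um / um_per_px
        r0, r1 = max(0, int(r_px) - half), min(rows, int(r_px) + half + 1)
        c0, c1 = max(0, int(c_px) - half), min(cols, int(c_px) + half + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1),
                             indexing="ij")
        r = np.hypot(rr - r_px, cc - c_px)
        frame[r0:r1, c0:c1] += contrast * cell_profile(r, d_px)


def simulate_cell_video(
    config: SimulationConfig,
) -> tuple[VideoStack, GroundTruthCells]:
    """Render a calibrated synthetic cell video plus exact ground truth.

    Rendering order mirrors acquisition: the clean scene is drawn, eye
    motion translates whole frames, the fast-axis sinusoidal distortion
    resamples columns, and sensor noise is added last. Ground truth records
    sub-pixel centres of the clean scene and the applied eye shifts.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_f = config.n_frames
    background = make_background(config.frame_shape, config.background_texture,
                                 rng)
    start = _initial_positions(config, rng)
    if config.n_cells > 0:
        pos = _trajectories(config, start, rng)
    else:
        pos = np.empty((n_f, 0, 2))

    frames = np.empty((n_f,) + tuple(config.frame_shape))
    for i in range(n_f):
        frame = background.copy()
        if config.n_cells:
            render_cells(frame, pos[i], config.um_per_px,
                         config.cell_diameter_um, config.cell_contrast)
        frames[i] = frame

    stack = VideoStack(frames, um_per_px=config.um_per_px,
                       frame_interval_s=1.0 / config.frame_rate, stage="raw")
    stack, shifts = apply_eye_motion(stack, config.eye_motion_sigma_px, rng)
    if config.scan_distortion_amplitude > 0:
        distorted = np.stack([
            _sinusoid.distort(f, config.scan_distortion_amplitude)
            for f in stack.frames
        ])
        stack = dataclasses.replace(stack, frames=distorted)
    if config.noise_sigma > 0:
        stack = dataclasses.replace(
            stack,
            frames=stack.frames + rng.normal(0.0, config.noise_sigma,
                                             stack.frames.shape))

    truth = GroundTruthCells(
        positions_um=pos,
        cell_ids=np.arange(config.n_cells),
        times_s=np.arange(n_f) / config.frame_rate,
        eye_shifts_px=shifts,
    )
    return stack, truth


def apply_eye_motion(
    stack: VideoStack, sigma_px: float, rng: np.random.Generator,
) -> tuple[VideoStack, np.ndarray]:
    """Translate each frame by an integer-rounded Gaussian draw.

    Shifts are applied periodically (wrap-around) so the truth is exactly
    invertible; the returned per-frame ``(drow, dcol)`` shifts are the
    negation of what registration must estimate.
    """
    if sigma_px < 0:
        raise ParameterError("eye motion sigma must be >= 0")
    n = stack.n_frames
    if sigma_px == 0:
        return stack, np.zeros((n, 2), dtype=int)
    shifts = np.rint(rng.normal(0.0, sigma_px, size=(n, 2))).astype(int)
    frames = np.stack([np.roll(f, tuple(s), axis=(0, 1))
                       for f, s in zip(stack.frames, shifts)])
    return dataclasses.replace(stack, frames=frames), shifts


def apply_scan_distortion(frame: np.ndarray, amplitude: float) -> np.ndarray:
    """Resample a frame's fast axis (columns) as a resonant scanner records it.

    ``amplitude=0`` is the identity; the mapping is odd-symmetric about the
    centre column, monotone and invertible (see
    :func:`oculoflow.registration.desinusoid_frame` for the inverse).
    """
    return _sinusoid.distort(frame, amplitude)


# ---------------------------------------------------------------------------
# vessel kymographs
# ---------------------------------------------------------------------------

@dataclass
class VesselSimConfig:
    """Parameters of a synthetic single-vessel line-scan kymograph.

    Velocity follows ``v(t) = V0 * (1 + m * sin(2*pi*f_c*t))`` with
    pulsatility fraction ``m < 1`` (sign of the flow never reverses).
    """

    true_velocity_mm_s: float = 10.0
    lumen_diameter_um: float = 40.0
    line_rate_hz: float = 15000.0
    duration_s: float = 0.5
    um_per_px: float = 1.0
    pulsatility_fraction: float = 0.0
    cardiac_freq_hz: float = 6.0
    streak_density_per_100ms: float = 40.0
    streak_sigma_um: float = 3.0
    noise_sigma: float = 0.03
    margin_um: float = 12.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.line_rate_hz <= 0 or self.duration_s <= 0:
            raise ParameterError("line rate and duration must be positive")
        if self.um_per_px <= 0 or self.lumen_diameter_um <= 0:
            raise ParameterError("scales must be positive")
        if not 0.0 <= self.pulsatility_fraction < 1.0:
            raise ParameterError("pulsatility fraction must lie in [0, 1)")
        if self.noise_sigma < 0 or self.streak_density_per_100ms < 0:
            raise ParameterError("noise and streak density must be >= 0")
        # Streaks must advance by less than their own width per line scan,
        # otherwise they degenerate into disconnected dots.
        peak_um_per_line = (abs(self.true_velocity_mm_s) * 1e3
                            * (1 + self.pulsatility_fraction)
                            / self.line_rate_hz)
        if peak_um_per_line >= self.streak_sigma_um:
            raise ParameterError(
                "line rate too low to resolve streaks at this velocity")


@dataclass
class VesselTruth:
    """Exact generative parameters of a simulated kymograph."""

    velocity_mm_s: float
    pulsatility_fraction: float
    cardiac_freq_hz: float
    lumen_diameter_um: float
    streak_entries: list  # (t_entry_s, x_entry_um) per streak
    band_start_um: float
    band_stop_um: float

    def velocity_at(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous velocity v(t) in mm/s."""
        t = np.asarray(t, dtype=float)
        return self.velocity_mm_s * (
            1.0 + self.pulsatility_fraction
            * np.sin(2 * np.pi * self.cardiac_freq_hz * t))

    def streak_position_um(self, t_entry: float, x_entry: float,
                           t: np.ndarray) -> np.ndarray:
        """Closed-form streak position x(t) in µm (velocity integral)."""
        t = np.asarray(t, dtype=float)
        v0 = self.velocity_mm_s * 1e3  # µm/s
        m, f = self.pulsatility_fraction, self.cardiac_freq_hz
        lin = v0 * (t - t_entry)
        if m > 0:
            w = 2 * np.pi * f
            lin = lin + v0 * m / w * (np.cos(w * t_entry) - np.cos(w * t))
        return x_entry + lin


def simulate_vessel_kymograph(
    config: VesselSimConfig,
) -> tuple[Kymograph, VesselTruth]:
    """Render a space-time image of blood-cell streaks crossing a lumen.

    Rows are position (µm/px), columns are successive line scans. Each cell
    enters at one lumen edge and leaves a Gaussian streak along its exact
    trajectory; the lumen is a brighter band of the true width.
    """
    rng = np.random.default_rng(config.rng_seed)
    d, margin = config.lumen_diameter_um, config.margin_um
    extent_um = d + 2 * margin
    n_rows = int(round(extent_um / config.um_per_px))
    n_cols = int(round(config.duration_s * config.line_rate_hz))
    band_lo, band_hi = margin, margin + d

    t_cols = np.arange(n_cols) / config.line_rate_hz
    rows_um = (np.arange(n_rows) + 0.5) * config.um_per_px

    image = np.full((n_rows, n_cols), 0.1)
    band_mask = np.clip(0.5 + (np.minimum(rows_um - band_lo,
                                          band_hi - rows_um))
                        / config.um_per_px, 0.0, 1.0)
    image += 0.15 * band_mask[:, None]

    v0 = config.true_velocity_mm_s
    n_streaks = rng.poisson(config.streak_density_per_100ms
                            * config.duration_s / 0.1)
    t_entries = np.sort(rng.uniform(-0.05, config.duration_s,
                                    size=n_streaks))
    truth = VesselTruth(
        velocity_mm_s=v0,
        pulsatility_fraction=config.pulsatility_fraction,
        cardiac_freq_hz=config.cardiac_freq_hz,
        lumen_diameter_um=d,
        streak_entries=[],
        band_start_um=band_lo,
        band_stop_um=band_hi,
    )

    sigma_px = config.streak_sigma_um / config.um_per_px
    rows_px = np.arange(n_rows)
    for t0 in t_entries:
        if v0 > 0:
            x0 = band_lo
        elif v0 < 0:
            x0 = band_hi
        else:
            x0 = rng.uniform(band_lo + 2, band_hi - 2)
        truth.streak_entries.append((float(t0), float(x0)))
        x_um = truth.streak_position_um(t0, x0, t_cols)
        active = (t_cols >= t0) & (x_um >= band_lo) & (x_um <= band_hi)
        if v0 == 0:  # stationary scatterer: finite dwell time
            active &= t_cols <= t0 + rng.exponential(0.03)
        cols_idx = np.nonzero(active)[0]
        if cols_idx.size == 0:
            continue
        x_px = x_um[cols_idx] / config.um_per_px - 0.5
        prof = np.exp(-(rows_px[:, None] - x_px[None, :]) ** 2
                      / (2 * sigma_px ** 2))
        image[:, cols_idx] += 0.6 * prof

    if config.noise_sigma > 0:
        image += rng.normal(0.0, config.noise_sigma, image.shape)

    kymo = Kymograph(image, um_per_px=config.um_per_px,
                     line_rate_hz=config.line_rate_hz)
    return kymo, truth


# ---------------------------------------------------------------------------
# vessel videos for motion contrast / diametry
# ---------------------------------------------------------------------------

def simulate_vessel_video(
    lumen_diameter_um: float,
    *,
    angle_deg: float = 0.0,
    frame_shape: tuple[int, int] = (96, 96),
    n_frames: int = 40,
    um_per_px: float = 0.9,
    flow_contrast: float = 0.30,
    static_contrast: float = 0.05,
    noise_sigma: float = 0.01,
    rng_seed: int = 0,
) -> tuple[VideoStack, dict]:
    """Registered-stage video of a vessel band with flowing blood.

    Pixels inside the lumen band decorrelate from frame to frame (moving
    scatterers); the surround carries a static texture. The band edge is
    anti-aliased over one pixel so the half-maximum of the temporal-contrast
    profile falls on the true lumen edge.
    """
    if lumen_diameter_um <= 0:
        raise ParameterError("lumen diameter must be positive")
    rng = np.random.default_rng(rng_seed)
    rows, cols = frame_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    theta = np.deg2rad(angle_deg)
    # perpendicular distance (px) from the vessel centreline through centre
    d_perp = np.abs(-(cc - (cols - 1) / 2) * np.sin(theta)
                    + (rr - (rows - 1) / 2) * np.cos(theta))
    half_px = lumen_diameter_um / um_per_px / 2.0
    mask = np.clip(0.5 + (half_px - d_perp), 0.0, 1.0)

    static = ndimage.gaussian_filter(rng.standard_normal(frame_shape), 1.5)
    static *= static_contrast / max(static.std(), 1e-12)

    frames = np.empty((n_frames, rows, cols))
    for i in range(n_frames):
        flow = ndimage.gaussian_filter(rng.standard_normal(frame_shape), 1.0)
        flow *= flow_contrast / max(flow.std(), 1e-12)
        frames[i] = 1.0 + mask * flow + (1.0 - mask) * static
        if noise_sigma > 0:
            frames[i] += rng.normal(0.0, noise_sigma, frame_shape)

    stack = VideoStack(frames, um_per_px=um_per_px, stage="registered")
    truth = {"lumen_diameter_um": lumen_diameter_um, "angle_deg": angle_deg,
             "mask": mask}
    return stack, truth


# ---------------------------------------------------------------------------
# conserved-flow longitudinal cohort
# ---------------------------------------------------------------------------

def simulate_conserved_cohort(
    *,
    n_replicates: int = 6,
    timepoints: tuple[str, ...] = ("baseline", "6h", "24h", "72h", "10d"),
    flow_change_pct: tuple[float, ...] = (0.0, 30.0, 67.0, 25.0, 10.0),
    biological_scale_sd: float = 0.4,
    physiological_sd: float = 0.15,
    noise_frac: float = 0.05,
    venule_baseline: tuple[float, float] = (10.0, 40.0),  # (V mm/s, D µm)
    arteriole_diameter_um: float = 25.0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Paired arteriole/venule longitudinal cohort with conserved flow.

    Within each replicate and timepoint the arteriole and venule share the
    *same* true flow change (conservation through the vascular bed); the
    venule realises it by dilation at constant velocity, the arteriole by a
    velocity increase at constant diameter. The magnitude of the shared
    inflammatory change varies biologically per replicate and visit
    (``biological_scale_sd``, relative; a peak flow change of +67% with a
    ±27% cohort SD corresponds to ~0.4), and on top of it the whole bed's
    flow fluctuates between imaging sessions (``physiological_sd``,
    multiplicative per replicate x visit — cardiac output and anesthesia
    depth vary, and since it is real flow it is shared by both vessels).
    Measured velocities carry multiplicative Gaussian noise of
    ``noise_frac``.
    """
    from .velocimetry import compute_flow

    if len(flow_change_pct) != len(timepoints):
        raise ParameterError("flow_change_pct must match timepoints")
    rng = np.random.default_rng(rng_seed)
    v_ven0, d_ven0 = venule_baseline
    q0 = compute_flow(v_ven0, d_ven0)
    v_art0 = q0 / (np.pi / 4.0 * (arteriole_diameter_um * 1e-3) ** 2 * 1e3)

    records = []
    for rep in range(n_replicates):
        for tp, dq_pct in zip(timepoints, flow_change_pct):
            scale = max(rng.normal(1.0, biological_scale_sd), 0.0)
            session = max(rng.normal(1.0, physiological_sd), 0.1)
            ratio = (1.0 + scale * dq_pct / 100.0) * session
            # venule: dilation-dominated; arteriole: velocity-dominated
            specs = [
                ("venule", v_ven0, d_ven0 * np.sqrt(ratio)),
                ("arteriole", v_art0 * ratio, arteriole_diameter_um),
            ]
            for vtype, v_true, d_true in specs:
                v_meas = v_true * (1.0 + (rng.normal(0.0, noise_frac)
                                          if noise_frac > 0 else 0.0))
                records.append({
                    "replicate": rep,
                    "vessel_type": vtype,
                    "timepoint": tp,
                    "velocity_mm_s": v_meas,
                    "diameter_um": d_true,
                    "flow_nl_s": compute_flow(v_meas, d_true),
                    "velocity_true_mm_s": v_true,
                    "flow_true_nl_s": compute_flow(v_true, d_true),
                })
    return pd.DataFrame.from_records(records)
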