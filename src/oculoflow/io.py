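"""File formats: multi-page TIFF videos, kymographs, CSV tables, JSON truth.

Conventions (repeated in every CSV header comment): pixel coordinates are
0-based (row, col); physical coordinates are µm; times are seconds from the
first frame; velocities mm/s; flows nL/s; densities cells/mm².
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .core import Detection, Kymograph, ParameterError, Track, VideoStack
from .synth import GroundTruthCells

_CAL_FIELDS = ("um_per_px", "frame_interval_s")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_video(stack: VideoStack, path: str | Path) -> None:
    """Multi-page grayscale TIFF plus a JSON calibration sidecar.

    Integer input dtypes are preserved bit-exactly; float frames are stored
    as 32-bit floats.
    """
    path = Path(path)
    frames = stack.frames
    if not np.issubdtype(frames.dtype, np.integer):
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {
        "um_per_px": stack.um_per_px,
        "frame_interval_s": stack.frame_interval_s,
        "stage": stack.stage,
        "average_window": stack.average_window,
        "timestamps_s": [float(t) for t in stack.timestamps],
    }
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=2)


def read_video(path: str | Path, calibration: dict | None = None) -> VideoStack:
    """Load a multi-page grayscale TIFF as a calibrated VideoStack.

    Calibration (µm/px, frame interval) comes from the JSON sidecar written
    by :func:`write_video`, or from the ``calibration`` dict. 8/16-bit
    integer data are accepted and promoted to float; RGB input and stacks
    with mismatched page shapes are rejected.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise ParameterError(
                f"pages have mismatched shapes {sorted(shapes)}")
        if any(page.samplesperpixel != 1 for page in tif.pages):
            raise ParameterError(
                "expected grayscale pages; RGB/multichannel TIFF "
                "not supported")
        frames = tif.asarray()
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ParameterError(
            "expected grayscale pages; RGB/multichannel TIFF not supported")
    meta: dict = {}
    if _sidecar(path).exists():
        with open(_sidecar(path)) as fh:
            meta = json.load(fh)
    if calibration:
        meta.update(calibration)
    missing = [f for f in _CAL_FIELDS if f not in meta]
    if missing:
        raise ParameterError(
            f"missing calibration fields {missing}; provide a "
            f"{_sidecar(path).name} sidecar or a calibration dict")
    timestamps = meta.get("timestamps_s")
    return VideoStack(
        frames=frames.astype(float) if not np.issubdtype(
            frames.dtype, np.floating) else frames,
        um_per_px=float(meta["um_per_px"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        stage=meta.get("stage", "raw"),
        average_window=meta.get("average_window"),
        timestamps=np.asarray(timestamps, dtype=float)
        if timestamps is not None else None,
    )


def write_kymograph(kymo: Kymograph, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, kymo.image.astype(np.float32),
                     photometric="minisblack")
    with open(_sidecar(path), "w") as fh:
        json.dump({"um_per_px": kymo.um_per_px,
                   "line_rate_hz": kymo.line_rate_hz,
                   "vessel_id": kymo.vessel_id}, fh, indent=2)


def read_kymograph(path: str | Path) -> Kymograph:
    path = Path(path)
    image = tifffile.imread(path)
    if not _sidecar(path).exists():
        raise ParameterError(
            f"missing calibration sidecar {_sidecar(path).name} "
            "(um_per_px, line_rate_hz)")
    with open(_sidecar(path)) as fh:
        meta = json.load(fh)
    return Kymograph(image.astype(float), um_per_px=float(meta["um_per_px"]),
                     line_rate_hz=float(meta["line_rate_hz"]),
                     vessel_id=meta.get("vessel_id", "vessel"))


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

_HEADER_COMMENT = ("# 0-based (row,col) pixels; positions um; times s from "
                   "first frame\n")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER_COMMENT)
        df.to_csv(fh, index=False)


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_detections(detections: Sequence[Detection], path: str | Path) -> None:
    """CSV columns: frame,cell_id,row_um,col_um,area_px,peak_prob
    (cell_id empty before linking)."""
    df = pd.DataFrame([{
        "frame": d.frame_index,
        "cell_id": d.cell_id if d.cell_id is not None else "",
        "row_um": d.row_um,
        "col_um": d.col_um,
        "area_px": d.area_px,
        "peak_prob": d.peak_prob,
    } for d in detections], columns=["frame", "cell_id", "row_um", "col_um",
                                     "area_px", "peak_prob"])
    _write_csv(df, Path(path))


def read_detections(path: str | Path) -> list[Detection]:
    df = _read_csv(path)
    return [Detection(frame_index=int(r.frame),
                      row_um=float(r.row_um), col_um=float(r.col_um),
                      area_px=int(r.area_px), peak_prob=float(r.peak_prob),
                      cell_id=None if pd.isna(r.cell_id) else int(r.cell_id))
            for r in df.itertuples()]


def write_tracks(tracks: Sequence[Track], path: str | Path) -> None:
    """CSV columns: cell_id,time_s,row_um,col_um,qc_status."""
    rows = []
    for t in tracks:
        for i in range(t.n_samples):
            rows.append({"cell_id": t.cell_id, "time_s": t.times_s[i],
                         "row_um": t.rows_um[i], "col_um": t.cols_um[i],
                         "qc_status": t.qc_status})
    df = pd.DataFrame(rows, columns=["cell_id", "time_s", "row_um", "col_um",
                                     "qc_status"])
    _write_csv(df, Path(path))


def read_tracks(path: str | Path) -> list[Track]:
    df = _read_csv(path)
    tracks = []
    for cid, sub in df.groupby("cell_id"):
        sub = sub.sort_values("time_s")
        tracks.append(Track(cell_id=int(cid),
                            times_s=sub.time_s.to_numpy(),
                            rows_um=sub.row_um.to_numpy(),
                            cols_um=sub.col_um.to_numpy(),
                            qc_status=str(sub.qc_status.iloc[0])))
    return tracks


def write_shifts(shifts: np.ndarray, path: str | Path) -> None:
    """CSV columns: frame,dr,dc (pixels applied to align each frame)."""
    df = pd.DataFrame({"frame": np.arange(len(shifts)),
                       "dr": shifts[:, 0], "dc": shifts[:, 1]})
    _write_csv(df, Path(path))


def write_ground_truth(truth: GroundTruthCells, path: str | Path) -> None:
    """CSV columns: frame,cell_id,row_um,col_um."""
    _write_csv(truth.to_dataframe(), Path(path))


def write_json_report(report: dict, path: str | Path) -> None:
    """Deterministic (sorted-key) JSON metrics report."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
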