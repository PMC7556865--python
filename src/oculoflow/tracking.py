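"""Nearest-neighbour track linking, trace QC, and motility metrics.

Per-frame detections are linked frame-to-frame by greedy mutual-nearest-
neighbour assignment within a maximum link distance (default one nominal
cell diameter, 13 µm — immune cells move far less than a diameter between
averaged frames). Tracks whose largest single step is an outlier relative
to their own median step are flagged, automating the visual rejection of
traces that jump between adjacent cells.

Motility metrics over a (default 100 s) window:

* displacement — Euclidean distance between the samples nearest the window
  end points;
* path length — sum of consecutive step lengths;
* confinement ratio — displacement / path length, 1 for ballistic motion,
  approaching 0 for confined wandering.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Detection, ParameterError, Track

DEFAULT_MAX_LINK_DIST_UM = 13.0
DEFAULT_WINDOW_S = 100.0


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def _group_by_frame(detections: Sequence[Detection]) -> dict[int, list[Detection]]:
    frames: dict[int, list[Detection]] = {}
    for det in detections:
        frames.setdefault(det.frame_index, []).append(det)
    return frames


def link_detections(
    detections: Sequence[Detection],
    times_s: dict[int, float] | None = None,
    max_link_dist_um: float = DEFAULT_MAX_LINK_DIST_UM,
    max_gap_frames: int = 0,
    frame_interval_s: float = 0.2,
    min_samples: int = 2,
) -> list[Track]:
    """Link per-frame detections into tracks.

    Greedy mutual-nearest-neighbour assignment between consecutive frames:
    candidate pairs are taken in order of increasing distance (ties broken
    by lowest track id, then detection order — fully deterministic) and a
    pair is linked when both ends are still free and the distance is within
    ``max_link_dist_um``. Unmatched detections seed new tracks; a track
    survives up to ``max_gap_frames`` frames without a match. Tracks with
    fewer than ``min_samples`` samples are dropped.

    ``times_s`` maps frame index to acquisition time; by default frames are
    ``frame_interval_s`` apart.
    """
    if max_link_dist_um <= 0:
        raise ParameterError("max_link_dist_um must be positive")
    by_frame = _group_by_frame(detections)
    if not by_frame:
        return []
    frame_indices = sorted(by_frame)

    def time_of(fi: int) -> float:
        return times_s[fi] if times_s is not None else fi * frame_interval_s

    # active track state: id -> (last_frame, samples list)
    next_id = 0
    active: dict[int, list] = {}
    done: list[tuple[int, list]] = []

    for fi in frame_indices:
        dets = by_frame[fi]
        candidates = {tid: s for tid, s in active.items()
                      if fi - s[-1][0] <= 1 + max_gap_frames}
        # distance-sorted greedy mutual assignment
        pairs = []
        for tid, samples in candidates.items():
            last = samples[-1]
            for j, det in enumerate(dets):
                d = np.hypot(det.row_um - last[2], det.col_um - last[3])
                if d <= max_link_dist_um:
                    pairs.append((d, tid, j))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for d, tid, j in pairs:
            if tid in used_tracks or j in used_dets:
                continue
            used_tracks.add(tid)
            used_dets.add(j)
            det = dets[j]
            active[tid].append((fi, time_of(fi), det.row_um, det.col_um))
        for j, det in enumerate(dets):
            if j not in used_dets:
                active[next_id] = [(fi, time_of(fi), det.row_um, det.col_um)]
                next_id += 1
        # retire tracks that exceeded the allowed gap
        for tid in [t for t, s in active.items()
                    if fi - s[-1][0] > max_gap_frames]:
            done.append((tid, active.pop(tid)))

    done.extend(active.items())
    tracks = []
    for tid, samples in sorted(done):
        if len(samples) < min_samples:
            continue
        samples.sort()
        tracks.append(Track(
            cell_id=tid,
            times_s=np.array([s[1] for s in samples]),
            rows_um=np.array([s[2] for s in samples]),
            cols_um=np.array([s[3] for s in samples]),
        ))
    return tracks


def qc_tracks(tracks: Sequence[Track], jump_factor: float = 5.0) -> list[Track]:
    """Flag tracks containing an implausible single-step jump.

    A track is flagged when any step exceeds ``jump_factor`` times that
    track's median step length (the signature of a link that hopped between
    two neighbouring cells). Flagged tracks are excluded from metric
    summaries by default.
    """
    if jump_factor <= 1:
        raise ParameterError("jump_factor must be > 1")
    out = []
    for track in tracks:
        steps = np.hypot(np.diff(track.rows_um), np.diff(track.cols_um))
        status = "accepted"
        if len(steps) >= 2:
            median = np.median(steps)
            floor = 1e-3  # µm; guards division on essentially static tracks
            if steps.max() > jump_factor * max(median, floor):
                status = "flagged"
        out.append(Track(track.cell_id, track.times_s, track.rows_um,
                         track.cols_um, qc_status=status))
    return out


# ---------------------------------------------------------------------------
# motility metrics
# ---------------------------------------------------------------------------

def _window_indices(track: Track, window_s: float,
                    allow_short: bool) -> tuple[int, int]:
    t0 = track.times_s[0]
    if track.duration_s < window_s:
        if not allow_short:
            raise ParameterError(
                f"track spans {track.duration_s:.1f} s < window {window_s} s; "
                "pass allow_short=True for the full-span value")
        warnings.warn("track shorter than window; using full span",
                      stacklevel=3)
        return 0, track.n_samples - 1
    i0 = int(np.argmin(np.abs(track.times_s - t0)))
    i1 = int(np.argmin(np.abs(track.times_s - (t0 + window_s))))
    return i0, i1


def displacement(track: Track, window_s: float = DEFAULT_WINDOW_S,
                 allow_short: bool = False) -> float:
    """Euclidean displacement (µm) over the window anchored at the first
    sample."""
    i0, i1 = _window_indices(track, window_s, allow_short)
    return float(np.hypot(track.rows_um[i1] - track.rows_um[i0],
                          track.cols_um[i1] - track.cols_um[i0]))


def path_length(track: Track, window_s: float = DEFAULT_WINDOW_S,
                allow_short: bool = False) -> float:
    """Total path length (µm) over the window."""
    i0, i1 = _window_indices(track, window_s, allow_short)
    steps = np.hypot(np.diff(track.rows_um[i0:i1 + 1]),
                     np.diff(track.cols_um[i0:i1 + 1]))
    return float(steps.sum())


def confinement_ratio(track: Track, window_s: float = DEFAULT_WINDOW_S,
                      allow_short: bool = False) -> float:
    """Displacement over path length in [0, 1]; NaN when the path length is
    zero (the ratio is undefined for a cell that never moved)."""
    length = path_length(track, window_s, allow_short)
    if length == 0:
        return float("nan")
    return displacement(track, window_s, allow_short) / length


def normalize_traces(tracks: Sequence[Track]) -> list[np.ndarray]:
    """Origin-centred traces for rose plots: each (n, 2) array of
    (row_um, col_um) starts at (0, 0)."""
    traces = []
    for track in tracks:
        xy = track.positions()
        traces.append(xy - xy[0])
    return traces


def motility_table(tracks: Sequence[Track],
                   window_s: float = DEFAULT_WINDOW_S,
                   allow_short: bool = False,
                   include_flagged: bool = False) -> pd.DataFrame:
    """Per-track metrics table (flagged tracks excluded by default)."""
    rows = []
    with warnings.catch_warnings():
        if allow_short:  # the per-track warning would repeat for each row
            warnings.simplefilter("ignore", UserWarning)
        for track in tracks:
            if track.qc_status != "accepted" and not include_flagged:
                continue
            rows.append({
                "cell_id": track.cell_id,
                "displacement_um": displacement(track, window_s,
                                                allow_short),
                "path_length_um": path_length(track, window_s, allow_short),
                "confinement_ratio": confinement_ratio(track, window_s,
                                                       allow_short),
                "window_s": window_s,
                "qc_status": track.qc_status,
            })
    return pd.DataFrame(rows, columns=["cell_id", "displacement_um",
                                       "path_length_um", "confinement_ratio",
                                       "window_s", "qc_status"])
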