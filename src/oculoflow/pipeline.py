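"""End-to-end orchestration of the synthetic study.

``run_pipeline`` executes the full workflow on generated data: simulate a
cell video -> de-sinusoid -> register -> temporally average -> detect ->
track -> motility metrics, plus, per vessel and timepoint, kymograph
velocimetry -> motion-contrast diametry -> volumetric flow -> longitudinal
conservation analysis. All tables are written as CSV, scalar results as one
deterministic JSON report, and (optionally) summary plots as PNG.
"""

from __future__ import annotations

import copy
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import detection, hemodynamics, io, registration, synth, tracking
from . import velocimetry
from .core import (LongitudinalSeries, ParameterError, VesselMeasurement,
                   TIMEPOINTS)

log = logging.getLogger("oculoflow")

#: Demo configuration: a complete miniature study that runs in about a
#: minute on one CPU. All values overridable through YAML.
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "outdir": "oculoflow_out",
    "log_level": "INFO",
    "plots": False,
    "cell_video": {
        "simulate": {
            "field_size_deg": 3.76,
            "frame_shape": [128, 128],
            "frame_rate": 25.0,
            "n_frames": 150,
            "n_cells": 8,
            "motion_model": "drift",
            "drift_velocity_um_s": [0.3, 0.2],
            "eye_motion_sigma_px": 2.0,
            "scan_distortion_amplitude": 0.15,
            "noise_sigma": 0.02,
        },
    },
    "registration": {"upsample_factor": 1},
    "averaging": {"window": 5, "stride": 5},
    "detector": {
        "kind": "learned",
        "training": {"n_frames": 20, "n_cells": 5},
    },
    "tracking": {
        "max_link_dist_um": 13.0,
        "jump_factor": 5.0,
        "window_s": 4.0,
    },
    "vessels": {
        "timepoints": list(TIMEPOINTS),
        "flow_change_pct": [0.0, 30.0, 67.0, 25.0, 10.0],
        # equal baseline volumetric flow (conserved bed), typical mouse
        # retinal values: venules slower and wider, arterioles faster
        "venule_baseline": {"velocity_mm_s": 7.0, "diameter_um": 40.0},
        "arteriole_baseline": {"velocity_mm_s": 14.29, "diameter_um": 28.0},
        "kymograph": {"duration_s": 0.4, "pulsatility_fraction": 0.3,
                      "cardiac_freq_hz": 6.0},
        "window_ms": 10.0,
        "profile_factor_k": 1.0,
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path: str | Path) -> dict:
    """YAML config merged over the defaults (round-trip lossless)."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    def merge(base: dict, over: dict) -> dict:
        out = dict(base)
        for k, v in over.items():
            out[k] = (merge(base[k], v)
                      if isinstance(v, dict) and isinstance(base.get(k), dict)
                      else v)
        return out
    return merge(default_config(), user)


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def validate_config(config: dict) -> None:
    """Fail before any computation when a stage block is missing."""
    for block in ("cell_video", "registration", "averaging", "detector",
                  "tracking", "vessels"):
        if block not in config or config[block] is None:
            raise ParameterError(f"config is missing the {block!r} block")
    if config["detector"].get("kind") not in ("learned", "classical"):
        raise ParameterError("detector.kind must be 'learned' or 'classical'")


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _train_pipeline_detector(config: dict, um_per_px: float,
                             seed: int) -> detection.DetectorModel:
    """Detector per config: classical needs no training; the learned model
    trains on freshly simulated annotated frames."""
    d_px = 13.0 / um_per_px
    det_cfg = detection.DetectorConfig(kind=config["detector"]["kind"],
                                       cell_diameter_px=d_px, seed=seed)
    if det_cfg.kind == "classical":
        return detection.train_detector([], [], det_cfg)
    tr = config["detector"]["training"]
    frames, targets = [], []
    for i in range(tr["n_frames"]):
        sim = synth.SimulationConfig(
            frame_shape=(128, 128), n_frames=1, n_cells=tr["n_cells"],
            rng_seed=seed + 10_000 + i)
        stack, truth = synth.simulate_cell_video(sim)
        frames.append(stack.frames[0])
        centroids = truth.frame_positions(0) / sim.um_per_px
        targets.append(detection.make_label_map(
            centroids, stack.frame_shape, radius_px=d_px / 2.0))
    return detection.train_detector(frames, targets, det_cfg)


def _measure_vessel(vessel_type: str, timepoint: str, v_true: float,
                    d_true: float, vcfg: dict, seed: int) -> VesselMeasurement:
    """One vessel at one timepoint: kymograph velocimetry + motion-contrast
    diametry + flow."""
    kcfg = vcfg["kymograph"]
    kymo, _ = synth.simulate_vessel_kymograph(synth.VesselSimConfig(
        true_velocity_mm_s=v_true,
        lumen_diameter_um=d_true,
        duration_s=kcfg["duration_s"],
        pulsatility_fraction=kcfg["pulsatility_fraction"],
        cardiac_freq_hz=kcfg["cardiac_freq_hz"],
        rng_seed=seed,
    ))
    times, vels = velocimetry.estimate_velocity(kymo, vcfg["window_ms"])
    v_meas = velocimetry.cycle_average_velocity(times, vels,
                                                kcfg["cardiac_freq_hz"])
    stack, _ = synth.simulate_vessel_video(d_true, rng_seed=seed + 1)
    mc = velocimetry.build_motion_contrast(stack)
    d_meas = velocimetry.measure_diameter(mc)
    k = vcfg["profile_factor_k"]
    return VesselMeasurement(
        vessel_id=f"{vessel_type}-0", vessel_type=vessel_type,
        timepoint=timepoint, velocity_mm_s=v_meas, diameter_um=d_meas,
        flow_nl_s=velocimetry.compute_flow(v_meas, d_meas, k), k=k)


def _vessel_truth(vcfg: dict) -> list[tuple[str, str, float, float]]:
    """(vessel_type, timepoint, V, D) truth rows: the venule dilates, the
    arteriole speeds up, both following the shared flow-change profile."""
    rows = []
    for vtype in ("venule", "arteriole"):
        base = vcfg[f"{vtype}_baseline"]
        v0, d0 = base["velocity_mm_s"], base["diameter_um"]
        for tp, dq in zip(vcfg["timepoints"], vcfg["flow_change_pct"]):
            ratio = 1.0 + dq / 100.0
            if vtype == "venule":
                v, d = v0, d0 * np.sqrt(ratio)
            else:
                v, d = v0 * ratio, d0
            rows.append((vtype, tp, v, d))
    return rows


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict) -> dict:
    """Execute the configured synthetic study and return the metrics report.

    Writes detections/tracks/metrics/vessel CSVs, shift tables, the
    ground-truth sidecars and ``report.json`` into ``config['outdir']``.
    Fixed seed implies a byte-identical report.
    """
    validate_config(config)
    seed = int(config["seed"])
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.get("log_level", "INFO"))
    report: dict[str, Any] = {"seed": seed,
                              "units": {"position": "um", "time": "s",
                                        "velocity": "mm/s", "flow": "nL/s",
                                        "density": "cells/mm^2",
                                        "change": "%"}}
    timings: dict[str, float] = {}

    def stage(name: str):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s ...", name)

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc_type is not None:
                    log.error("stage %s failed: %s", name, exc)
        return _T()

    # --- cell video --------------------------------------------------------
    cv = config["cell_video"]
    with stage("simulate"):
        if "simulate" in cv:
            sim_kwargs = dict(cv["simulate"])
            sim_kwargs["frame_shape"] = tuple(sim_kwargs.get("frame_shape",
                                                             (128, 128)))
            if "drift_velocity_um_s" in sim_kwargs:
                sim_kwargs["drift_velocity_um_s"] = tuple(
                    sim_kwargs["drift_velocity_um_s"])
            sim_cfg = synth.SimulationConfig(rng_seed=seed, **sim_kwargs)
            stack, truth = synth.simulate_cell_video(sim_cfg)
            io.write_ground_truth(truth, outdir / "cell_truth.csv")
            distortion = sim_cfg.scan_distortion_amplitude
            n_true_cells = sim_cfg.n_cells
        elif "path" in cv:
            stack = io.read_video(cv["path"], cv.get("calibration"))
            truth = None
            distortion = float(cv.get("scan_distortion_amplitude", 0.0))
            n_true_cells = None
        else:
            raise ParameterError(
                "cell_video needs a 'simulate' block or a 'path'")

    with stage("desinusoid"):
        if distortion > 0:
            stack = registration.desinusoid_video(stack, distortion)

    with stage("register"):
        stack, shifts = registration.register_video(
            stack, upsample_factor=config["registration"]["upsample_factor"])
        io.write_shifts(shifts, outdir / "shifts.csv")

    with stage("average"):
        avg = registration.temporal_average(stack,
                                            config["averaging"]["window"],
                                            config["averaging"]["stride"])

    # --- detection ---------------------------------------------------------
    with stage("detect"):
        model = _train_pipeline_detector(config, avg.um_per_px, seed)
        model.save(outdir / "detector.pkl")
        detections = []
        per_frame_counts = []
        for i, frame in enumerate(avg.frames):
            pmap = detection.predict_probability_map(
                model, frame, frame_index=i, um_per_px=avg.um_per_px)
            dets = detection.detect_centroids(pmap)
            detections.extend(dets)
            per_frame_counts.append(len(dets))
        io.write_detections(detections, outdir / "detections.csv")
        count = detection.count_cells(per_frame_counts, allow_short=True)
        h_px, w_px = avg.frame_shape
        density = detection.cell_density(
            count, (h_px * avg.um_per_px, w_px * avg.um_per_px))
        report["cells"] = {"count_mean_first25": count,
                           "density_cells_per_mm2": density,
                           "n_true_cells": n_true_cells}

    # --- tracking & motility ----------------------------------------------
    with stage("track"):
        tcfg = config["tracking"]
        times = {i: float(t) for i, t in enumerate(avg.timestamps)}
        tracks = tracking.link_detections(
            detections, times_s=times,
            max_link_dist_um=tcfg["max_link_dist_um"],
            frame_interval_s=avg.frame_interval_s)
        tracks = tracking.qc_tracks(tracks, tcfg["jump_factor"])
        io.write_tracks(tracks, outdir / "tracks.csv")
        metrics = tracking.motility_table(tracks, window_s=tcfg["window_s"],
                                          allow_short=True)
        io._write_csv(metrics, outdir / "motility.csv")
        accepted = metrics.dropna(subset=["displacement_um"])
        report["motility"] = {
            "n_tracks": int(len(tracks)),
            "n_accepted": int(len(accepted)),
            "window_s": tcfg["window_s"],
            "displacement_um_mean": (float(accepted.displacement_um.mean())
                                     if len(accepted) else None),
            "displacement_um_sd": (float(accepted.displacement_um.std(ddof=1))
                                   if len(accepted) > 1 else None),
            "confinement_ratio_mean": (
                float(accepted.confinement_ratio.dropna().mean())
                if len(accepted) else None),
        }

    # --- vessels -----------------------------------------------------------
    with stage("flow"):
        vcfg = config["vessels"]
        measurements: dict[str, list[VesselMeasurement]] = {
            "venule": [], "arteriole": []}
        for j, (vtype, tp, v, d) in enumerate(_vessel_truth(vcfg)):
            m = _measure_vessel(vtype, tp, v, d, vcfg,
                                seed + 20_000 + 7 * j)
            measurements[vtype].append(m)
        vessel_rows = [vars(m) for ms in measurements.values() for m in ms]
        vessel_df = pd.DataFrame(vessel_rows)
        io._write_csv(vessel_df, outdir / "vessels.csv")

    with stage("analyze"):
        series = {vtype: LongitudinalSeries(f"{vtype}-0", vtype, ms)
                  for vtype, ms in measurements.items()}
        changes = pd.concat([hemodynamics.series_relative_changes(s)
                             for s in series.values()], ignore_index=True)
        ratios = pd.concat([hemodynamics.v_over_d2_ratio(s)
                            for s in series.values()], ignore_index=True)
        io._write_csv(changes.merge(ratios), outdir / "longitudinal.csv")
        art = changes[changes.vessel_type == "arteriole"]
        ven = changes[changes.vessel_type == "venule"]
        nonbase = lambda df: df[df.timepoint != "baseline"]  # noqa: E731
        slope, intercept, r2 = hemodynamics.flow_conservation_fit(
            nonbase(art).dq_pct.to_numpy(), nonbase(ven).dq_pct.to_numpy())
        report["hemodynamics"] = {
            "timepoints": list(vcfg["timepoints"]),
            "venule": {
                "dv_pct": ven.dv_pct.round(6).tolist(),
                "dd_pct": ven.dd_pct.round(6).tolist(),
                "dq_pct": ven.dq_pct.round(6).tolist(),
            },
            "arteriole": {
                "dv_pct": art.dv_pct.round(6).tolist(),
                "dd_pct": art.dd_pct.round(6).tolist(),
                "dq_pct": art.dq_pct.round(6).tolist(),
            },
            "v_over_d2_change_pct": {
                vt: ratios[ratios.vessel_type == vt]
                .v_over_d2_change_pct.round(6).tolist()
                for vt in ("venule", "arteriole")},
            "conservation": {"slope": round(slope, 6),
                             "intercept": round(intercept, 6),
                             "r_squared": round(r2, 6)},
        }

    if config.get("plots"):
        with stage("plots"):
            _render_plots(report, tracks, outdir)

    # report.json is byte-identical for a fixed config+seed; run-specific
    # provenance (wall-clock timings, output location) goes to run_info.json
    effective = {k: v for k, v in config.items() if k != "outdir"}
    report["effective_config"] = effective
    io.write_json_report(report, outdir / "report.json")
    io.write_json_report({"timings_s": timings, "outdir": str(outdir)},
                         outdir / "run_info.json")
    log.info("report written to %s", outdir / "report.json")
    return report


def _render_plots(report: dict, tracks, outdir: Path) -> None:
    """Time-course, conservation scatter, V/D² bars and rose plot."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hd = report["hemodynamics"]
    tps = hd["timepoints"]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for vt, color in (("venule", "tab:blue"), ("arteriole", "tab:red")):
        axes[0].plot(tps, hd[vt]["dq_pct"], "o-", color=color, label=vt)
        axes[1].plot(tps, hd["v_over_d2_change_pct"][vt], "o-", color=color)
    axes[0].set_ylabel("flow change (%)")
    axes[0].legend()
    axes[1].set_ylabel("V/D$^2$ change (%)")
    axes[2].scatter(hd["arteriole"]["dq_pct"][1:], hd["venule"]["dq_pct"][1:])
    axes[2].set_xlabel("arteriole ΔQ (%)")
    axes[2].set_ylabel("venule ΔQ (%)")
    fit = hd["conservation"]
    axes[2].set_title(f"R² = {fit['r_squared']:.2f}")
    fig.tight_layout()
    fig.savefig(outdir / "hemodynamics.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    for trace in tracking.normalize_traces(
            [t for t in tracks if t.qc_status == "accepted"]):
        ax.plot(trace[:, 1], trace[:, 0], lw=0.8)
    circle = plt.Circle((0, 0), 13.0, fill=False, ls="--", color="grey")
    ax.add_patch(circle)
    ax.set_aspect("equal")
    ax.set_xlabel("Δcol (µm)")
    ax.set_ylabel("Δrow (µm)")
    fig.tight_layout()
    fig.savefig(outdir / "traces.png", dpi=120)
    plt.close(fig)
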