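"""End-to-end orchestration: video in, agreement report out.

For each region of interest the pipeline tracks the target, calibrates the
pixel trajectory to millimeters, differentiates twice to acceleration, and
resamples everything onto a common reference-clock grid (5000 Hz by
default, matching typical accelerometer DAQ rates). When reference channels
are supplied it synchronizes the two instruments via audio taps, detects
ECG R peaks, forms beat ensembles of both SCG signals, and computes the
full validation battery: Pearson r, DTW similarity index, lag, wavelet
coherence, and heart-rate agreement. Regions fail independently — an
untrackable patch is reported, not fatal.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as scgio
from .beats import detect_r_peaks, ensemble_average, segment_beats
from .errors import ConfigError, ScgVisionError
from .heartrate import hr_from_r_peaks, hr_from_scg
from .metrics import (
    bland_altman,
    estimate_lag,
    pearson_r,
    similarity_index,
    wavelet_coherence,
)
from .signals import (
    ClockMap,
    UniformSignal,
    align_clocks,
    bandpass,
    detect_taps,
    displacement_to_acceleration,
    resample_to,
)
from .tracking import (
    TrackerConfig,
    apply_calibration,
    extract_template,
    scaling_factor_from_target,
    track_sequence,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs; paths may be None when a stage is
    not wanted (no references -> tracking and HR only)."""

    video: str
    rois: list = field(default_factory=list)          # (x0, y0, w, h) each
    rotations: list | None = None                     # degrees CCW, per roi
    frame_rate: float | None = None
    target_mm: float | None = None                    # physical target size
    target_px: float | None = None                    # its pixel size (default: roi width)
    scale_mm_per_px: float | None = None              # direct override

    ecg: str | None = None
    accel_x: str | None = None
    accel_y: str | None = None
    video_audio: str | None = None
    daq_audio: str | None = None

    scg_band: tuple = (1.0, 30.0)
    common_fs: float = 5000.0
    coherence_fs: float = 100.0
    dtw_band_fraction: float = 0.05
    max_lag_s: float = 0.5
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    out_dir: str | None = None

    def validate(self):
        if not self.rois:
            raise ConfigError("at least one ROI is required")
        if (self.scale_mm_per_px is None and self.target_mm is None):
            raise ConfigError("provide target_mm (with target_px) or scale_mm_per_px")
        lo, hi = self.scg_band
        if not (0 < lo < hi):
            raise ConfigError(f"invalid SCG band {self.scg_band}")


def _to_reference_clock(sig: UniformSignal, clock: ClockMap,
                        fs: float) -> UniformSignal:
    """Resample a source-clock signal onto the reference-clock grid."""
    up = resample_to(sig, fs)
    t_ref = clock.apply(up.times)
    t0 = np.ceil(t_ref[0] * fs) / fs
    n = int(np.floor((t_ref[-1] - t0) * fs)) + 1
    grid = t0 + np.arange(n) / fs
    vals = np.interp(grid, t_ref, up.values)
    return UniformSignal(vals, fs, units=sig.units, t0=t0)


def _crop_overlap(sigs: list[UniformSignal]) -> list[UniformSignal]:
    """Crop same-rate signals to their common time window so sample index i
    refers to the same instant in every record."""
    fs = sigs[0].fs
    t_start = max(s.t0 for s in sigs)
    t_end = min(s.t0 + (len(s) - 1) / fs for s in sigs)
    if t_end - t_start < 1.0:
        raise ConfigError("records overlap by less than 1 s after sync")
    out = []
    for s in sigs:
        i0 = int(round((t_start - s.t0) * fs))
        i1 = int(round((t_end - s.t0) * fs)) + 1
        out.append(UniformSignal(s.values[i0:i1], fs, units=s.units, t0=t_start))
    n_min = min(len(s) for s in out)
    return [s if len(s) == n_min else
            UniformSignal(s.values[:n_min], fs, units=s.units, t0=t_start)
            for s in out]


def _axis_metrics(gold: UniformSignal, vision: UniformSignal, rpeaks,
                  config: PipelineConfig, axis: str) -> dict:
    seg_g = segment_beats(gold, rpeaks)
    seg_v = segment_beats(vision, rpeaks)
    ens_g = ensemble_average(seg_g)
    ens_v = ensemble_average(seg_v)
    sim = similarity_index(ens_g, ens_v, config.dtw_band_fraction,
                           axis_label=axis)
    coh = wavelet_coherence(resample_to(gold, config.coherence_fs),
                            resample_to(vision, config.coherence_fs))
    inside = coh.inside_coi()
    out = {
        "pearson_r": pearson_r(ens_g.values, ens_v.values),
        "similarity_index": sim.s,
        "similarity_in_range": sim.in_range,
        "dtw_distance": sim.d,
        "dtw_normalizer": sim.m,
        "lag_s": estimate_lag(gold, vision, config.max_lag_s),
        "coherence_mean_in_coi": float(coh.coherence[inside].mean()),
        "n_beats": int(ens_g.n_beats),
        "n_c": int(seg_g.n_c),
    }
    return out, ens_g, ens_v, coh


def _analyze_roi(frames, roi, rotation, refs, rpeaks, clock,
                 config: PipelineConfig) -> dict:
    template = extract_template(frames, roi)
    traj = track_sequence(frames, template, config.tracker)
    if config.scale_mm_per_px is not None:
        from .tracking import CameraCalibration
        cal = CameraCalibration(sf=config.scale_mm_per_px, method="target_dimension")
    else:
        d_px = config.target_px if config.target_px is not None else roi[2]
        cal = scaling_factor_from_target(config.target_mm, d_px)
    traj_mm = apply_calibration(traj, cal)

    result = {"roi": list(roi), "rotation_deg": rotation, "ok": True,
              "sf_mm_per_px": cal.sf,
              "mean_track_error": float(np.mean(traj.per_frame_error)),
              "axes": {}, "artifacts": {"trajectory": traj_mm}}
    scg_v = {}
    for axis in ("x", "y"):
        disp = traj_mm.component(axis)
        disp_ref = _to_reference_clock(disp, clock, config.common_fs)
        accel = displacement_to_acceleration(disp_ref)
        accel = bandpass(accel, *config.scg_band)
        scg_v[axis] = accel
    result["artifacts"]["scg_v"] = scg_v

    if rpeaks is not None and refs:
        for axis in ("x", "y"):
            if axis not in refs:
                continue
            gold, vision, ecg_c = _crop_overlap(
                [refs[axis], scg_v[axis], refs["ecg"]])
            peaks_c = detect_r_peaks(ecg_c)
            metrics, ens_g, ens_v, coh = _axis_metrics(
                gold, vision, peaks_c, config, axis)
            result["axes"][axis] = metrics
            result["artifacts"][f"ensemble_{axis}"] = (ens_g, ens_v)
            result["artifacts"][f"coherence_{axis}"] = coh

    hr = {}
    for axis in ("x", "y"):
        try:
            hr_v = hr_from_scg(scg_v[axis])
            hr[f"scg_{axis}_mean_bpm"] = hr_v.mean_bpm
            result["artifacts"][f"hr_scg_{axis}"] = hr_v
        except ScgVisionError as exc:
            hr[f"scg_{axis}_error"] = str(exc)
    if rpeaks is not None:
        hr_e = hr_from_r_peaks(rpeaks)
        hr["ecg_mean_bpm"] = hr_e.mean_bpm
        result["artifacts"]["hr_ecg"] = hr_e
        for axis in ("x", "y"):
            hr_v = result["artifacts"].get(f"hr_scg_{axis}")
            if hr_v is not None and len(hr_v) >= 2:
                paired = np.interp(hr_e.times, hr_v.times, hr_v.bpm)
                ba = bland_altman(hr_e.bpm, paired)
                hr[f"bland_altman_{axis}"] = {
                    "bias_bpm": ba.bias, "loa_low_bpm": ba.loa_low,
                    "loa_high_bpm": ba.loa_high, "n": ba.n}
    result["hr"] = hr
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline described in the module docstring.

    Returns the consolidated report dict (also written to
    ``<out_dir>/report.json`` with per-ROI CSV artifacts when ``out_dir``
    is set).
    """
    config.validate()
    t_begin = time.time()
    frames = scgio.load_video(config.video, frame_rate=config.frame_rate)
    report = {"video": str(config.video), "n_frames": len(frames),
              "frame_rate_hz": frames.frame_rate, "rois": []}

    # two-instrument synchronization from tap audio; identity when absent
    if config.video_audio and config.daq_audio:
        taps_v = detect_taps(scgio.read_wav(config.video_audio))
        taps_d = detect_taps(scgio.read_wav(config.daq_audio))
        try:
            clock = align_clocks(taps_v, taps_d)
        except ScgVisionError as exc:
            raise type(exc)(f"clock sync from "
                            f"{config.video_audio} / {config.daq_audio}: {exc}") from exc
        report["clock"] = {"offset_s": clock.offset, "drift": clock.drift}
    else:
        clock = ClockMap(offset=0.0, drift=1.0)

    refs = {}
    rpeaks = None
    if config.ecg:
        ecg = scgio.read_signal_csv(config.ecg)
        if abs(ecg.fs - config.common_fs) > 1e-9:
            ecg = resample_to(ecg, config.common_fs)
        refs["ecg"] = ecg
        rpeaks = detect_r_peaks(ecg)
    for axis, path in (("x", config.accel_x), ("y", config.accel_y)):
        if path:
            sig = scgio.read_signal_csv(path)
            if abs(sig.fs - config.common_fs) > 1e-9:
                sig = resample_to(sig, config.common_fs)
            refs[axis] = bandpass(sig, *config.scg_band)

    rotations = config.rotations or [0.0] * len(config.rois)
    for k, roi in enumerate(config.rois):
        rot = rotations[k] if k < len(rotations) else 0.0
        roi_frames = frames
        if rot:
            roi_frames = scgio.load_video(config.video,
                                          frame_rate=config.frame_rate,
                                          rotation_deg=rot)
        try:
            result = _analyze_roi(roi_frames, tuple(roi), rot, refs, rpeaks,
                                  clock, config)
        except ScgVisionError as exc:
            logger.warning("roi %s failed: %s", roi, exc)
            result = {"roi": list(roi), "rotation_deg": rot, "ok": False,
                      "error": f"{type(exc).__name__}: {exc}"}
        report["rois"].append(result)

    logger.info("pipeline finished in %.2f s", time.time() - t_begin)
    if config.out_dir:
        _write_outputs(report, config)
    for r in report["rois"]:
        r.pop("artifacts", None)
    return report


def _write_outputs(report: dict, config: PipelineConfig) -> None:
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for k, r in enumerate(report["rois"]):
        art = r.get("artifacts")
        if not art:
            continue
        tag = f"roi{k}"
        scgio.write_trajectory_csv(outdir / f"{tag}_trajectory_mm.csv",
                                   art["trajectory"])
        for axis, sig in art["scg_v"].items():
            scgio.write_signal_csv(outdir / f"{tag}_scg_v_{axis}.csv", sig)
        for axis in ("x", "y"):
            ens = art.get(f"ensemble_{axis}")
            if ens:
                ens_g, ens_v = ens
                pd.DataFrame({
                    "time_s": np.arange(len(ens_g.values)) / ens_g.fs,
                    "gold": ens_g.values, "vision": ens_v.values,
                }).to_csv(outdir / f"{tag}_ensemble_{axis}.csv", index=False)
            coh = art.get(f"coherence_{axis}")
            if coh is not None:
                np.savetxt(outdir / f"{tag}_coherence_{axis}.csv",
                           coh.coherence, delimiter=",", fmt="%.6g")
                pd.DataFrame({"freq_hz": coh.freqs}).to_csv(
                    outdir / f"{tag}_coherence_{axis}_freqs.csv", index=False)
                pd.DataFrame({"time_s": coh.times, "coi_hz": coh.coi}).to_csv(
                    outdir / f"{tag}_coherence_{axis}_times.csv", index=False)
        for axis in ("x", "y"):
            hr_v = art.get(f"hr_scg_{axis}")
            if hr_v is not None:
                pd.DataFrame({"time_s": hr_v.times, "bpm": hr_v.bpm,
                              "source": hr_v.source}).to_csv(
                    outdir / f"{tag}_hr_scg_{axis}.csv", index=False)
        hr_e = art.get("hr_ecg")
        if hr_e is not None:
            pd.DataFrame({"time_s": hr_e.times, "bpm": hr_e.bpm,
                          "source": hr_e.source}).to_csv(
                outdir / "hr_ecg.csv", index=False)
    clean = {k: v for k, v in report.items()}
    clean["rois"] = [{kk: vv for kk, vv in r.items() if kk != "artifacts"}
                     for r in report["rois"]]
    with open(outdir / "report.json", "w") as fh:
        json.dump(clean, fh, indent=2, sort_keys=True)
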