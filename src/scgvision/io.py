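"""File I/O: videos as frame stacks or containers, signals as annotated CSV,
audio as WAV, and synthetic-scene bundles with a JSON manifest.

Signal CSVs carry their metadata (fs, units, t0) in ``#``-prefixed header
comments above a ``time_s,value`` table, so a file round-trips to an
identical :class:`~scgvision.signals.UniformSignal`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.io import wavfile

from .errors import ConfigError, DomainError
from .signals import UniformSignal
from .tracking import DisplacementTrajectory, FrameSequence

__all__ = [
    "load_video",
    "write_frames",
    "read_signal_csv",
    "write_signal_csv",
    "read_wav",
    "write_wav",
    "write_trajectory_csv",
    "write_scene",
    "load_scene",
]

_LUMA = np.array([0.299, 0.587, 0.114])


def _to_gray01(arr: np.ndarray) -> np.ndarray:
    """Convert frames to [0, 1] grayscale luma."""
    arr = np.asarray(arr)
    if arr.ndim == 4 or (arr.ndim == 3 and arr.shape[-1] in (3, 4)):
        arr = arr[..., :3] @ _LUMA
    arr = arr.astype(float)
    if arr.max() > 1.0:
        info_max = 255.0 if arr.max() <= 255 else 65535.0
        arr = arr / info_max
    return np.clip(arr, 0.0, 1.0)


def _rotate_frames(frames: np.ndarray, angle: float) -> np.ndarray:
    """Rotate counterclockwise; exact for multiples of 90 degrees."""
    if angle == 0:
        return frames
    if angle % 90 == 0:
        return np.rot90(frames, k=int(angle // 90) % 4, axes=(1, 2)).copy()
    out = ndimage.rotate(frames, angle, axes=(2, 1), reshape=False,
                         order=1, mode="nearest")
    return np.clip(out, 0.0, 1.0)


def load_video(path: str | Path, frame_rate: float | None = None,
               rotation_deg: float = 0.0) -> FrameSequence:
    """Load a video as a grayscale FrameSequence.

    Supported sources: TIFF stacks (``.tif``/``.tiff``), NumPy stacks
    (``.npy``, or ``.npz`` with a ``frames`` array and optional
    ``frame_rate`` scalar), and any container imageio can read (MP4/AVI,
    when an ffmpeg backend is available). ``frame_rate`` overrides metadata;
    TIFF/npy stacks carry none, so it is required for them.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"video not found: {path}")
    suffix = path.suffix.lower()
    meta_fps = None
    if suffix in (".tif", ".tiff"):
        import tifffile
        frames = tifffile.imread(path)
    elif suffix == ".npy":
        frames = np.load(path)
    elif suffix == ".npz":
        with np.load(path) as z:
            frames = z["frames"]
            if "frame_rate" in z:
                meta_fps = float(z["frame_rate"])
    else:
        import imageio.v3 as iio
        frames = iio.imread(path)
        try:
            meta = iio.immeta(path)
            meta_fps = float(meta.get("fps")) if meta.get("fps") else None
        except Exception:
            meta_fps = None
    fps = frame_rate if frame_rate is not None else meta_fps
    if fps is None:
        raise ConfigError(f"{path}: frame rate not in metadata; pass frame_rate")
    gray = _to_gray01(frames)
    if gray.ndim != 3:
        raise DomainError(f"{path}: expected a frame stack, got shape {gray.shape}")
    gray = _rotate_frames(gray, rotation_deg)
    return FrameSequence(frames=gray, frame_rate=fps, rotation_deg=rotation_deg)


def write_frames(path: str | Path, frames: FrameSequence) -> None:
    """Write frames as a lossless float32 TIFF stack."""
    import tifffile
    tifffile.imwrite(Path(path), frames.frames.astype(np.float32))


def write_signal_csv(path: str | Path, sig: UniformSignal) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={sig.fs!r}\n# units={sig.units}\n# t0_s={sig.t0!r}\n")
        fh.write("time_s,value\n")
        np.savetxt(fh, np.column_stack([sig.times, sig.values]),
                   delimiter=",", fmt="%.10g")


def read_signal_csv(path: str | Path) -> UniformSignal:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"signal file not found: {path}")
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    data = pd.read_csv(path, comment="#")
    values = data["value"].to_numpy(float)
    if "fs_hz" in meta:
        fs = float(meta["fs_hz"])
    else:
        dt = np.diff(data["time_s"].to_numpy(float))
        fs = 1.0 / float(np.median(dt))
    t0 = float(meta.get("t0_s", data["time_s"].iloc[0]))
    return UniformSignal(values, fs, units=meta.get("units", "a.u."), t0=t0)


def write_wav(path: str | Path, sig: UniformSignal) -> None:
    wavfile.write(Path(path), int(round(sig.fs)),
                  sig.values.astype(np.float32))


def read_wav(path: str | Path) -> UniformSignal:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"audio file not found: {path}")
    fs, data = wavfile.read(path)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    data = np.asarray(data, float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return UniformSignal(data, float(fs), units="a.u.")


def write_trajectory_csv(path: str | Path, traj: DisplacementTrajectory) -> None:
    with open(path, "w") as fh:
        fh.write(f"# units={traj.units}\n# frame_rate_hz={traj.frame_rate!r}\n")
        pd.DataFrame({
            "time_s": traj.times,
            "ux": traj.ux,
            "uy": traj.uy,
            "error": traj.per_frame_error,
        }).to_csv(fh, index=False, float_format="%.10g")


def write_scene(scene, outdir: str | Path) -> dict:
    """Write a synthetic scene bundle: frame stack, truth CSVs, ECG, tap
    audio and a JSON manifest. Returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_frames(outdir / "frames.tif", scene.frames)
    manifest = {
        "video": "frames.tif",
        "frame_rate_hz": scene.frames.frame_rate,
        "scale_mm_per_px": scene.scale_mm_per_px,
        "hr_bpm": scene.hr_bpm,
        "clock_offset_s": scene.clock_offset_s,
        "seed": scene.seed,
        "files": {},
    }
    for axis, sig in scene.truth_disp_px.items():
        name = f"truth_disp_px_{axis}.csv"
        write_signal_csv(outdir / name, sig)
        manifest["files"][f"truth_disp_px_{axis}"] = name
    for axis, sig in scene.truth_disp_mm.items():
        name = f"truth_disp_mm_{axis}.csv"
        write_signal_csv(outdir / name, sig)
        manifest["files"][f"truth_disp_mm_{axis}"] = name
    for axis, sig in scene.truth_accel.items():
        name = f"truth_accel_{axis}.csv"
        write_signal_csv(outdir / name, sig)
        manifest["files"][f"truth_accel_{axis}"] = name
    if scene.ecg is not None:
        write_signal_csv(outdir / "ecg.csv", scene.ecg)
        manifest["files"]["ecg"] = "ecg.csv"
    if scene.truth_rpeaks is not None:
        pd.DataFrame({
            "index": scene.truth_rpeaks.indices,
            "time_s": scene.truth_rpeaks.times,
        }).to_csv(outdir / "truth_rpeaks.csv", index=False)
        manifest["files"]["truth_rpeaks"] = "truth_rpeaks.csv"
    if scene.daq_audio is not None:
        write_wav(outdir / "daq_audio.wav", scene.daq_audio)
        manifest["files"]["daq_audio"] = "daq_audio.wav"
    if scene.frames.audio is not None:
        write_wav(outdir / "video_audio.wav", scene.frames.audio)
        manifest["files"]["video_audio"] = "video_audio.wav"
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_scene(scenedir: str | Path):
    """Reload a scene bundle written by :func:`write_scene`."""
    from .synthetic import SyntheticScene

    scenedir = Path(scenedir)
    with open(scenedir / "manifest.json") as fh:
        manifest = json.load(fh)
    frames = load_video(scenedir / manifest["video"],
                        frame_rate=manifest["frame_rate_hz"])
    scene = SyntheticScene(frames=frames,
                           scale_mm_per_px=manifest["scale_mm_per_px"],
                           hr_bpm=manifest.get("hr_bpm"),
                           clock_offset_s=manifest.get("clock_offset_s", 0.0),
                           seed=manifest.get("seed", 0))
    files = manifest["files"]
    for key, name in files.items():
        path = scenedir / name
        if key.startswith("truth_disp_px_"):
            scene.truth_disp_px[key[-1]] = read_signal_csv(path)
        elif key.startswith("truth_disp_mm_"):
            scene.truth_disp_mm[key[-1]] = read_signal_csv(path)
        elif key.startswith("truth_accel_"):
            scene.truth_accel[key[-1]] = read_signal_csv(path)
        elif key == "ecg":
            scene.ecg = read_signal_csv(path)
        elif key == "daq_audio":
            scene.daq_audio = read_wav(path)
        elif key == "video_audio":
            scene.frames.audio = read_wav(path)
        elif key == "truth_rpeaks":
            from .beats import RPeakSeries
            df = pd.read_csv(path)
            scene.truth_rpeaks = RPeakSeries(
                indices=df["index"].to_numpy(int),
                fs=scene.ecg.fs if scene.ecg is not None else 5000.0)
    return scene
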