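"""Ground-truthed synthetic fixtures: cardiac-like chest displacement,
rendered videos of a textured target moving by that displacement, and
synthetic ECG with known R-peak times.

The displacement waveform emulates the two oscillatory bursts seen in each
cardiac cycle of a chest-vibration record (one near the first heart sound,
one near the second): per beat, two Gabor-like packets with carriers in the
10-20 Hz range and ~0.1 mm amplitude, plus low-level 1/f drift noise kept
below 25 Hz so the waveform is representable at 60 fps video. These are
deliberate stand-ins, not physiological simulations — they reproduce the
amplitude scale, band limits and beat periodicity of real chest vibration,
nothing more.

The renderer composites a band-limited high-contrast texture patch onto a
static background at sub-pixel positions using closed-form bilinear
resampling — the same interpolation family the tracker assumes — so the
prescribed displacement is an exact oracle for tracking accuracy. A
supersampled variant (area-style sampling) provides an independent
cross-check that results do not hinge on that shared assumption.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .beats import RPeakSeries
from .errors import DomainError, RenderBoundsError
from .signals import UniformSignal, displacement_to_acceleration
from .tracking import FrameSequence

__all__ = [
    "SyntheticScene",
    "make_scg_waveform",
    "make_synthetic_ecg",
    "make_texture",
    "render_video",
    "make_scene",
]

#: guard margin (px) between the texture border and the sampling window
_RENDER_MARGIN = 8


@dataclass
class SyntheticScene:
    """A rendered scene plus every ground-truth channel needed to validate
    the full pipeline."""

    frames: FrameSequence
    #: prescribed patch displacement at the frame rate, pixels, per axis
    truth_disp_px: dict = field(default_factory=dict)
    #: full-rate displacement waveform, millimeters, per axis
    truth_disp_mm: dict = field(default_factory=dict)
    #: full-rate ground-truth acceleration, m/s^2, per axis
    truth_accel: dict = field(default_factory=dict)
    ecg: UniformSignal | None = None
    truth_rpeaks: RPeakSeries | None = None
    daq_audio: UniformSignal | None = None
    scale_mm_per_px: float = 1.0
    hr_bpm: float | None = None
    clock_offset_s: float = 0.0
    seed: int = 0


def make_scg_waveform(hr_bpm: float, duration: float, fs: float,
                      seed: int, amp_mm: float = 0.1,
                      noise_mm: float = 0.003,
                      t_first_beat: float = 0.0) -> UniformSignal:
    """Cardiac-like chest displacement waveform in millimeters.

    Each beat contributes two Gabor packets: centers at 5% and 35% of the
    cycle, carrier frequencies drawn once per waveform from 10-20 Hz, and
    amplitudes ``amp_mm`` and ``0.6 * amp_mm``. A slow per-beat heave (a
    smooth hump of ``0.4 * amp_mm`` once per cycle) supplies the
    beat-fundamental energy that real chest motion carries and that
    rate-from-SCG estimators rely on. Seeded 1/f noise (lowpassed to
    < 25 Hz) adds baseline drift. Spectral energy above 30 Hz stays below
    1% of the total, so the waveform is faithfully representable at 60 fps.
    ``t_first_beat`` shifts the beat grid so the waveform can be
    phase-locked to an ECG's R-peak times.
    """
    if not (30 <= hr_bpm <= 180):
        raise DomainError(f"hr_bpm {hr_bpm} outside [30, 180]")
    if fs < 120:
        raise DomainError("waveform sampling rate must be >= 120 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    period = 60.0 / hr_bpm

    f1 = rng.uniform(12.0, 18.0)
    f2 = rng.uniform(10.0, 16.0)
    phase1 = rng.uniform(0, 2 * np.pi)
    phase2 = rng.uniform(0, 2 * np.pi)
    sigma1, sigma2 = 0.040, 0.050          # packet envelopes, seconds
    x = np.zeros(n)
    n_beats = int(np.ceil(duration / period)) + 1
    for k in range(-2, n_beats):
        t0 = t_first_beat + k * period
        for center, carrier, phase, sigma, amp in (
                (0.05 * period, f1, phase1, sigma1, amp_mm),
                (0.35 * period, f2, phase2, sigma2, 0.6 * amp_mm)):
            tc = t - t0 - center
            mask = np.abs(tc) < 5 * sigma
            x[mask] += (amp * np.exp(-0.5 * (tc[mask] / sigma) ** 2)
                        * np.cos(2 * np.pi * carrier * tc[mask] + phase))
        # slow cardiac heave: one smooth hump per cycle
        sigma_h = 0.12 * period
        tc = t - t0 - 0.2 * period
        mask = np.abs(tc) < 5 * sigma_h
        x[mask] += 0.4 * amp_mm * np.exp(-0.5 * (tc[mask] / sigma_h) ** 2)

    # seeded 1/f drift, band-limited below 25 Hz
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shaping = np.zeros_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    shaping[freqs > 25.0] = 0.0
    drift = np.fft.irfft(spec * shaping, n)
    rms = np.sqrt(np.mean(drift**2))
    if rms > 0:
        x += drift * (noise_mm / rms)
    return UniformSignal(x, fs, units="mm")


def make_synthetic_ecg(hr_bpm: float, duration: float, fs: float,
                       snr_db: float | None = None, seed: int = 0,
                       rr_jitter: float = 0.0
                       ) -> tuple[UniformSignal, RPeakSeries]:
    """Synthetic ECG with known R-peak times.

    QRS complexes are narrow Gaussian R waves flanked by small negative Q/S
    lobes, with P and T humps; Gaussian noise is added at ``snr_db``
    relative to the clean signal RMS (None = noiseless). ``rr_jitter``
    perturbs each beat time by up to that fraction of the RR interval
    (<= 0.02). Returns the signal and the true R-peak indices.
    """
    if fs < 100:
        raise DomainError("ECG sampling rate must be >= 100 Hz")
    if not (0 <= rr_jitter <= 0.02):
        raise DomainError("rr_jitter must be within [0, 0.02]")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    period = 60.0 / hr_bpm
    beat_times = np.arange(0.5 * period, duration - 0.2 * period, period)
    if rr_jitter > 0:
        beat_times = beat_times + rng.uniform(-rr_jitter, rr_jitter,
                                              len(beat_times)) * period

    def hump(center, sigma, amp):
        tc = t - center
        mask = np.abs(tc) < 6 * sigma
        out = np.zeros(n)
        out[mask] = amp * np.exp(-0.5 * (tc[mask] / sigma) ** 2)
        return out

    x = np.zeros(n)
    for tb in beat_times:
        x += hump(tb, 0.012, 1.0)            # R
        x += hump(tb - 0.030, 0.009, -0.15)  # Q
        x += hump(tb + 0.035, 0.010, -0.20)  # S
        x += hump(tb - 0.170, 0.030, 0.12)   # P
        x += hump(tb + 0.250, 0.050, 0.30)   # T
    if snr_db is not None:
        noise_rms = np.sqrt(np.mean(x**2)) * 10 ** (-snr_db / 20)
        x = x + rng.standard_normal(n) * noise_rms
    r_indices = np.round(beat_times * fs).astype(int)
    r_indices = r_indices[(r_indices >= 0) & (r_indices < n)]
    return (UniformSignal(x, fs, units="mV"),
            RPeakSeries(indices=r_indices, fs=fs))


def make_texture(size: int, seed: int, smooth_px: float = 2.0) -> np.ndarray:
    """Band-limited high-contrast texture: Gaussian-smoothed uniform noise
    stretched to the [0.05, 0.95] intensity range."""
    rng = np.random.default_rng(seed)
    tex = ndimage.gaussian_filter(rng.uniform(0, 1, (size, size)), smooth_px)
    tex = (tex - tex.min()) / (tex.max() - tex.min())
    return 0.05 + 0.90 * tex


def _sample_bilinear(tex: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(tex, [rows, cols], order=1, mode="nearest")


def render_video(waveform_x: UniformSignal, waveform_y: UniformSignal,
                 scale_mm_per_px: float, fps: float, texture_seed: int,
                 patch_px: int = 96, border_px: int = 24,
                 noise_sigma: float = 0.0, oversample: int = 1,
                 t_start: float = 0.0, duration: float | None = None
                 ) -> SyntheticScene:
    """Render a video of a textured patch translating by the prescribed
    displacement waveforms.

    Frame n (at time ``t_start + n/fps`` on the waveform clock) shows the
    texture shifted by ``waveform(t)/scale_mm_per_px`` pixels, sampled by
    closed-form bilinear resampling inside a fixed window composited on a
    uniform background. ``oversample > 1`` instead averages an NxN grid of
    sub-pixel samples per output pixel (area-style sampling), providing a
    renderer independent of the tracker's bilinear model. Motion beyond the
    guard margin raises :class:`RenderBoundsError`.
    """
    if abs(waveform_x.fs - waveform_y.fs) > 1e-9:
        raise DomainError("x/y waveforms must share a sampling rate")
    if duration is None:
        duration = waveform_x.duration - t_start
    n_frames = int(round(duration * fps))
    t_frames = t_start + np.arange(n_frames) / fps
    dx_px = np.interp(t_frames, waveform_x.times, waveform_x.values) / scale_mm_per_px
    dy_px = np.interp(t_frames, waveform_y.times, waveform_y.values) / scale_mm_per_px
    # displacement is reported relative to frame 1, matching the tracker
    dx_px = dx_px - dx_px[0]
    dy_px = dy_px - dy_px[0]
    max_motion = max(np.abs(dx_px).max(), np.abs(dy_px).max())
    if max_motion > _RENDER_MARGIN - 2:
        raise RenderBoundsError(
            f"motion amplitude {max_motion:.1f} px exceeds the "
            f"{_RENDER_MARGIN - 2} px guard margin")

    tex = make_texture(patch_px + 2 * _RENDER_MARGIN, texture_seed)
    rng = np.random.default_rng(texture_seed + 1)
    frame_size = patch_px + 2 * border_px
    window = slice(border_px, border_px + patch_px)
    base_rows, base_cols = np.mgrid[0:patch_px, 0:patch_px].astype(float)
    base_rows += _RENDER_MARGIN
    base_cols += _RENDER_MARGIN

    frames = np.full((n_frames, frame_size, frame_size), 0.5)
    for i in range(n_frames):
        rows = base_rows - dy_px[i]
        cols = base_cols - dx_px[i]
        if oversample <= 1:
            patch = _sample_bilinear(tex, rows, cols)
        else:
            patch = np.zeros((patch_px, patch_px))
            offsets = (np.arange(oversample) + 0.5) / oversample - 0.5
            for oy in offsets:
                for ox in offsets:
                    patch += _sample_bilinear(tex, rows + oy, cols + ox)
            patch /= oversample**2
        frames[i, window, window] = patch
    if noise_sigma > 0:
        frames = np.clip(frames + rng.normal(0, noise_sigma, frames.shape),
                         0.0, 1.0)

    fseq = FrameSequence(frames=frames, frame_rate=fps)
    scene = SyntheticScene(frames=fseq, scale_mm_per_px=scale_mm_per_px,
                           seed=texture_seed)
    scene.truth_disp_px = {
        "x": UniformSignal(dx_px, fps, units="pixel"),
        "y": UniformSignal(dy_px, fps, units="pixel"),
    }
    return scene


def _tap_track(duration: float, fs: float, tap_times, seed: int) -> UniformSignal:
    """Quiet audio track with short decaying tap bursts at the given times."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    x = rng.normal(0, 0.002, n)
    t_burst = np.arange(int(0.03 * fs)) / fs
    burst = np.exp(-t_burst / 0.008) * np.sin(2 * np.pi * 1200 * t_burst)
    for tt in tap_times:
        i0 = int(round(tt * fs))
        seg = burst[:max(0, n - i0)]
        if i0 >= 0 and len(seg):
            x[i0:i0 + len(seg)] += 0.8 * seg
    return UniformSignal(x, fs, units="a.u.")


def make_scene(hr_bpm: float = 72.0, duration: float = 20.0, fps: float = 60.0,
               fs_ref: float = 5000.0, scale_mm_per_px: float = 0.1,
               seed: int = 0, ecg_snr_db: float | None = 20.0,
               noise_sigma: float = 0.0, clock_offset_s: float = 0.0,
               audio_fs: float = 8000.0, amp_mm: float = 0.1) -> SyntheticScene:
    """Assemble a complete synchronized recording session.

    One waveform per axis drives the rendered video (sampled at ``fps`` on
    the video clock, which starts ``clock_offset_s`` after the reference
    clock) while the reference channels — displacement, acceleration, ECG
    with true R peaks, and tap audio — live at ``fs_ref`` on the reference
    clock. Tap bursts at 0.5 s and ``duration - 0.5`` s appear in both
    audio tracks, so clock alignment is recoverable exactly as in a real
    two-instrument session.
    """
    if not (0 <= clock_offset_s <= 0.4):
        raise DomainError("clock_offset_s must be within [0, 0.4] s")
    # phase-lock the vibration bursts to the ECG beat grid (R waves sit at
    # half a period plus multiples of the period; bursts follow each R)
    t_first = 0.5 * 60.0 / hr_bpm
    wx = make_scg_waveform(hr_bpm, duration, fs_ref, seed, amp_mm=amp_mm,
                           t_first_beat=t_first)
    wy = make_scg_waveform(hr_bpm, duration, fs_ref, seed + 1, amp_mm=amp_mm,
                           t_first_beat=t_first)
    ecg, rpeaks = make_synthetic_ecg(hr_bpm, duration, fs_ref,
                                     snr_db=ecg_snr_db, seed=seed + 2)
    scene = render_video(wx, wy, scale_mm_per_px, fps,
                         texture_seed=seed + 3, noise_sigma=noise_sigma,
                         t_start=clock_offset_s)
    scene.hr_bpm = hr_bpm
    scene.clock_offset_s = clock_offset_s
    scene.seed = seed
    scene.truth_disp_mm = {"x": wx, "y": wy}
    scene.truth_accel = {axis: displacement_to_acceleration(w)
                         for axis, w in scene.truth_disp_mm.items()}
    scene.ecg = ecg
    scene.truth_rpeaks = rpeaks

    tap_times = (0.5, duration - 0.5)
    scene.daq_audio = _tap_track(duration, fs_ref, tap_times, seed + 4)
    video_taps = [tt - clock_offset_s for tt in tap_times]
    scene.frames.audio = _tap_track(duration - clock_offset_s, audio_fs,
                                    video_taps, seed + 5)
    return scene
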