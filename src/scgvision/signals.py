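"""Uniformly sampled 1-D signals and the operations that prepare them for
beat-level comparison: numerical differentiation, rate conversion, band
filtering, and two-clock synchronization via audio taps.

The central container is :class:`UniformSignal` — a plain value/rate/units
triple used for displacement, acceleration, ECG and audio channels alike.
All chest-vibration content of interest lives below 30 Hz (half the 60 fps
video rate), which motivates the default band edges used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal as sps

from .errors import (
    ClockDriftError,
    DomainError,
    InsufficientAnchorsError,
    NoTapsError,
    SignalLengthError,
)

__all__ = [
    "UniformSignal",
    "SyncEvents",
    "ClockMap",
    "displacement_to_acceleration",
    "resample_to",
    "bandpass",
    "detect_taps",
    "align_clocks",
]


@dataclass(frozen=True)
class UniformSignal:
    """A uniformly sampled real-valued series.

    Parameters
    ----------
    values : ndarray
        Sample values; finite, length >= 2.
    fs : float
        Sampling frequency in Hz, > 0.
    units : str
        Free-text physical units ("mm", "m/s^2", "mV", "a.u.").
    t0 : float
        Time of the first sample on the signal's own clock, seconds.
    """

    values: np.ndarray
    fs: float
    units: str = "a.u."
    t0: float = 0.0

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.fs <= 0:
            raise DomainError(f"fs must be positive, got {self.fs}")
        if values.ndim != 1 or values.size < 2:
            raise SignalLengthError("signal must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise DomainError("signal contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        """Record duration in seconds (n / fs)."""
        return len(self.values) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds on the signal's own clock."""
        return self.t0 + np.arange(len(self.values)) / self.fs

    def with_values(self, values: np.ndarray, units: str | None = None) -> "UniformSignal":
        return replace(self, values=np.asarray(values, float),
                       units=self.units if units is None else units)


@dataclass(frozen=True)
class SyncEvents:
    """Tap events detected in an audio channel, on that channel's clock."""

    tap_times: np.ndarray
    detection_threshold: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.tap_times, dtype=float)
        object.__setattr__(self, "tap_times", t)
        if t.size < 1:
            raise NoTapsError("at least one tap event required")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise DomainError("tap times must be strictly increasing")


@dataclass(frozen=True)
class ClockMap:
    """Affine map from a source clock to a target clock.

    ``t_target = offset + drift * t_source``. Drift is dimensionless and must
    lie in [0.9, 1.1]: consumer-grade clocks disagree by far less, so values
    outside that range indicate mismatched tap events rather than real drift.
    """

    offset: float
    drift: float = 1.0

    def __post_init__(self):
        if not (0.9 <= self.drift <= 1.1):
            raise ClockDriftError(f"drift {self.drift:.4f} outside [0.9, 1.1]")

    def apply(self, t):
        return self.offset + self.drift * np.asarray(t, float)


def displacement_to_acceleration(disp: UniformSignal) -> UniformSignal:
    """Second-difference acceleration from a calibrated displacement signal.

    Interior samples use the central second difference
    ``a[n] = (x[n+1] - 2 x[n] + x[n-1]) * fs**2``; the two endpoint samples
    replicate their nearest interior value so the output keeps the input
    length. Millimeter input is converted so the output is in m/s^2.
    """
    if len(disp) < 3:
        raise SignalLengthError("need at least 3 samples to differentiate twice")
    x = disp.values
    a = np.empty_like(x)
    a[1:-1] = (x[2:] - 2.0 * x[1:-1] + x[:-2]) * disp.fs**2
    a[0] = a[1]
    a[-1] = a[-2]
    units = disp.units
    if units == "mm":
        a = a * 1e-3
        units = "m/s^2"
    elif units == "m":
        units = "m/s^2"
    else:
        units = f"{units}/s^2"
    return UniformSignal(a, disp.fs, units=units, t0=disp.t0)


def _antialias_fir(n_in: int, fs: float, f_nyq_min: float,
                   droop_fs: float | None) -> np.ndarray:
    """Linear-phase FIR lowpass at ``0.9..1.1 * f_nyq_min`` for rate ``fs``.

    When ``droop_fs`` is given, the passband additionally compensates the
    sinc^2 amplitude droop of a linear interpolator running at that source
    rate, so band-limited content survives rate conversion with <1% error.
    """
    pass_edge = 0.9 * f_nyq_min
    stop_edge = min(1.1 * f_nyq_min, 0.499 * fs)
    trans = stop_edge - pass_edge
    numtaps = int(np.ceil(7.0 * fs / trans)) // 2 * 2 + 1
    # keep the kernel shorter than the padded signal
    numtaps = min(numtaps, max(3, (n_in - 1) // 2 * 2 + 1))
    fgrid = np.linspace(0.0, pass_edge, 64)
    if droop_fs is not None:
        gains_pass = 1.0 / np.sinc(fgrid / droop_fs) ** 2
    else:
        gains_pass = np.ones_like(fgrid)
    freqs = np.concatenate([fgrid, [stop_edge, fs / 2]])
    gains = np.concatenate([gains_pass, [0.0, 0.0]])
    h = sps.firwin2(numtaps, freqs, gains, fs=fs)
    return h / h.sum()    # pin the DC gain to exactly 1


def _filter_zero_phase(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR with its group delay removed.

    The kernel is centered (odd length), so convolving the odd-reflection
    padded signal and taking the valid part yields zero net delay; odd
    reflection preserves the edge value and slope, keeping edge transients
    small for smooth signals.
    """
    half = len(h) // 2
    if half == 0:
        return x.copy()
    left = 2.0 * x[0] - x[1:half + 1][::-1]
    right = 2.0 * x[-1] - x[-half - 1:-1][::-1]
    padded = np.concatenate([left, x, right])
    return sps.fftconvolve(padded, h, mode="valid")


def resample_to(sig: UniformSignal, target_fs: float) -> UniformSignal:
    """Resample onto a uniform grid at ``target_fs`` by linear interpolation
    with FIR antialiasing at the lower of the two Nyquist frequencies.

    Upsampling: interpolate first, then lowpass (the filter also equalizes
    the interpolator's sinc^2 droop). Downsampling: lowpass at the source
    rate first, then interpolate. The FIR is linear-phase and applied with
    its group delay compensated, so timing is preserved. Duration is
    preserved to within one target sample period.
    """
    if target_fs <= 0:
        raise DomainError("target_fs must be positive")
    if target_fs == sig.fs:
        return sig
    f_nyq_min = 0.5 * min(sig.fs, target_fs)
    n_out = int(round(len(sig) * target_fs / sig.fs))
    n_out = max(n_out, 2)
    t_out = np.arange(n_out) / target_fs
    t_in = np.arange(len(sig)) / sig.fs
    if target_fs > sig.fs:
        y = np.interp(t_out, t_in, sig.values)
        h = _antialias_fir(len(y), target_fs, f_nyq_min, droop_fs=sig.fs)
        y = _filter_zero_phase(y, h)
    else:
        h = _antialias_fir(len(sig), sig.fs, f_nyq_min, droop_fs=None)
        xf = _filter_zero_phase(sig.values, h)
        y = np.interp(t_out, t_in, xf)
    return UniformSignal(y, target_fs, units=sig.units, t0=sig.t0)


def bandpass(sig: UniformSignal, lo: float, hi: float, order: int = 4) -> UniformSignal:
    """Zero-phase Butterworth bandpass (applied forward-backward).

    Zero net phase matters here because beat timing is compared across
    instruments; a causal filter would bias every lag estimate.
    """
    nyq = sig.fs / 2.0
    if not (0.0 < lo < hi < nyq):
        raise DomainError(f"band ({lo}, {hi}) Hz invalid for fs={sig.fs} Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=sig.fs, output="sos")
    y = sps.sosfiltfilt(sos, sig.values)
    return sig.with_values(y)


def detect_taps(audio: UniformSignal, threshold_factor: float = 8.0,
                window_s: float = 0.020, merge_s: float = 0.5) -> SyncEvents:
    """Find synchronization tap onsets in an audio track.

    A short-time energy envelope (boxcar of ``window_s``) is thresholded at
    ``threshold_factor`` times its median; each threshold crossing marks a
    tap onset, and crossings closer than ``merge_s`` are merged (a single
    physical tap rings for tens of milliseconds).
    """
    if audio.duration < 0.5:
        raise SignalLengthError("audio shorter than 0.5 s")
    win = max(1, int(round(window_s * audio.fs)))
    env = ndimage.uniform_filter1d(audio.values.astype(float) ** 2, win, mode="nearest")
    thr = threshold_factor * np.median(env)
    above = env > thr
    if not np.any(above):
        raise NoTapsError("no envelope crossing above threshold")
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        onsets = np.concatenate([[0], onsets])
    times = onsets / audio.fs + audio.t0
    merged = [times[0]]
    for t in times[1:]:
        if t - merged[-1] >= merge_s:
            merged.append(t)
    return SyncEvents(np.asarray(merged), detection_threshold=float(thr))


def align_clocks(src: SyncEvents, dst: SyncEvents) -> ClockMap:
    """Two-anchor clock alignment: the first and last taps of each recording
    correspond, fixing an affine map from the source clock to the target.

    drift = (dst_last - dst_first) / (src_last - src_first);
    offset = dst_first - drift * src_first. The map reproduces both anchor
    taps exactly.
    """
    if len(src.tap_times) < 2 or len(dst.tap_times) < 2:
        raise InsufficientAnchorsError("need >= 2 tap events on both clocks")
    s0, s1 = src.tap_times[0], src.tap_times[-1]
    d0, d1 = dst.tap_times[0], dst.tap_times[-1]
    drift = (d1 - d0) / (s1 - s0)
    if not (0.9 <= drift <= 1.1):
        raise ClockDriftError(f"drift {drift:.4f} outside [0.9, 1.1]; "
                              "tap events probably mismatched")
    offset = d0 - drift * s0
    return ClockMap(offset=float(offset), drift=float(drift))
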