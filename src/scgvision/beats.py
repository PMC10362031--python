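"""ECG R-peak detection and beat-synchronous segmentation of SCG signals.

R peaks are found with the classic Pan-Tompkins chain (bandpass 5-15 Hz,
derivative, squaring, 150 ms moving-window integration, adaptive dual
thresholds with a 200 ms refractory period and RR-based searchback). SCG
records are then cut into one window per cardiac cycle, anchored a quarter
cycle before each R peak — ``SCG[n_i - n_c/4 : n_i + 3 n_c/4)`` with ``n_c``
the average cycle length in samples — and ensemble-averaged to suppress
beat-to-beat variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal as sps

from .errors import (
    CannotComputeCycleError,
    DomainError,
    EmptySegmentationError,
    NoBeatsError,
    SignalLengthError,
)
from .signals import UniformSignal

__all__ = [
    "RPeakSeries",
    "BeatSegmentation",
    "EnsembleWaveform",
    "detect_r_peaks",
    "segment_beats",
    "ensemble_average",
]


@dataclass(frozen=True)
class RPeakSeries:
    """R-peak sample indices on the ECG's own grid (0-based)."""

    indices: np.ndarray
    fs: float

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if self.fs <= 0:
            raise DomainError("fs must be positive")
        if idx.size > 1 and not np.all(np.diff(idx) > 0):
            raise DomainError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def times(self) -> np.ndarray:
        """R-peak times in seconds."""
        return self.indices / self.fs


@dataclass
class BeatSegmentation:
    """Equal-length beat windows cut around R peaks.

    ``segments`` is (n_beats, n_c); ``kept_beats`` lists the indices (into
    the R-peak series) of beats whose full window fit inside the record;
    ``dropped_beats`` the ones that did not.
    """

    n_c: int
    segments: np.ndarray
    kept_beats: np.ndarray
    dropped_beats: np.ndarray
    fs: float

    @property
    def n_beats(self) -> int:
        return self.segments.shape[0]


@dataclass
class EnsembleWaveform:
    """Pointwise mean across beat segments."""

    values: np.ndarray
    n_beats: int
    fs: float

    def __len__(self) -> int:
        return len(self.values)


# Pan-Tompkins internal constants, from the original algorithm (not tunable
# per-study): QRS energy band, integration window, refractory period.
_PT_BAND = (5.0, 15.0)
_PT_INTEGRATION_S = 0.150
_PT_REFRACTORY_S = 0.200
_PT_SEARCHBACK_FACTOR = 1.66
_PT_REFINE_S = 0.025


def detect_r_peaks(ecg: UniformSignal) -> RPeakSeries:
    """Pan-Tompkins QRS detection.

    Returns R indices refined to the local maximum of the bandpass-filtered
    ECG within +-25 ms of each detection, so the reported index sits on the
    R wave rather than on the energy envelope.
    """
    if ecg.fs < 100:
        raise DomainError("ECG sampling rate must be >= 100 Hz")
    if ecg.duration < 2.0:
        raise SignalLengthError("ECG record shorter than 2 s")
    fs = ecg.fs
    x = ecg.values - np.mean(ecg.values)

    sos = sps.butter(2, _PT_BAND, btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(filtered) * fs
    squared = deriv**2
    win = max(1, int(round(_PT_INTEGRATION_S * fs)))
    integrated = ndimage.uniform_filter1d(squared, win, mode="nearest")

    refractory = int(round(_PT_REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(integrated, distance=max(1, refractory))
    if cand.size == 0:
        raise NoBeatsError("no candidate peaks in the integrated ECG")

    # adaptive dual thresholds on the integrated signal (Pan-Tompkins running
    # estimates of signal and noise peak levels)
    spki = float(np.max(integrated[:int(2 * fs)])) * 0.5
    npki = float(np.mean(integrated[:int(2 * fs)])) * 0.5
    peaks: list[int] = []

    def threshold1():
        return npki + 0.25 * (spki - npki)

    rr_history: list[float] = []
    last_accepted: int | None = None
    i = 0
    while i < len(cand):
        idx = cand[i]
        val = integrated[idx]
        if val > threshold1():
            peaks.append(idx)
            spki = 0.125 * val + 0.875 * spki
            if last_accepted is not None:
                rr_history.append((idx - last_accepted) / fs)
                rr_history = rr_history[-8:]
            last_accepted = idx
        else:
            # searchback: if the expected beat is overdue, accept the best
            # candidate since the last beat at half threshold
            overdue = (last_accepted is not None and rr_history
                       and (idx - last_accepted) / fs
                       > _PT_SEARCHBACK_FACTOR * float(np.mean(rr_history)))
            if overdue and val > 0.5 * threshold1():
                peaks.append(idx)
                spki = 0.25 * val + 0.75 * spki
                last_accepted = idx
            else:
                npki = 0.125 * val + 0.875 * npki
        i += 1

    if not peaks:
        raise NoBeatsError("no R peaks above the adaptive threshold")

    # refine each detection to the local max of the filtered ECG
    half = max(1, int(round(_PT_REFINE_S * fs)))
    refined = []
    for p in peaks:
        lo = max(0, p - half)
        hi = min(len(filtered), p + half + 1)
        refined.append(lo + int(np.argmax(filtered[lo:hi])))
    refined = np.unique(refined)
    # enforce the refractory period after refinement
    keep = [int(refined[0])]
    for r in refined[1:]:
        if r - keep[-1] >= refractory:
            keep.append(int(r))
        elif filtered[r] > filtered[keep[-1]]:
            keep[-1] = int(r)
    return RPeakSeries(indices=np.asarray(keep), fs=fs)


def segment_beats(scg: UniformSignal, rpeaks: RPeakSeries) -> BeatSegmentation:
    """Cut the SCG record into one window per R peak.

    The average cycle length ``n_c`` is the mean RR interval rounded to the
    nearest integer sample count. The window for beat i starts
    ``floor(n_c/4)`` samples before the R peak and runs ``n_c`` samples, so
    each segment covers a quarter cycle of pre-R context and three quarters
    after. Beats whose window leaves the record are dropped (padding would
    break the rectangular segment matrix the similarity index requires).
    """
    if abs(scg.fs - rpeaks.fs) > 1e-9:
        raise DomainError(f"SCG fs {scg.fs} != R-peak fs {rpeaks.fs}; "
                          "resample/synchronize first")
    if len(rpeaks) < 2:
        raise CannotComputeCycleError(
            "need >= 2 R peaks to compute the average cycle length")
    n_c = int(round(float(np.mean(np.diff(rpeaks.indices)))))
    if n_c < 4:
        raise CannotComputeCycleError(f"cycle length n_c={n_c} too short")
    pre = n_c // 4
    kept, dropped, rows = [], [], []
    n = len(scg.values)
    for k, ni in enumerate(rpeaks.indices):
        start = ni - pre
        stop = start + n_c
        if start < 0 or stop > n:
            dropped.append(k)
            continue
        kept.append(k)
        rows.append(scg.values[start:stop])
    segments = (np.asarray(rows) if rows
                else np.empty((0, n_c)))
    return BeatSegmentation(n_c=n_c, segments=segments,
                            kept_beats=np.asarray(kept, int),
                            dropped_beats=np.asarray(dropped, int),
                            fs=scg.fs)


def ensemble_average(seg: BeatSegmentation) -> EnsembleWaveform:
    """Pointwise arithmetic mean across beat segments."""
    if seg.n_beats < 1:
        raise EmptySegmentationError("no segments to average")
    return EnsembleWaveform(values=seg.segments.mean(axis=0),
                            n_beats=seg.n_beats, fs=seg.fs)
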