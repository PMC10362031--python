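"""Beat-to-beat heart rate from ECG R peaks and from vision-based SCG.

From ECG, the rate over each RR interval is ``60 / (t(n_{i+1}) - t(n_i))``
bpm. From SCG, a deliberately simple estimator is used: bandpass the signal
to the fundamental heart-rate band (0.7-1.5 Hz, i.e. 42-90 bpm), find the
peaks of the filtered signal, and convert consecutive peak intervals to bpm
the same way. The narrow band suppresses the intra-beat oscillatory bursts
so that one peak survives per cardiac cycle; the trade-off is reduced
fidelity outside the band (underestimation above ~81 bpm, wider dispersion
below 60 bpm), which is accepted rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .beats import RPeakSeries
from .errors import DomainError, InsufficientBeatsError, SignalLengthError
from .signals import UniformSignal, bandpass

__all__ = ["HrSeries", "hr_from_r_peaks", "hr_from_scg", "HR_BAND"]

#: fundamental heart-rate band for the SCG peak-picking estimator, Hz
HR_BAND = (0.7, 1.5)

#: minimum peak separation (s) — a 150 bpm ceiling — and the prominence
#: floor as a fraction of the filtered signal's SD
_MIN_PEAK_SEPARATION_S = 0.4
_PROMINENCE_SD = 0.25
#: peaks within this many band periods (1/lo) of a record edge are ignored:
#: the zero-phase narrowband filter rings for a few periods at the edges,
#: phase-modulating nearby peaks
_EDGE_GUARD_PERIODS = 3.0
#: RR intervals outside this multiplicative window around the median are
#: artifacts of a missed or split peak and are discarded
_RR_ARTIFACT_WINDOW = (0.65, 1.55)


@dataclass
class HrSeries:
    """Per-interval heart rate: one bpm value per consecutive beat pair,
    timestamped at the interval midpoint."""

    times: np.ndarray
    bpm: np.ndarray
    source: str

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.bpm = np.asarray(self.bpm, float)

    def __len__(self) -> int:
        return len(self.bpm)

    @property
    def mean_bpm(self) -> float:
        """Record-average heart rate (for Bland-Altman style summaries)."""
        return float(np.mean(self.bpm))


def hr_from_r_peaks(rpeaks: RPeakSeries) -> HrSeries:
    """Beat-to-beat heart rate from ECG R-peak times:
    bpm_i = 60 / (t(n_{i+1}) - t(n_i))."""
    if len(rpeaks) < 2:
        raise InsufficientBeatsError("need >= 2 R peaks for an RR interval")
    t = rpeaks.times
    rr = np.diff(t)
    return HrSeries(times=(t[:-1] + t[1:]) / 2.0, bpm=60.0 / rr, source="ecg")


def hr_from_scg(scg_v: UniformSignal) -> HrSeries:
    """Heart rate from a vision-based SCG record by narrowband filtering
    and peak picking.

    The record is bandpassed to 0.7-1.5 Hz (zero-phase); peaks of the
    filtered signal are taken as one fiducial per cardiac cycle (minimum
    separation 0.4 s, prominence >= 0.25 SD of the filtered record), and
    consecutive peak intervals become bpm values. Two robustness guards
    apply: peaks within 3 band periods of either record edge are ignored
    (the narrowband filter rings there), and RR intervals outside
    0.65-1.55x the median RR — the signature of a missed or split peak —
    are discarded.
    """
    if scg_v.duration < 5.0:
        raise SignalLengthError("need >= 5 s of SCG for heart-rate estimation")
    if scg_v.fs < 10:
        raise DomainError("SCG sampling rate must be >= 10 Hz")
    filt = bandpass(scg_v, *HR_BAND)
    x = filt.values
    distance = max(1, int(round(_MIN_PEAK_SEPARATION_S * scg_v.fs)))
    prominence = _PROMINENCE_SD * float(np.std(x))
    peaks, _ = sps.find_peaks(x, distance=distance, prominence=prominence)
    t = peaks / scg_v.fs
    guard = _EDGE_GUARD_PERIODS / HR_BAND[0]
    if scg_v.duration > 2.5 * guard:
        t = t[(t >= guard) & (t <= scg_v.duration - guard)]
    if len(t) < 2:
        raise InsufficientBeatsError("fewer than 2 cardiac peaks after filtering")
    t = t + scg_v.t0
    rr = np.diff(t)
    mid = (t[:-1] + t[1:]) / 2.0
    med = float(np.median(rr))
    keep = (rr > _RR_ARTIFACT_WINDOW[0] * med) & (rr < _RR_ARTIFACT_WINDOW[1] * med)
    if not np.any(keep):
        raise InsufficientBeatsError("no plausible RR intervals")
    return HrSeries(times=mid[keep], bpm=60.0 / rr[keep], source="scg")
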