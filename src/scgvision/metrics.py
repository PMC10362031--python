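"""Agreement metrics between a vision-derived SCG waveform and its
accelerometer gold standard.

Four complementary views of agreement are provided:

* Pearson correlation of beat-ensemble waveforms (sensitive to residual
  inter-instrument lag);
* band-constrained dynamic time warping with a normalized similarity index
  ``S = (M - D) / M``, where ``D`` is the accumulated |a_i - b_j| cost along
  the optimal warping path (restricted to a corridor around the straight
  diagonal) and ``M = max|gold| * n_c`` bounds the cost of the worst flat
  mismatch — S is insensitive to small time warps that wreck the Pearson r;
* magnitude-squared wavelet coherence (analytic Morlet), a time-frequency
  map of local squared correlation with a cone of influence marking
  edge-contaminated regions;
* Bland-Altman bias and 1.96-SD limits of agreement for paired heart-rate
  estimates, plus a cross-correlation lag estimate between whole records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage, signal as sps, stats

from .beats import EnsembleWaveform
from .errors import (
    AlignmentError,
    DomainError,
    InfeasibleBandError,
    InsufficientPairsError,
    UndefinedCorrelationError,
    UndefinedLagError,
    ZeroNormalizerError,
)
from .signals import UniformSignal

__all__ = [
    "DtwResult",
    "SimilarityScore",
    "CoherenceMap",
    "AgreementStats",
    "pearson_r",
    "dtw_alignment",
    "similarity_index",
    "estimate_lag",
    "wavelet_coherence",
    "bland_altman",
]


@dataclass
class DtwResult:
    """Optimal banded-DTW alignment of two scalar series."""

    distance: float
    path: np.ndarray          # (k, 2) index pairs, (0,0) .. (na-1, nb-1)
    band_fraction: float


@dataclass
class SimilarityScore:
    """DTW-based similarity index S = (M - D) / M.

    ``in_range`` flags whether S landed in [0, 1]; out-of-range values are
    reported as-is, never clamped (they indicate a vision waveform whose
    warped distance exceeds the flat-zero bound M).
    """

    s: float
    m: float
    d: float
    axis_label: str = ""

    @property
    def in_range(self) -> bool:
        return 0.0 <= self.s <= 1.0


@dataclass
class CoherenceMap:
    """Magnitude-squared wavelet coherence over time and frequency.

    ``coherence`` is (n_freqs, n_times) in [0, 1]; ``coi`` gives, per time
    column, the lowest frequency unaffected by edge effects (rows with
    ``freqs >= coi[j]`` are inside the cone of influence).
    """

    coherence: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    coi: np.ndarray
    smoothing: dict

    def inside_coi(self) -> np.ndarray:
        """Boolean mask of map cells inside the cone of influence."""
        return self.freqs[:, None] >= self.coi[None, :]


@dataclass
class AgreementStats:
    """Bland-Altman bias and limits of agreement (bias -/+ 1.96 SD)."""

    bias: float
    loa_low: float
    loa_high: float
    n: int


def pearson_r(a, b) -> float:
    """Product-moment correlation of two equal-length series."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 3:
        raise DomainError("inputs must be equal-length with >= 3 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float(stats.pearsonr(a, b).statistic)


def _band_limits(na: int, nb: int, band_fraction: float | None):
    """Per-row column window of the warping corridor.

    The corridor has half-width ``ceil(band_fraction * max(na, nb))`` around
    the straight line from (0,0) to (na-1, nb-1).
    """
    if band_fraction is None:
        width = max(na, nb)
    else:
        width = int(np.ceil(band_fraction * max(na, nb)))
        width = max(width, 1)   # >=1 cell keeps the corners connectable
    slope = (nb - 1) / (na - 1) if na > 1 else 0.0
    i = np.arange(na)
    center = i * slope
    lo = np.maximum(0, np.ceil(center - width).astype(int))
    hi = np.minimum(nb - 1, np.floor(center + width).astype(int))
    if np.any(lo > hi):
        raise InfeasibleBandError("warping band leaves no admissible cells")
    return lo, hi


def dtw_alignment(a, b, band_fraction: float | None = 0.05) -> DtwResult:
    """Banded dynamic time warping with local cost |a_i - b_j|.

    Steps are (1,0), (0,1), (1,1); the path starts at (0,0), ends at
    (na-1, nb-1) and stays within the corridor of half-width
    ``ceil(band_fraction * max(na, nb))`` around the straight-line fit
    between the endpoints. ``band_fraction=None`` disables the constraint.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise DomainError("DTW inputs must be non-empty")
    na, nb = len(a), len(b)
    lo, hi = _band_limits(na, nb, band_fraction)

    INF = np.inf
    # banded storage: row i covers columns lo[i]..hi[i]
    prev_cost = None
    prev_lo = 0
    back = []  # per row: int8 array of step codes (0=diag,1=up,2=left)
    for i in range(na):
        li, hi_i = lo[i], hi[i]
        width = hi_i - li + 1
        cost_row = np.abs(a[i] - b[li:hi_i + 1])
        acc = np.empty(width)
        steps = np.zeros(width, dtype=np.int8)
        if i == 0:
            if li > 0:
                raise InfeasibleBandError("band excludes the (0,0) corner")
            acc[0] = cost_row[0]
            steps[0] = -1
            for j in range(1, width):
                acc[j] = acc[j - 1] + cost_row[j]
                steps[j] = 2
        else:
            pw = len(prev_cost)
            for j in range(width):
                col = li + j
                jp = col - prev_lo          # same column in previous row
                best = INF
                step = -1
                if 0 <= jp < pw and prev_cost[jp] < best:
                    best = prev_cost[jp]
                    step = 1                # up (i-1, j)
                if 0 <= jp - 1 < pw and prev_cost[jp - 1] <= best:
                    best = prev_cost[jp - 1]
                    step = 0                # diagonal (i-1, j-1)
                if j > 0 and acc[j - 1] < best:
                    best = acc[j - 1]
                    step = 2                # left (i, j-1)
                acc[j] = cost_row[j] + best
                steps[j] = step
        back.append((li, steps))
        prev_cost, prev_lo = acc, li
    if hi[-1] != nb - 1:
        raise InfeasibleBandError("band excludes the (na-1, nb-1) corner")
    distance = float(prev_cost[-1])
    if not np.isfinite(distance):
        raise InfeasibleBandError("no admissible path through the band")

    # backtrack one optimal path
    path = []
    i, col = na - 1, nb - 1
    while True:
        path.append((i, col))
        li, steps = back[i]
        step = steps[col - li]
        if step == -1:
            break
        if step == 0:
            i, col = i - 1, col - 1
        elif step == 1:
            i = i - 1
        else:
            col = col - 1
    path.reverse()
    return DtwResult(distance=distance, path=np.asarray(path, int),
                     band_fraction=band_fraction if band_fraction is not None else 1.0)


def similarity_index(gold: EnsembleWaveform | np.ndarray,
                     vision: EnsembleWaveform | np.ndarray,
                     band_fraction: float = 0.05,
                     axis_label: str = "") -> SimilarityScore:
    """Similarity index S = (M - D) / M between two beat ensembles.

    D is the banded-DTW distance and M = max|gold| * n_c, the cost a flat
    zero estimate would accumulate against the gold standard. Identical
    waveforms give S = 1; S is invariant to joint amplitude scaling.
    """
    g = gold.values if isinstance(gold, EnsembleWaveform) else np.asarray(gold, float)
    v = vision.values if isinstance(vision, EnsembleWaveform) else np.asarray(vision, float)
    if len(g) != len(v):
        raise DomainError("ensembles must have equal length (same n_c)")
    m = float(np.max(np.abs(g))) * len(g)
    if m == 0:
        raise ZeroNormalizerError("gold ensemble is identically zero")
    d = dtw_alignment(g, v, band_fraction).distance
    return SimilarityScore(s=(m - d) / m, m=m, d=d, axis_label=axis_label)


def estimate_lag(a: UniformSignal, b: UniformSignal, max_lag: float) -> float:
    """Lag (seconds) maximizing the normalized cross-correlation of b on a,
    over lags in [-max_lag, +max_lag]. Positive lag means b trails a."""
    if abs(a.fs - b.fs) > 1e-9:
        raise AlignmentError("signals must share a sampling rate")
    xa = a.values - np.mean(a.values)
    xb = b.values - np.mean(b.values)
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise UndefinedLagError("lag undefined for constant input")
    max_shift = int(round(max_lag * a.fs))
    if min(len(xa), len(xb)) < 2 * max_shift:
        raise DomainError("records shorter than twice the lag search range")
    full = sps.correlate(xb, xa, mode="full")
    lags = sps.correlation_lags(len(xb), len(xa), mode="full")
    sel = np.abs(lags) <= max_shift
    best = lags[sel][int(np.argmax(full[sel]))]
    return float(best / a.fs)


# Analytic Morlet with center frequency omega0 = 6 rad/s: the standard
# compromise between time and frequency resolution for cardiomechanical
# signals. pywt's "cmor" family implements exactly this envelope for B=2.
_OMEGA0 = 6.0
_MORLET_FC = _OMEGA0 / (2.0 * np.pi)      # cycles per unit time
_WAVELET = f"cmor2.0-{_MORLET_FC:.10f}"
#: time-smoothing width in wavelet e-folding times, and the number of
#: adjacent scales averaged; sized so the coherence estimator has enough
#: degrees of freedom that independent noise decorrelates (see docs)
_TIME_SMOOTH_EFOLDS = 3.0
_SCALE_SMOOTH = 7
_VOICES = 12


def _cwt_morlet(x: np.ndarray, fs: float, freqs: np.ndarray):
    scales = _MORLET_FC * fs / freqs
    coef, _ = pywt.cwt(x, scales, _WAVELET, sampling_period=1.0 / fs,
                       method="fft")
    return coef, scales


def _smooth(mat: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Coherence smoothing: per-scale boxcar in time spanning
    ``_TIME_SMOOTH_EFOLDS`` e-folding times (sqrt(2) * scale samples each),
    then a boxcar over ``_SCALE_SMOOTH`` adjacent scales."""
    out = np.empty_like(mat)
    for i, a in enumerate(scales):
        w = max(1, int(round(_TIME_SMOOTH_EFOLDS * np.sqrt(2.0) * a)))
        w = min(w, mat.shape[1])
        if np.iscomplexobj(mat):
            out[i] = (ndimage.uniform_filter1d(mat[i].real, w, mode="nearest")
                      + 1j * ndimage.uniform_filter1d(mat[i].imag, w, mode="nearest"))
        else:
            out[i] = ndimage.uniform_filter1d(mat[i], w, mode="nearest")
    return ndimage.uniform_filter1d(out, min(_SCALE_SMOOTH, len(scales)),
                                    axis=0, mode="nearest")


def wavelet_coherence(g: UniformSignal, v: UniformSignal,
                      f_max: float = 30.0) -> CoherenceMap:
    """Magnitude-squared wavelet coherence of two synchronized records.

        C(a,b) = |S(Cg* Cv)|^2 / ( S(|Cg|^2) * S(|Cv|^2) )

    with continuous analytic-Morlet transforms Cg, Cv and the smoothing
    operator S described in :func:`_smooth`. The frequency grid spans
    [max(2/duration, 0.5), f_max] Hz at 12 voices per octave (a record of
    finite length cannot resolve frequencies below ~2 cycles per record, so
    a nominal 0 Hz lower edge is realized as 2/duration). The cone of
    influence uses the Morlet e-folding time sqrt(2)*a: at distance d from
    the nearer record edge, frequencies below ``sqrt(2)*fc/d`` are flagged
    as edge-contaminated.
    """
    if abs(g.fs - v.fs) > 1e-9 or len(g) != len(v):
        raise AlignmentError("coherence inputs must share fs and length")
    if g.duration < 4.0:
        raise DomainError("need >= 4 s of signal for wavelet coherence")
    fs = g.fs
    dur = g.duration
    f_min = max(2.0 / dur, 0.5)
    n_freq = int(np.ceil(np.log2(f_max / f_min) * _VOICES)) + 1
    freqs = f_max * 2.0 ** (-np.arange(n_freq) / _VOICES)

    cg, scales = _cwt_morlet(g.values, fs, freqs)
    cv, _ = _cwt_morlet(v.values, fs, freqs)
    sxy = _smooth(np.conj(cg) * cv, scales)
    sxx = _smooth(np.abs(cg) ** 2, scales)
    syy = _smooth(np.abs(cv) ** 2, scales)
    coh = np.abs(sxy) ** 2 / (sxx * syy)

    n = len(g)
    dist_s = np.minimum(np.arange(n), n - 1 - np.arange(n)) / fs
    with np.errstate(divide="ignore"):
        coi = np.sqrt(2.0) * _MORLET_FC / np.maximum(dist_s, 1.0 / fs)
    smoothing = {"time_efolds": _TIME_SMOOTH_EFOLDS,
                 "scale_window": _SCALE_SMOOTH,
                 "voices_per_octave": _VOICES,
                 "wavelet": _WAVELET}
    return CoherenceMap(coherence=coh, freqs=freqs, times=g.times,
                        coi=coi, smoothing=smoothing)


def bland_altman(a, b) -> AgreementStats:
    """Bland-Altman agreement: bias = mean(a - b) and limits of agreement
    bias -/+ 1.96 * sample SD of the differences."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise InsufficientPairsError("need >= 2 paired values")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementStats(bias=bias, loa_low=bias - 1.96 * sd,
                          loa_high=bias + 1.96 * sd, n=len(d))
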