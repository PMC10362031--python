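# Methods

This note documents the models, algorithms, and numerical choices behind
`scgvision`, and what its synthetic-data validation does and does not
demonstrate.

## Problem setting

Seismocardiography (SCG) records the millimeter-scale vibrations of the
chest wall produced by the heart's mechanical activity, conventionally with
a chest-mounted accelerometer. `scgvision` implements a contactless
alternative: a camera observes a high-contrast target attached to the chest
(e.g. a printed QR-code sticker, used purely as texture), the target's
sub-pixel translation is tracked through the video, and twice
differentiating the calibrated displacement yields acceleration signals in
the image-plane axes — right-to-left (x) and head-to-foot (y). At 60 fps
the method covers the infrasonic SCG band up to 30 Hz.

## Template tracking

The tracker is a Lucas–Kanade / forward-additive Gauss–Newton solver for a
pure-translation warp. With template T cut from frame 1 and warp
W(x; u) = x + u, each frame minimizes

    E(u) = Σ_x [ I_n(W(x; u)) − T(x) ]²

by iterating

    Δu = H⁻¹ Σ_x ∇I_nᵀ [ T(x) − I_n(W(x; u)) ],
    H  = Σ_x ∇I_nᵀ ∇I_n,        u ← u + Δu,

until ‖Δu‖ ≤ ε. The Jacobian ∂W/∂u is the 2×2 identity for translation, so
H is the patch structure tensor. Choices a practitioner should know:

- **Interpolation.** Frame intensities at warped positions use bilinear
  interpolation (`scipy.ndimage.map_coordinates`, order 1), consistent with
  the first-order Taylor model; bicubic is available via
  `TrackerConfig(interpolation="bicubic")`.
- **Gradient.** ∇I is computed once per frame by central differences on the
  full frame and bilinearly sampled at the warped positions. On
  bilinear-resampled imagery this gradient acts like a half-pixel smoothing
  and empirically cancels most interpolation bias: rendered 0.3 px
  sinusoidal motion is recovered with ~5·10⁻⁴ px RMSE.
- **Convergence.** ε = 0.01 px and iᵐᵃˣ = 50. ε sits two orders below the
  0.05 px accuracy target; typical frames converge in 2–4 iterations.
- **Non-monotonicity.** Plain Gauss–Newton does not guarantee a monotone
  SSD decrease. With warm starts (each frame initialized at the previous
  frame's u) the converged SSD occasionally exceeds the starting SSD by a
  few percent of its noise floor while being the *better* displacement
  estimate; reverting to the lowest-SSD iterate would bias amplitudes low.
  The solver therefore keeps the final iterate and falls back to the best
  iterate only when the final SSD exceeds 1.10× the starting SSD (a real
  divergence). Per-frame initial and final SSD are recorded in the
  trajectory for auditing.
- **Degeneracy.** A template with zero variance is rejected at extraction;
  at solve time a structure tensor with condition number above 10⁶ raises a
  degenerate-texture error (texture too weak along one axis).
- **Template update.** Off by default: chest motion is small and the
  appearance of a rigid sticker is stable. The optional `drift_corrected`
  mode re-cuts a working template every m frames and refines every solve
  against the frame-1 template, so re-cut errors cannot accumulate.

### Camera calibration

For a fronto-parallel target plane, pixel displacement converts to
millimeters by a scaling factor: SF = D_mm / D_pixel from the target's known
physical size, or SF = d·p/f from pinhole geometry (object distance d,
sensor unit length p in µm/pixel, focal length f). The target-size route is
the default since the tracked sticker has a known printed size.
Calibration is single-application; trajectories carry a units flag.

## Signal processing

- **Acceleration.** Second central difference,
  a[n] = (x[n+1] − 2x[n] + x[n−1])·fs², exact for quadratics; endpoint
  samples replicate their nearest interior value to preserve length. Output
  in m/s².
- **Resampling.** Values are linearly interpolated onto the target grid and
  filtered with a linear-phase FIR lowpass at 0.9× the lower of the two
  Nyquist frequencies (applied at the source rate when downsampling). The
  filter is designed with `firwin2`; its passband equalizes the 
  sinc² amplitude droop of the linear interpolator — without this, a 25 Hz
  tone sampled at 60 Hz loses ~45% amplitude — and its length adapts to the
  transition band (≈7·fs/Δf taps, DC gain pinned to 1). Group delay is
  removed by centered convolution over an odd-reflection-padded signal,
  which preserves edge value and slope. Measured: 5 Hz tone error 0.03%,
  25 Hz error 0.1%, 60→5000→60 Hz round trip 0.08% RMS, phase shift ≪ 1 ms.
- **Band filtering.** 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`), giving zero net phase — essential because beat timing is
  compared across instruments. The SCG comparison band is 1–30 Hz (the
  video Nyquist bound at 60 fps).
- **Synchronization.** Two independently clocked instruments (camera and
  DAQ) each record the same microphone, tapped at the start and end of the
  session. Tap onsets are detected on a 20 ms short-time-energy envelope
  thresholded at 8× its median (crossings closer than 0.5 s merge); the
  first and last taps fix an affine clock map (offset + drift, drift
  sanity-bounded to [0.9, 1.1]). Tap timing is envelope-limited to a few
  milliseconds; this residual desynchronization is precisely why the
  warp-tolerant DTW similarity is the primary agreement metric and Pearson
  correlation the secondary one.

## Beat analysis

R peaks come from a Pan–Tompkins chain: 5–15 Hz bandpass (zero-phase),
derivative, squaring, 150 ms moving-window integration, adaptive dual
thresholds with a 200 ms refractory period and RR-overdue searchback at
half threshold, with each detection refined to the local maximum of the
filtered ECG within ±25 ms. These internal constants follow the classic
algorithm and are not study-tunable.

Segmentation cuts each SCG record into windows
[nᵢ − ⌊n_c/4⌋, nᵢ − ⌊n_c/4⌋ + n_c) around R peaks nᵢ, where n_c is the mean
RR interval rounded to integer samples — a quarter cycle of pre-R context
and three quarters after. Beats whose window leaves the record are dropped
(padding would break the rectangular segment matrix). The ensemble average
is the pointwise mean across segments; with k beats it suppresses
beat-incoherent noise by √k.

## Agreement metrics

- **DTW similarity index.** Segments are compared by dynamic time warping
  with local cost |aᵢ − bⱼ|, steps (1,0),(0,1),(1,1), constrained to a
  corridor of half-width ⌈0.05·max(len)⌉ cells around the straight line
  between the endpoints. The similarity index is S = (M − D)/M with D the
  optimal warped distance and M = max|gold| · n_c — the cost a flat-zero
  estimate would accumulate. S = 1 for identical waveforms; S is invariant
  to joint amplitude scaling and tolerant of small time warps. Values
  outside [0, 1] are possible for grossly mismatched amplitudes and are
  reported with a flag, never clamped. The banded dynamic program is exact
  (verified against exhaustive path enumeration); M uses the ensemble
  average, not individual segments.
- **Wavelet coherence.** Magnitude-squared coherence
  C = |S(C_g* C_v)|² / (S(|C_g|²)·S(|C_v|²)) of analytic-Morlet (ω₀ = 6)
  continuous wavelet transforms, on a scale grid of 12 voices/octave
  spanning [max(2/duration, 0.5), 30] Hz — a record of finite length cannot
  resolve lower frequencies, so a nominal 0 Hz edge is realized as
  2/duration. The smoothing operator S is a per-scale boxcar in time
  spanning 3 wavelet e-folding times (√2·a samples each) followed by a
  boxcar over 7 adjacent scales (≈0.6 octave). This sizing matters: with
  materially less smoothing the estimator's degrees of freedom collapse and
  independent white noise scores spuriously high coherence (≈0.64 mean with
  a 1-e-folding/3-scale smoother vs ≈0.29 with the chosen one; an
  unsmoothed estimator is identically 1). The cone of influence marks, per
  column, frequencies below √2·f_c/d (d = distance to the nearer edge) as
  edge-contaminated. Since all content lies below 30 Hz, the pipeline
  computes coherence on records resampled to 100 Hz; results are
  grid-independent for band-limited inputs and ~50× cheaper than at the
  5000 Hz analysis rate.
- **Lag.** Argmax of the full normalized cross-correlation within
  ±max_lag; positive lag means the second signal trails the first.
- **Bland–Altman.** Bias = mean difference of paired heart-rate estimates;
  limits of agreement = bias ± 1.96 × sample SD.

## Heart rate

From ECG: bpmᵢ = 60/(t(nᵢ₊₁) − t(nᵢ)) per RR interval. From SCG: the record
is bandpassed to the heart-rate fundamental band 0.7–1.5 Hz (42–90 bpm) and
peaks of the filtered signal — minimum separation 0.4 s (a 150 bpm
ceiling), prominence ≥ 0.25 SD — serve as per-cycle fiducials, with
intervals converted as above. Two robustness guards: peaks within 3 band
periods (≈4.3 s) of a record edge are discarded, because the zero-phase
narrowband filter rings there and phase-modulates nearby peaks; and RR
intervals outside 0.65–1.55× the median RR (the signature of a missed or
split peak) are rejected. This estimator is deliberately basic: rates above
90 bpm rely on the attenuated fundamental leaking past the band edge, and
no correction is applied for the known underestimation tendency at high
rates — fidelity to the simple filter-and-peak-pick scheme is preferred
over accuracy embellishments.

## Synthetic data: what it emulates, and what it does not

All validation runs on generated scenes with exact ground truth.

- **Displacement waveform.** Per cardiac cycle: two Gabor packets (centers
  at 5% and 35% of the cycle, carriers drawn from 10–20 Hz, amplitudes 0.1
  and 0.06 mm, envelopes 40/50 ms) standing in for the two intra-beat
  vibration bursts; a slow per-beat heave (Gaussian hump, 0.04 mm, σ =
  0.12 cycle) supplying the beat-fundamental energy that real chest motion
  carries and the heart-rate estimator relies on; and seeded 1/f drift
  (0.003 mm RMS, lowpassed below 25 Hz). Less than 1% of spectral power
  lies above 30 Hz, so the waveform is representable at 60 fps. These are
  amplitude- and band-matched stand-ins, not physiological simulations.
- **Renderer.** A Gaussian-smoothed noise texture (high contrast,
  band-limited) translates behind a fixed 96 px window composited on a
  uniform background, sampled by closed-form bilinear resampling at the
  prescribed sub-pixel offsets — the same interpolation family the tracker
  assumes, making the prescribed displacement an exact oracle. An
  `oversample=N` mode averages N×N sub-pixel samples per output pixel
  (area-style sampling) as an independent cross-check that accuracy does
  not hinge on the shared bilinear assumption. Regions of interest should
  stay ≥8 px inside the moving window: at the window boundary the
  full-frame gradient mixes static background into template-edge pixels
  and biases recovered amplitudes.
- **ECG.** Gaussian R waves with Q/S side lobes and P/T humps at programmed
  beat times (R truth indices returned), optional white noise at a given
  SNR and ≤2% RR jitter.
- **Sessions.** `make_scene` phase-locks the vibration waveform to the
  ECG beat grid, renders the video on a camera clock that may start up to
  0.4 s after the reference clock, and writes tap bursts at 0.5 s and
  duration − 0.5 s into both audio tracks, so synchronization is exercised
  exactly as in a two-instrument recording.

Passing on these scenes demonstrates the numerical correctness of every
stage and of the end-to-end chain under ideal optics. It does **not**
demonstrate robustness to real-world effects that the generator omits:
skin/cloth appearance change, lighting drift, camera shake, respiration
motion (the intended protocol is a breath-hold), target rotation or
off-plane tilt, and rolling-shutter artifacts.

## Problem sizes and defaults

Defaults mirror a typical recording session: 60 fps video, 5000 Hz
reference/analysis rate, 1–30 Hz SCG band, 5% DTW corridor, 0.7–1.5 Hz HR
band. The test suite and the acceptance script use 10–20 s records, ECG at
1000 Hz for detection checks, coherence at 100 Hz, and three programmed
rates (60/80/100 bpm) for end-to-end recovery; these sizes give stable
statistics (≈16–33 beats per record, 20 noise seeds for the coherence
floor) at interactive runtimes.

## Known limitations

- Pure-translation warp only: target rotation or perspective change is
  model violation, not handled.
- The scaling factor assumes a fronto-parallel target; tilt mixes axes and
  scales amplitudes.
- HR estimation degrades outside 42–90 bpm by construction of the band.
- Tap synchronization is milliseconds-accurate; residual lag depresses
  Pearson correlations between instruments (the DTW index is the intended
  primary metric).
- Wavelet coherence significance is not assessed (no surrogate testing);
  the white-noise floor (~0.3 with the default smoother) should be kept in
  mind when reading coherence maps.
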