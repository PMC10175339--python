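# Methods

## Signal model

Nasal airflow modulates the skin-surface temperature of the nostril
region: exhalation washes the area with near-core-temperature air,
inhalation with ambient air. The observable is the mean thermal
intensity over a small rectangle below the nose tip; its dominant
spectral component in the physiological band is the breathing frequency.
The pipeline assumes a single subject, rigidly co-mounted cameras
(one registration per recording), and breathing rates inside the
configured band — 0.1–0.85 Hz for adults, 0.5–1.5 Hz for neonates.

## Phase congruency and the log-Gabor bank

Phase congruency marks points where Fourier components align in phase,
independently of contrast — the property that lets features correspond
between reflected-light and emitted-heat images. For each scale `k` and
orientation `o` a 2-D log-Gabor filter (Gaussian transfer on the
log-frequency axis, Gaussian angular lobe, exactly zero DC gain) yields
quadrature responses `(E_ko, O_ko)` with amplitude
`A_ko = sqrt(E_ko² + O_ko²)`. Per orientation, the responses summed over
scales define a mean-phase unit vector via the total amplitude

    AR_o = sqrt((Σ_k E_ko)² + (Σ_k O_ko)²) + ε,

and the local energy is the projection of each scale's response onto
that vector minus the absolute out-of-phase component. The energy is
soft-thresholded by a noise estimate `T_N` and normalised by `Σ_k A_ko + ε`,
giving `PC_o ∈ [0, 1]`. We deliberately use the vector-magnitude form of
`AR_o`: a sum of *signed* responses under a single square root can go
negative and destroys the unit-norm property the mean-phase geometry
relies on, so the package documents this as its reading rather than
implementing an expression that is not well-defined.

Two further conventions:

- `T_N` is estimated per orientation from the finest-scale amplitude via
  the Rayleigh noise model (median-based scale estimate, extrapolated
  across scales by the geometric amplitude decay), times `noise_k`
  (default 2.0) standard deviations above the mean noise energy.
- The threshold is applied to the scale-summed energy (equivalently to a
  per-scale application with a shared weight, since the sigmoidal weight
  does not depend on scale).

Defaults: 4 scales, 6 orientations, minimum wavelength 3 px, scale
multiplier 2.1, `σ/f = 0.55`, `ε = 1e-4` — conventional settings for
phase-congruency feature detection. The angular lobe width defaults to
`(π/N_o)/2`, i.e. the neighbouring orientation sits two sigma away;
this keeps orientation channels cleanly separable (the dominant channel
carries ≥5× the energy of any other for a pure directional tone) while
the midpoint between lobes retains ~60% gain, and it sharpens the
orientation-index descriptors used for matching. The sigmoidal
frequency-spread weight uses gain 10 and cut-off 0.5. Filtering happens
in the frequency domain after symmetric boundary padding by the coarsest
wavelength, so wrap-around never masquerades as structure.

Moment analysis across the per-orientation PC maps
(`p = Σ(PC cosφ)²`, `q = 2Σ(PC cosφ)(PC sinφ)`, `r = Σ(PC sinφ)²`,
`M,m = (r+p ± sqrt(q²+(p−r)²))/2`) produces the maximum/minimum moment
images; corners are large in both, edges only in `M`.

## Registration

**Rig phase.** Checkerboard inner corners are found with a
polarity-agnostic X-junction kernel (absolute response of a 2×2-quadrant
template after light smoothing; sub-pixel peak by parabolic fit, with a
half-pixel correction because the even-sized kernel centres between
pixels). Corners are ordered row-major assuming near-axis-aligned
boards and a least-squares similarity (isotropic scale + translation;
rotation optionally enabled) is fitted. Scale-only is the default
because the cameras sit parallel on a common mount; residual rotation
is absorbed by the precise phase.

**Precise phase.** The visible frame is resampled into rough thermal
coordinates through the rig map; both images then go through the PC
chain. FAST corners (contiguous arc of 12 on the 16-pixel circle,
non-maximum suppression, strongest 500) are taken on min-max-normalised
`M` and `m`. Each keypoint is described by the orientation-index map
(per-pixel argmax orientation of the scale-summed amplitude, 1-based,
ties to the lowest index — invariant under any positive intensity
scaling): the 72 px patch is split into a 6×6 grid, each cell
contributing an `N_o`-bin index histogram, concatenated and
L2-normalised. On frames whose short side cannot accommodate the patch,
it shrinks to the largest grid multiple within a third of the short
side. Matching is SSD with the nearest-neighbour distance-ratio test
(`d1 ≤ 0.85·d2`) and mutual-best filtering; the affine is fitted by fast
sample consensus: sample 3 matches, fit, grow the inlier set (2 px
tolerance) by repeated refitting until it is a fixed point, keep the
largest consensus (ties: lowest RMS), 2000 trials, fully deterministic
under the configured seed. The refined map composed with the rig map is
held fixed for the recording.

ROI mapping transforms the 4 box corners, takes the axis-aligned
bounding box, rounds outward to integers and clips; a box fully outside
the thermal frame returns flagged empty (a detection failure for that
frame, not an error).

## ROI selection and tracking

`η` and `ω` from the landmark formulas use round-half-to-even (the
formulas only say "round"; the banker's convention removes a systematic
half-pixel bias). Degenerate geometry (`η = 0` or `ω = 0`) is an error;
boxes thinner than 2 px after clipping count as failed detections.

The landmark detector is a declared contract. The bundled
implementation locates the synthetic generator's colour-coded fiducial
markers by colour masking (confidence = visible fraction of the expected
disk area; threshold 0.6); an adapter slot for an external pretrained
face-landmark network satisfies the same contract but is not required
anywhere. While the loop is tracking, detection searches only a halo
(120 px) around the current ROI; in detecting mode the full frame.

The tracker is a normalised-cross-correlation template tracker:
grayscale ROI template, search window ±20 px, quality = correlation
peak, exponential template update with learning rate 0.075 applied only
on confident frames so occluders are not learned. `t_s` is
quality ≥ 0.5 — the failure criterion is this package's choice; nothing
in the problem statement defines when a tracker "fails".

Selection operator: both `t_s` and `d_s` True → the next frame tracks;
either False → tracking is disabled and detection takes over. A
successful detection in detecting mode (re)initialises the tracker and
counts as a healthy tracker for the transition; a failed tracking frame
keeps `t_s = False` even if detection succeeded that frame, so the loop
spends one frame in detection before resuming — the conservative reading
of the operator's truth table.

## Respiratory signal and rate

Frames without a valid ROI are flagged invalid and linearly interpolated
between neighbouring valid samples (edges held); gaps longer than 2 s
mark every overlapping window's estimate low-quality. The conditioning
chain is z-score → Hampel (half-window 1 s, 3 MAD-scaled sigma, MAD
floored at 1e-9 so flat stretches still reject spikes) → centred moving
average (~fs/3 samples, odd, shrinking at edges) → 2nd-order Butterworth
bandpass applied forward-backward. Zero-phase filtering is used because
a causal pass would delay the waveform without benefiting a
retrospective window estimate; the band edges are the −3 dB points of
the one-pass filter.

The chirp-Z transform evaluates the spectrum on `[low, high]` at 5 mHz
(0.3 bpm) — finer than the 1/30 Hz rectangular-window resolution, which
is the point of using the CZT for band zooming. The peak (global argmax,
ties to the lower frequency) gives `RR = 60·f_peak`; the peak-to-median
in-band magnitude ratio is reported as a quality index. Windows are
30 s sliding by 20 s, starting at t₀, as long as a full window fits.

A window whose in-band RMS falls below 25% of the whole-record RMS is
scored as a breathing pause (0 bpm, low quality): spectral peak-picking
has no notion of "no breath", so an explicit energy gate is the only way
a varying-pattern recording with stop segments can be scored honestly.
The margin between a breathing window (RMS ≈ record RMS) and a pause
window (band-filtered noise only, roughly an order of magnitude lower at
10 dB trace SNR) is wide, so the gate is insensitive to its exact value.

## Evaluation

AAE is the mean of `AE(k) = |BR_m(k) − BR_r(k)|`; SDE is the sample
standard deviation of AE about AAE with an N−1 denominator — exactly as
defined, even though an SD of *absolute* errors is an unusual statistic.
Bland-Altman uses measured − reference differences and ±1.96 sample-SD
limits. Window alignment is by start time and requires identical
window/step settings on both sides. The belt reference is converted to
windowed RR through the identical conditioning + CZT chain at the belt's
native 10 Hz — how the original reference rates were derived is not
stated anywhere, so "same chain, native rate" is documented as this
package's assumption rather than a reproduction.

## Synthetic data: what it emulates, and what it does not

The generator emulates the acquisition geometry (960×720 visible and
320×240 thermal at 30 fps, visible ≈ 3× thermal scale), a warm face
ellipse with an oscillating nostril patch (baseline 34 °C, amplitude
0.4 °C — mid-range for nasal airflow temperature modulation), textured
shared background structure so registration has features, checkerboard
rig frames with inverted thermal contrast, head-translation and
occlusion events, and a respiration belt observing the same waveform.
Noise has two parts: trace-level Gaussian noise on the patch temperature
sized by the requested SNR (`σ = A/√(2·10^(SNR/10))`), and 0.05 °C
per-pixel sensor noise matching the thermal sensitivity of the
acquisition hardware class. Breathing waveforms are phase-continuous
piecewise sinusoids; pauses are zero-amplitude segments with
raised-cosine amplitude cross-fades (≤1.5 s) so no step discontinuities
exist. All randomness flows from one seed (per-frame streams are seeded
by (seed, frame), so lazy frame synthesis is reproducible in any access
order).

Deliberately not emulated: photorealistic faces (the detector contract,
not face appearance, is under test — the visible face is a shaded,
speckled ellipse with colour-coded fiducial markers at the five landmark
positions), non-rigid facial motion, breathing-rate variability within a
segment, radiometric drift, lens distortion, and multi-person scenes.
Consequently, passing tests demonstrate the correctness of the geometry,
tracking logic and signal path under the stated conditions; they do not
certify detector robustness on real faces or thermal scenes — that is
exactly the part delegated to the pluggable external detector.

## Problem sizes and numerical choices

The closed-loop checks run a 90 s constant-rate recording and a 180 s
three-segment recording at the full default geometry, a 20-geometry
registration sweep, and 20-tone spectral cross-checks — sizes chosen so
the whole suite completes in minutes on one CPU while every windowed
estimate, not a subsample, is asserted. Ties in the orientation argmax
break toward the lowest index; FSC is deterministic given its seed; the
Hampel MAD floor, the `ε` guards, and outward ROI rounding are the only
places where exact arithmetic is deliberately biased, each noted above.

## Known limitations

- The rig corner finder assumes a near-axis-aligned board (a few degrees
  of roll at most) for row-major ordering.
- The NCC tracker handles translation only; in-plane rotation or scale
  change of the face degrades quality and falls back to detection.
- Registration is computed once per recording; a bumped camera mid-take
  would require re-running calibration.
- The pause gate is relative to the record's own RMS; a recording that
  is *mostly* pause would inflate window RMS ratios and could misscore
  short breathing bursts.
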