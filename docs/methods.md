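# Methods

This note documents the models, estimators and numerical choices behind
`cagevitals`, and what the synthetic validation does and does not show.

## Signal model of the synthetic cage scene

The generator renders a top-down view of a standard cage floor
(612 × 435 mm by default, the EUROSTANDARD Type III/IV footprint) at a
configurable sampling density (default 0.5 px/mm, matching a 320 px sensor
across the long cage side). Each animal is an anti-aliased ellipse
(default semi-axes 35 × 15 mm, a ~7 cm adult mouse) whose pixel coverage
varies continuously, so sub-pixel boundary motion is expressible.

Per animal, the scene encodes:

* **Respiration** — the ellipse semi-axes dilate as
  `Δ(t) = A_b · sin(2π f_rr t)` in pixels (default `A_b` = 0.8 px,
  `f_rr` = 150 breaths/min). This is the boundary expansion/contraction a
  top-down camera sees.
* **Cardiac iPPG** — a small fur-free "ear" disc (default radius 4 mm)
  rendered brighter than the body, with relative intensity modulation
  `1 + a·sin(2π f_hr t)` (default `a` = 0.05, `f_hr` = 500 beats/min). The
  amplitude is a synthetic choice, not a measured physiological value; no
  quantitative murine iPPG amplitude is available, so it is configurable
  and the recovery claims are conditional on it.
* **Optional cardiac micro-motion** — an extra boundary dilation at the
  heart rate (default 0 px) for the motion-based HR variant.
* **Thermal signature** — background at 22 °C, body at 37 °C with the
  anti-aliased edge acting as a smooth gradient, and the eye disc at
  38.5 °C as the hottest region. Thermal pixels are quantized to
  centi-kelvin (a radiometric sensor model), which also makes the uint16
  container round-trip bit-exact.
* **Noise** — i.i.d. Gaussian sensor noise per pixel (default sd 1.5
  intensity units for NIR on a 0–255-like scale; 0.05 °C for thermal,
  an NETD-like figure). The **ambient lighting** flag adds a frame-wide
  white noise term (default sd 3.0 units) that raises the spectral noise
  floor of every ROI without averaging down over pixels — the mechanism by
  which room lighting degrades iPPG SNR. An optional **room oscillation**
  adds a global 6 cycles/min sinusoid, the slow building/illumination sway
  visible in real recordings even in animal-free reference regions.
* **Trajectories** — piecewise-linear waypoints in mm; timestamps are
  integer microseconds with optional bounded jitter.

All randomness derives from `SceneConfig.seed` through independent
substreams (timestamps, NIR noise, thermal noise, ambient term), so the
same config is bit-reproducible and NIR/thermal renders share geometry and
timestamps.

What the generator does **not** emulate: fur texture, specularity, body
pose and articulation, occlusion by enrichment or bedding, multi-animal
contact/overlap, breathing waveform asymmetry, and heart-rate variability.
Passing tests therefore demonstrate the correctness and calibration of the
signal chain, not field performance on real animals.

## Spectral core

Traces are detrended (linear) and whitened before spectral estimation.
Whitening is **AR(1) prewhitening**: the lag-1 autocorrelation ρ̂ is
estimated from the detrended trace (clipped to |ρ̂| ≤ 0.98) and the filter
`y[t] − ρ̂·y[t−1]` is applied, followed by amplitude normalization. On
drift-dominated traces ρ̂ → 1 and the filter approaches first differencing,
suppressing slow room-wide oscillation; on already-white traces ρ̂ → 0 and
the filter is near identity. Plain differencing was rejected as the default
because it imposes a `4·sin²(πf/fs)` power slope on white noise, which
biases any in-band noise-floor statistic; it remains selectable
(`method="diff"`). Constant (or pure-trend) traces return an all-zero
flagged trace rather than raising.

Spectra are one-sided Hann-windowed periodograms with frequencies in
events/min; a 15 s window (the default analysis length) gives a resolution
of 60/15 = 4 events/min, which is the "one bin" tolerance quoted for rate
recovery. Timestamp jitter below 5% of the frame interval is linearly
resampled onto the uniform grid; larger jitter rejects the epoch.

**Peak picking** returns the in-band maximum, ties broken toward the lower
frequency. **SNR** is defined (the underlying procedures leave it open) as
peak power divided by the median in-band power, excluding bins within one
resolution step of the peak and of its second harmonic; bands spanning
fewer than 8 bins are refused. Because the maximum of ~40 exponentially
distributed periodogram noise bins sits 3–5× above their median even for
pure noise, SNRs reported by the pipelines are evaluated on a
Welch-averaged spectrum (segments of a quarter window, 50% overlap), whose
segment averaging stabilizes the floor; peak *localization* stays on the
full-resolution periodogram. This is what makes "an animal-free ROI has
SNR < 2" a meaningful statement.

The quality flag is `OK` when SNR ≥ 3 (default), else `LOW_SNR`; epochs
with locomotion are `MOTION_REJECTED` and never produce `OK` estimates.

## Stillness detection

Vital-sign extraction is restricted to still epochs. The motion metric is
the RMS difference between Gaussian-smoothed frames (σ = 2 px) separated by
a 0.5 s lag, with the frame-wide mean difference removed, normalized by the
sequence dynamic range. Three properties motivated each term:

* smoothing suppresses the per-pixel noise floor, which otherwise dominates
  any absolute-difference statistic;
* the lag makes the metric blind to zero-mean sub-pixel breathing
  oscillation (bounded lagged difference) while locomotion accumulates
  displacement (≈ 25 px per 0.5 s at a moderate 50 mm/s walk);
* removing the mean difference makes the metric invariant to frame-wide
  illumination changes, so the ambient-lighting noise term is not
  misclassified as motion.

The default threshold is 1.2% of dynamic range, between the breathing/noise
floor (≤ 0.9% across the tested rates) and slow locomotion (> 2%). Window
boundaries are recovered to within a few frames of a scripted
move/still/move schedule; the boundary uncertainty is on the order of the
time it takes the threshold displacement to accumulate (~6 frames at
40 fps).

## Respiration pipeline

Features are the strongest-gradient points (Sobel magnitude of the smoothed
first frame) inside the user-supplied thorax/edge ROI, selected greedily
with a minimum separation (default 4 px, max 20 features) — a strict
local-maximum detector finds almost nothing on a smooth boundary ridge.
Each feature's 16 × 16 px patch is registered against the first frame by
windowed FFT cross-correlation with 3-point parabolic sub-pixel
interpolation, batched over all frames in a single FFT per feature. The
parabolic estimator is monotone and accurate to ~0.15 px at ±0.9 px shifts,
sufficient for spectral readout of a 0.8 px breathing oscillation.

Each feature's 2-D displacement is projected onto its principal axis
(eigenvector of the displacement covariance), whitened, and the per-feature
power spectra are *averaged* — robust to a minority of bad tracks, unlike
averaging displacements first. The default search band is
30–400 breaths/min: the ceiling is the murine physiological maximum, the
floor excludes the ~6/min room oscillation.

## Cardiac pipeline

The iPPG path takes the spatial-mean NIR trace of a fur-free patch through
the same whiten → periodogram → band-peak chain (default mouse band
200–1000 beats/min; rat preset 150–600). Fur-free patch candidates are
detected as compact regions inside the Otsu body mask whose intensity
exceeds the body median by a quarter of the median-to-maximum span, ranked
by area; an inter-class contrast guard (≥ 6 within-class sd) prevents an
empty cage from yielding spurious "bodies" out of sensor noise. Detection
can return an empty list; callers then supply a manual ROI.

Lossy-compressed input is refused by default (`allow_compressed=True`
overrides): video encoders preserve motion and form but destroy the weak
intensity modulation that carries the pulse. Bands above the sequence
Nyquist raise an error naming the required frame rate. The aliasing
demonstration renders a 700 beats/min tone at 20 fps and recovers it at the
predicted alias |700 − 1200| = 500 beats/min.

## Thermometry

Segmentation thresholds at 30 °C by default — between the ~22 ± 2 °C room
contract and body temperature — and removes components below 25 px.
Surface temperature is the arithmetic mean over the mask; because the mask
includes blended edge-gradient pixels, the default reading biases a few
tenths of a degree low, and an interior mask (higher threshold) recovers
the configured temperature almost exactly. The eye/core proxy is the
95th-percentile temperature of the eye ROI — robust to single-pixel noise,
unlike the maximum — and requires the eye to span at least 2 × 2 px
(≈ 1 px/mm for a 2.5 mm mouse eye). Readings are flagged invalid whenever
any contributing pixel leaves the +20…+60 °C radiometric range. No
emissivity correction is applied; calibration is assumed upstream. Whether
the tail belongs in "skin area" is unresolved in the field; masks are
component-wise so callers can include or drop secondary components.

## Activity and circadian analysis

Tracking uses the thermal modality (segmentation against the cool floor is
trivial there) and reports the centroid of the largest warm component per
frame, in mm; frames with an empty mask are invalid. Animal identity is
*not* maintained — group-housed mice are visually near-identical — so
multi-animal scenes yield anonymous detections and occupancy aggregates
over all of them. Speeds are centered finite differences (one-sided at the
ends, NaN at invalid frames). Occupancy maps store integer frame counts per
cell times the frame interval, so total dwell time equals
`n_valid × interval` exactly rather than to rounding. The circadian
periodogram is Lomb–Scargle on hourly-binned mean speed (gap-tolerant, as
real recordings have handling gaps), scanned over periods from 2 bins to
48 h; the result carries a peak/median power ratio and is flagged
low-confidence when the recording spans fewer than two cycles of the
dominant period — a single day cannot pin down a 24 h rhythm.

## Requirement calculators and the validation report

The sampling-theorem pair `max_detectable_rate(fps) = fps·60/2` and
`required_fps(rate) = 2·rate/60` are exact inverses; resolution arithmetic
is direct px/field division plus an integer-ceiling feature requirement.
Values are held at full precision and rounded only for display.

`roi_spectral_report` reproduces the three-ROI validation workflow on the
first still epoch of length ≥ 15 s: inner-ear, outer-edge and animal-free
reference ROIs, each annotated with the three characteristic bands
(~6/min room oscillation, 100–250/min respiratory, 400–600/min cardiac),
per-band peaks and Welch-floor SNRs, and a paired comparison across two
recordings (e.g. lighting on/off) as SNR ratios. The room band spans too
few Welch bins at 15 s for a robust floor, so its SNR is reported as
unavailable rather than unstable.

## Problem sizes and tolerances used in validation

Scenes are 15 s at 40 fps (600 frames, 218 × 306 px) for vital-sign tests,
8 s at 20 fps for tracking, and 20 seeds for every distributional claim;
these sizes keep the full validation in the minutes range while leaving the
frequency resolution (4 events/min) that defines the one-bin recovery
tolerance. Tracking accuracy is asserted at ≤ 1 px position error and ≤ 5%
speed error on noiseless scenes; temperatures at ±0.2 °C (eye) and a few
tenths (surface, edge-gradient bias); the circadian period at ±1 h.

## Known limitations

* ROIs are user-supplied (or, for skin patches, detected on the synthetic
  appearance model); automatic thorax localization on real animals is out
  of scope.
* The estimators report a single rate per window; within-window rate
  tracking (spectrogram/wavelet) is not implemented.
* Compressed-video import is an adapter stub; decoding depends on an
  available imageio plugin.
* The skin-to-core temperature regression of the prior literature is not
  reproduced (no published coefficients); the eye statistic is a proxy.
* Multi-animal occlusion and identity are not modeled; occupancy and rates
  are population-level in group housing.
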