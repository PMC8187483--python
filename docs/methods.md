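# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `thermoflow`.

## Signal model

A facial thermal recording is treated as a static baseline temperature
map plus a small number of physiological sources, rigidly and mildly
elastically displaced by head motion, and degraded by sensor noise:

    frame_t(x) = [ baseline + Σ_k a_k(t) · s_k(x) ] ∘ w_t(x) + ε_t(x)

where `s_k` are spatial maps (nose tip, bilateral cheeks, nostril
respiration plume), `a_k` their time courses, `w_t` the motion warp and
`ε ~ N(0, σ²)` with σ = 0.05 °C, a typical noise-equivalent temperature
difference for an uncooled microbolometer. Spatial ICA assumes exactly
this structure with spatially independent `s_k`; motion correction
exists to make the warp the identity so that pixel intensity changes
mean temperature, not displacement.

## Motion correction

Per frame, a dense displacement field is estimated against a reference
frame (first frame by default; mean or previous-frame references are
available), Gaussian-smoothed, composed with the accumulated field, and
the *original* frame is re-warped — so interpolation error never
accumulates. Iteration stops when the incremental displacement of every
pixel is below 1 px, or earlier when the mean absolute image mismatch
stops improving.

The second stopping rule matters. Real thermal sources change pixel
brightness between frames, and a brightness-constancy flow estimator
converts irreducible intensity differences into a persistent, spatially
localized flow demand. Composing those increments indefinitely makes
the field drift (we observed several-pixel local errors after 20 blind
iterations); freezing at the mismatch plateau keeps the field at its
most accurate iterate. Frames stopped this way are honestly flagged
`converged = False` in the registration report because they do not meet
the strict all-pixels-below-1-px criterion, even though their
registration accuracy is typically a fraction of a pixel (the
ground-truth recovery tests quantify this).

Defaults and why:

- **Flow core**: scikit-image iterative Lucas–Kanade, window radius 15,
  one internal warp. Thermal faces are smooth, so a wide integration
  window is needed to resolve the aperture problem; internal warps are
  redundant because the outer loop re-warps between estimates. A
  coarse-to-fine pyramidal variant is provided for displacements beyond
  the window radius, and any estimator with the scikit-image flow
  convention can be plugged in — the identity/known-shift contracts are
  normative, the algorithm is not.
- **Field smoothing σ = 5 px**: suppresses discontinuities at the face
  boundary (where face flow meets static background) without destroying
  rigid motion. σ = 0 disables smoothing.
- **max_iter = 20**: convergence is typically reached in 2–5
  iterations; the cap bounds runtime on pathological frames.
- **Warping**: bilinear, edge-clamped, so no NaNs are injected into the
  downstream decomposition. Frame means are removed before flow
  estimation, making a uniform temperature offset register as zero
  motion.

## Face mask and source matrix

The mask is computed once per subject on the motion-corrected mean
frame: threshold at 28 °C (between a 22 °C room and 33 °C skin), keep
the largest 4-connected component, fill holes. A polygon path exists
for manual masks. Masked frames flatten into a T×P matrix in row-major
pixel order; `vectorize`/`unflatten` are exact inverses on the mask.

## Spatial ICA

The T×P matrix is column-centred and reduced by PCA; the whitened T×k
time courses have identity sample covariance and the stored
back-projection reproduces the rank-k data exactly. The k×P spatial
modes are row-centred over pixels and sphered, and a symmetric
fixed-point iteration (tanh contrast by default, pow3 available)
estimates an orthonormal unmixing matrix; convergence requires
successive unmixing matrices to agree within 1e-4 under sign alignment,
with up to 1000 iterations and a mandatory seed for reproducibility.

Conventions: spatial maps have unit variance over pixels; each
component is oriented so its map skewness is positive (a deterministic
resolution of ICA's sign indeterminacy that points compact warm
structures upward); time courses are least-squares mixing coefficients,
and the spatially uniform part of the retained subspace is kept as a
separate mean-offset time course so that
`timecourses @ spatial_maps + mean_offset` reconstructs the whitened
subspace to machine precision when K = k.

The component count defaults to 50 for full-resolution recordings,
matching common practice of over-extracting so artifacts receive their
own components; the desk-scale simulations here use K = 15 at 96×96 px
for the same reason — with registration residuals present, a too-small
K lets boundary artifacts displace the weakest true source (the
respiration plume) from the retained subspace entirely.

Component labelling is a heuristic aid, not a claim of automation: the
top decile of |map| is intersected with anatomical templates, the
overlap normalized by the smaller of support and template (so a nose
much smaller than a face decile can still score 1), and a component is
labelled with its best region when overlap exceeds 0.5 — a nostril
component must additionally carry more than half its non-DC spectral
power in the 0.16–0.35 Hz respiratory band to be called `respiration`.
Spectra are Welch estimates (64-sample Hann segments, 50% overlap), a
robust default for ~20 min at 5 Hz. Manual override remains the
escape hatch, mirroring how such components are selected in practice.

Recovery scoring handles permutation and sign indeterminacy by greedy
absolute-correlation matching of estimated to true maps.

## ROI benchmark

The classical comparator is the per-frame mean over a rasterized disk
(pixel-centre distance ≤ radius; radius 9 → 253 px ≈ the conventional
"~250 pixel" nose-tip area), extracted from the *same* motion-corrected
video and rescaled to [0, 1]. The synthetic face is proportioned so
that this disk is nose-tip-sized (96×96 frames, ~17 px nose) and clear
of the nostril plume — the proportions a 640×480 camera sees at
conversational distance.

## Physiology

- **GSR**: linear detrend, zero-phase 4th-order Butterworth low-pass at
  5 Hz, polyphase resampling to the thermal frame rate, then [0, 1]
  rescaling per subject.
- **R peaks**: band-pass 5–30 Hz, derivative-energy envelope (120 ms
  smoothing), adaptive threshold at 40% of the 98th percentile, 200 ms
  refractory period, refinement to the local ECG maximum. Externally
  corrected peak files are accepted as a drop-in replacement.
- **IBI**: successive differences in ms, each interval stamped at its
  second beat (a causal convention the interpolation needs and which we
  state explicitly).
- **HRV spectrogram**: cubic-spline resampling of the IBI at 2 Hz; 16 s
  windows (32 samples) advancing by 32 − 15 = 17 samples ("15-sample
  overlap" is read literally in interpolated samples; an overlap in
  seconds is configurable since the convention is ambiguous); per
  window a Burg autoregressive spectrum of order 16 (standard for short
  HRV windows; configurable) on an nfft = 1024 grid, integrated over LF
  (0.04–0.14 Hz) and HF (0.15–0.4 Hz). Windows overlapping the first or
  last ~8 s are edge-flagged, reflecting the half-window of data lost
  to edge effects at each end. Zero-variance windows return zero power
  rather than an undefined AR fit.

## Group statistics

ISC is the mean Pearson correlation over all unique subject pairs
(N = 17 → 136 pairs). Nulls are built by circularly shifting each
subject's series by an independent uniform offset in [1, T−1] per
realization (zero is excluded because it reproduces the observed
statistic and would bias the null); cross-modal tests shift one
modality relative to the other, independently per subject. Defaults:
5000 realizations, one-sided positive for ISC, one-sided negative for
nose-vs-GSR (the physiologically predicted direction), with a two-sided
option. The permutation loop uses the identity
Σ_{i<j} zᵢ·zⱼ = (‖Σzᵢ‖² − NT)/2 on standardized series, so each
realization costs O(NT).

Calibration: under circularly stationary nulls the test is exact by the
group-invariance argument (measured 0.045 rejection at α = 0.05 over
200 runs); under linear AR(1) nulls — which are not circularly
stationary — it is approximate and mildly anticonservative at short T
(measured 0.0575/0.0475 for ISC/cross-modal over 400 runs at T = 600,
φ = 0.9, stationary initialization). Simulated AR(1) series must be
initialized stationarily (burn-in); a zero-start transient alone
inflates the empirical rate to ~0.07–0.10.

Lagged correlation pairs `a[t]` with `b[t + lag]` on the truncated
overlap — positive lag treats `b` as the delayed response — matching
the convention of correlating a ~3 s-lagged thermal response with a
stimulus time series. FDR control is Benjamini–Hochberg. Modalities at
different rates are aligned by polyphase anti-aliased resampling and
cropped to common support.

## Synthetic data: what it does and does not emulate

The generator produces exactly the structure the analysis assumes:
elliptical face, disjoint anatomical templates, smooth seeded
temperature texture (without which optical flow has nothing to track —
real faces have structured temperature), a slow nasal drift (< 0.05 Hz
random walk), a nostril oscillation at a per-subject frequency drawn
from 0.16–0.35 Hz, a cheek source carrying a scaled copy of the
respiration waveform (the spectral overlap seen in real cheek
components), sinusoidal rigid translation anchored at zero displacement
in the reference frame plus a mild elastic wobble, and white Gaussian
sensor noise. Source amplitude defaults to 0.5 °C, so the default
noise floor gives an amplitude SNR of 10.

Group simulations share one band-limited latent process: subject nose
series are −√f·L + √(1−f)·ε with matched-spectrum noise, making the
expected pairwise ISC equal the shared-variance fraction f and the
power tests self-calibrating; GSR is the latent convolved with a slow
rise/decay conductance kernel (generated at 50 Hz — upsample if a 2 kHz
fixture is needed); the IBI is modulated by the latent in the LF band
plus a respiratory HF rhythm, with beats from integrate-and-fire; and
emotion scores are a noisy 1 Hz read-out of the latent.

Deliberately not emulated: photorealistic anatomy, perspiration,
out-of-plane (3-D) head rotation, camera drift, and expression-driven
deformation. Passing tests therefore demonstrate correctness of the
algorithms under the model's assumptions, not performance on arbitrary
real recordings — in particular, 2-D optical flow cannot fully undo
3-D pose changes.

## Problem sizes

Simulation studies run at desk scale by design: 96×96 frames, T = 300–
900 frames (1–3 min) for imaging checks, T = 6000 (20 min) for pure
time-series statistics, groups of 10 subjects for the end-to-end
pipeline and 17 for statistical power checks, 200 runs × 500
permutations for calibration. The ISC permutation identity above makes
the statistics cheap; the imaging sizes keep motion correction around
20 ms per frame.

## Known limitations

- The strict all-pixels-below-1-px convergence flag is frequently
  unattainable on frames with strong source dynamics (see Motion
  correction); accuracy is then validated by recovery, not by the flag.
- Component labelling is a heuristic; diffuse or split components
  (e.g. cheeks decomposing into separate lateral components at high K)
  fall back to `other` and need manual inspection.
- Permutation tests are approximate for non-circularly-stationary
  series at short T; at the study scales used here the miscalibration
  is within a percentage point or two of the nominal level.
- The detector targets clean, upright-R ECG; inverted leads or heavy
  baseline wander should use the external-peaks path.
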