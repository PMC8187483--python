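# thermoflow

Motion-corrected spatial ICA of facial thermal video, with the
multimodal statistics used to validate it against classical
psychophysiology.

## The problem

Facial infrared imaging measures skin temperature without contact, and
autonomic blood-flow changes — nasal vasoconstriction under arousal,
respiratory airflow below the nostrils — show up as fractions of a
degree riding on an 11 °C face/background contrast. The traditional
analysis averages a hand-placed region of interest (ROI), which wastes
most of the face and is fragile to head motion. `thermoflow` implements
the data-driven alternative:

1. **Motion correction.** A dense optical-flow field is estimated
   between each frame and a reference, Gaussian-smoothed to keep the
   face boundary coherent, composed with the running field and applied
   to the original frame — iterating until the incremental displacement
   of every pixel falls below 1 px (or the image mismatch stops
   improving, which signals brightness change rather than motion).
2. **Spatial ICA.** The masked video becomes a T×P matrix X (rows:
   frames, columns: pixel time series), modelled as X ≈ A S with
   mutually independent spatial maps S (K×P) and mixing time courses A
   (T×K). After PCA whitening, a symmetric fixed-point iteration with a
   tanh contrast estimates the orthonormal unmixing; components are
   sign-fixed by positive map skewness and labelled (nose / cheeks /
   respiration) from template overlap and the fraction of spectral
   power in the 0.16–0.35 Hz respiratory band.
3. **Benchmark & physiology.** The nose component is compared against a
   9-px-radius nose-tip ROI (~250 px), against low-pass-filtered skin
   conductance (GSR), and against autoregressive LF/HF heart-rate-
   variability power from ECG R peaks.
4. **Group statistics.** Inter-subject correlation (ISC) — the mean
   Pearson r over all N(N−1)/2 subject pairs — and cross-modal group
   tests, with significance from circular-shift surrogates: rotating a
   series in time preserves its autocorrelation exactly while
   destroying its alignment with other subjects or modalities. P-values
   use the add-one estimator (1 + #extreme)/(1 + n permutations).

Real recordings of this kind are privacy-restricted, so the package
ships a first-class synthetic generator: face-shaped video with planted
nose/cheek/respiration sources, head motion and sensor noise at the
camera noise floor (0.05 °C), plus GSR, ECG and emotion-score series
coupled through a shared latent arousal process. Every stage is tested
against this ground truth.

## Worked example

`examples/decompose_thermal_video.py` simulates one subject (96×96 px,
5 Hz, 2 min, 3 px head motion), corrects the motion and decomposes the
masked video:

```
video: 600 frames @ 5.0 Hz, (96, 96) px
motion correction: 315/600 frames below the 1 px criterion
face mask: 3893 pixels -> source matrix (600, 3893)

comp        label resp. band  best-region overlap
   0         nose       0.14  nose: 1.00
   2       cheeks       0.88  cheeks: 0.95
  12  respiration       0.91  nostril: 1.00

matched |spatial r| vs planted sources (nose, cheek, respiration): [0.984 0.966 0.97 ]
```

The nose component is respiration-free (band fraction 0.14) while the
cheek and respiration components are band-dominated — the spectral
signature that motivates restricting arousal analyses to the nose. All
three planted maps are recovered with |r| > 0.96.

`examples/group_isc.py` runs the group statistics on 17 simulated
subjects (20 min at 5 Hz, shared variance 0.25, negative GSR coupling):

```
thermal ISC: mean r = 0.264 over 136 pairs, p = 0.0002 (5000 permutations)
nose vs GSR: group mean r = -0.496, one-sided p = 0.0002
```

Subjects' nasal temperatures covary (positive ISC) and move opposite to
skin conductance, the expected sympathetic signature. See also
`examples/roi_benchmark.py` (nose IC vs ROI: r = 0.996) and
`examples/hrv_from_ecg.py` (R-peak detection and LF/HF band power).

## Command line

```bash
thermoflow simulate --preset single --seed 1 --out video.tiff
thermoflow mc video.tiff --out corrected.tiff
thermoflow ica corrected.tiff --out-prefix run1 --components 15 --seed 2
thermoflow isc subjects.csv --seed 3
thermoflow run --config cfg.yaml --out report.json
```

`thermoflow run` executes the whole pipeline (motion correction → mask
→ sICA → labelling → ROI benchmark → GSR/HRV → ISC and cross-modal
permutation tests) from a YAML config and writes a JSON report in which
every p-value carries its permutation count and seed.

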