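# Methods

`periopix` automates periocular anthropometry from frontal photographs: it
detects ten periocular landmarks with a heatmap-regression network, converts
pixels to millimetres using a forehead fiducial sticker of known diameter,
computes seven clinical measurements, and quantifies agreement between two
raters (typically a human annotator and the automated pipeline). This note
records the models, conventions, parameter choices, and known limitations.

## Landmarks and coordinate conventions

Ten landmarks per face, five per eye: pupillary centre, upper- and
lower-lid margin midpoints (on the pupil's vertical midline), medial
canthus, lateral canthus. "Right"/"left" are the subject's; the subject's
right eye appears on the left of a frontal image, and the index order keeps
the right-eye block first (indices 0–4).

All coordinates are sub-pixel, 0-based, origin at the centre of the
top-left pixel, x rightward, y downward. Every module (rendering,
annotation files, heatmap codec, measurements) shares this convention.

## Clinical measurements

With a mm-per-pixel scale `s` and landmark points `p`:

- MRD1 = (y_pupil − y_upperlid) · s, signed; positive when the upper lid
  midpoint sits above the pupil centre. MRD2 = (y_lowerlid − y_pupil) · s.
  The signed vertical component is used, not the Euclidean distance,
  because the clinical definition is a vertical distance along the pupil
  midline; negative MRD1 (lid below the pupil centre, severe ptosis) is
  reported, not rejected.
- PFH = MRD1 + MRD2, per eye, exactly by construction (a bit-exact sum,
  never measured independently).
- HPA, IICD, OICD, IPD: Euclidean distances between the named landmark
  pairs, times `s`. Euclidean (rather than x-component) distances make
  these metrics invariant to small head roll; for a level head the two
  definitions coincide. An `horizontal="x"` switch selects the strict
  x-component convention.

A documented consequence: the vertical MRD/PFH measures are **not**
roll-invariant. Rolled scenes are therefore generated with roll only in
tests that exercise the Euclidean metrics' invariance.

## Fiducial calibration

A green circular sticker (default diameter 24 mm) on the forehead
calibrates each image: mm_per_px = diameter / (2 · fitted radius).
Detection: HSV thresholding (hue 0.20–0.47, saturation ≥ 0.30, value
≥ 0.15), connected components, a minimum-area gate (200 px) and a
circularity gate (4πA/P² ≥ 0.8), largest surviving component wins, then an
algebraic (Kasa) least-squares circle fit to the sub-pixel component
boundary. The RMS boundary residual is reported; a residual above 10% of
the radius flags the fit as degraded (warning, not an error). The
calibration assumes the sticker and the eyes are coplanar with the sensor;
parallax at a ~1 m standoff is ignored. On synthetic scenes the recovered
scale is within 2% of truth (typically within 0.2%).

## Heatmap codec

Landmarks are encoded as one Gaussian likelihood map per landmark at 1/4 of
the input resolution (stride 4). The Gaussian is centred at the continuous
sub-cell position x/stride with σ = 2 heatmap pixels, truncated to zero
beyond 3σ, and normalized so the peak value is exactly 1 at the nearest
cell. Keeping the continuous centre matters: the asymmetry of the
neighbouring cells carries the sub-cell offset that decoding recovers.
(An earlier variant quantized the centre; that erases sub-cell information
and measurably degrades localization.)

Decoding takes each map's argmax cell (row-major first occurrence on
ties), shifts a quarter cell toward the larger of each 4-neighbour pair,
and multiplies by the stride. The encode→decode round trip is bounded by
1 heatmap-pixel-quarter per axis (≤ 1 input px; the conservative guarantee
is L∞ ≤ stride). The training loss is the mean squared error over all map
elements — the mean reduction makes the value independent of batch
assembly.

## Detector

The backbone is pluggable; the default "compact" network is a small
fully-convolutional NumPy-implemented encoder: 3×3 conv (16 ch) → 2×2
max-pool → 3×3 conv (24) → pool → 3×3 conv (32) → 3×3 conv (32, dilation
2) → 3×3 conv (32, dilation 4) → 1×1 conv to 10 maps, ReLU throughout,
~35k parameters, trainable in minutes on one CPU. The two dilated stages
widen the receptive field to ≈ 90 input pixels; without them the canthi —
whose local appearance is nearly mirror-symmetric between the medial and
lateral corner — are frequently confused. Two normalized coordinate
channels are appended to the grayscale input so the translation-invariant
convolutions can separate the subject's right and left eye, whose local
appearance is identical.

Training follows the standard protocol: images stretched anisotropically
to the configured input size (default 512×256, matching full-scale
photographic practice; the recorded affine is inverted at prediction time
to return coordinates in the original resolution), Adam (β = 0.9/0.999)
with base learning rate 1e-3 decayed to 1e-4 at epoch 30 and 1e-5 at
epoch 50, batch 16, 60 epochs, 70/30 train/eval split at the face level.
Augmentation per sample: in-plane rotation within ±30°, isotropic scaling
in [0.75, 1.25], horizontal flip with probability 0.5. A flip mirrors the
raster and permutes the landmark index blocks so anatomical roles are
preserved; if an affine draw pushes any landmark out of frame it is
re-drawn up to five times, after which the sample passes through
unaugmented (logged). One seed controls the split, initialization,
shuffling and augmentation.

Evaluation: per image, NME = mean Euclidean landmark error divided by the
ground-truth inter-pupillary pixel distance (the normalizer is a
convention choice; inter-pupillary distance is the natural face scale
here), and the failure rate is the fraction of images with NME > 0.1.

### Desk scale

CPU-scale runs in the test suite and the acceptance script use a 256×128
input, 20 epochs at a constant 1e-3 learning rate, and 200 training / 60
held-out synthetic scenes. At this scale training takes a few minutes on
one CPU and the held-out mean NME is ≈ 0.03 with failure rate 0 at the 0.1
threshold across seeds. The localization floor of argmax decoding at
stride 4 — a quarter-cell per axis after refinement — is ≈ 1 input px,
i.e. ≈ 3 px in 640×480 scene coordinates (NME ≈ 0.01); results at
256×128 are within ≈ 3× of that floor.

## Synthetic scenes

The generator emulates the photographic protocol the pipeline targets:
frontal face crop, eyes on a horizontal line at 58% of image height, a
green fiducial disc on the forehead, uniform head-on lighting, Gaussian
pixel noise (SD 3 of 255). Eyes are schematic: a white opening bounded by
two parabolic lid arcs through the canthi with apices at the lid-midpoint
landmarks, an iris disc (radius 5.85 mm) and pupil disc (radius 2 mm)
clipped to the opening, and a dark lash line along both arcs. Ground-truth
landmarks are placed analytically from the requested measurements
*before* rasterization; the raster is only the detector's input. Head
roll rotates raster and truth identically about the image centre.

Default sampling ranges are uniform over mean ± 2 SD of an adult clinical
population: MRD1 3.66 ± 0.89 mm, MRD2 5.24 ± 1.22 mm, HPA 25.30 ± 2.08 mm,
IPD 61.2 ± 3.7 mm, IICD 33.3 ± 3.4 mm, with OICD ≡ IICD + HPA_r + HPA_l
(the implied OICD mean, 83.9 mm, is anatomically consistent with the
population OICD of ≈ 84 mm). Scale is drawn from 0.22–0.28 mm/px with a
640×480 frame, head roll defaults to 0 (so vertical measures match their
parameters exactly), and bilateral quantities are drawn independently per
eye.

What the generator does **not** emulate — and hence what passing tests do
not show about clinical photographs: skin/iris texture, eyelashes and
brows, specular corneal reflexes, shadows and lighting gradients,
occlusion by ptotic lids, out-of-plane head pose, camera distortion, and
inter-subject appearance variability. Detector scores on synthetic scenes
demonstrate that the pipeline's machinery (codec, training loop,
augmentation-role bookkeeping, calibration, measurement geometry) is
correct, not that the compact network reaches clinical accuracy on real
faces.

## Agreement statistics

Bilateral metrics (MRD1, MRD2, PFH, HPA) are pooled across eyes — two
pairs per face — while IPD, IICD and OICD contribute one pair per face.
Pooled pairs are treated as independent observations, replicating common
clinical reporting even though eyes within a face are correlated; passing
per-face records directly gives the unpooled sensitivity analysis.

- MAE: mean |A−B| with the sample SD of the absolute differences.
- Bland-Altman: bias = mean difference d̄, LoA = d̄ ± 1.96·s. CI of the
  bias: d̄ ± t_{n−1,0.975}·s/√n; CI of each LoA uses the standard
  standard-error approximation s·√(3/n). Zero-variance differences
  collapse the LoA onto the bias with zero-width CIs.
- ICC(A,1) — single measures, absolute agreement, two-way model — from
  the subjects×raters ANOVA mean squares:
  ICC = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE)), with the
  F-based McGraw–Wong confidence interval. The p-value tests ICC = 0 with
  F = MSR/MSE on (n−1, (n−1)(k−1)) df — with two raters this matches the
  df convention of the common R/Python implementations. Interpretation
  bands: < 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, > 0.9 excellent.
  Zero between-subject variance is a degenerate error, not a number.

## Numerical and design choices

- Loss reduction is the mean (not sum) over elements: batch-size
  independent.
- Argmax ties break to the row-major first occurrence; refinement shifts
  exactly 0, ±0.25 cells per axis (no shift when neighbours tie).
- The annotation JSON is written in canonical form (sorted keys, fixed
  landmark order) so identical content is byte-identical — manifests and
  annotation files diff cleanly across runs.
- Measurement CSVs report mm to 2 decimals (the scale factor to 6).
- The Kasa circle fit is linear least squares; for the near-complete,
  near-circular boundaries produced by the detector gates its bias is
  far below the 2% calibration tolerance.
- Degenerate inputs raise typed errors (`CalibrationNotFoundError`,
  `DecodingError` with the landmark index, `DegenerateIccError`, …) rather
  than returning sentinel values.

## Known limitations

- Prediction coordinates are quantized at stride-4 cells of the network
  input; predictions on independently resampled copies of the same scene
  can differ by up to one heatmap cell (sub-cell refinement flips), so
  cross-resolution consistency is cell-level, not pixel-level.
- MRD1/MRD2 assume an upright head; in-plane roll biases the vertical
  measures (by design, matching the clinical definition). A preprocessing
  roll correction would be needed for rolled photographs.
- The compact backbone is sized for schematic scenes on a CPU. Clinical
  images need a stronger backbone (the registry accepts one) and real
  annotated data.
- Calibration ignores sticker-to-eye depth parallax and lens distortion.
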