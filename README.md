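# periopix

Automated periocular anthropometry from frontal facial photographs.

Clinicians monitor eyelid and orbital disease (ptosis, thyroid eye
disease, trauma) with a small set of periocular measurements — marginal
reflex distances (MRD1, MRD2), palpebral fissure height (PFH), horizontal
palpebral aperture (HPA), inner/outer intercanthal distance (IICD, OICD),
and interpupillary distance (IPD). Manual measurement is subjective,
operator-dependent, and impractical over telehealth. `periopix` automates
the photographic version of the exam:

1. **Landmark detection.** A heatmap-regression network predicts ten
   periocular landmarks (pupil centre, upper/lower lid midpoints, medial
   and lateral canthus, per eye). Ground truth is encoded as 2D Gaussian
   likelihood maps at 1/4 input resolution (σ = 2, peak 1); training
   minimizes the mean squared heatmap error; decoding is argmax with
   quarter-cell sub-pixel refinement. The default backbone is a compact
   dilated conv-net that trains in minutes on a CPU; stronger backbones
   can be registered.
2. **Calibration.** A green circular fiducial sticker of known diameter
   (24 mm) on the forehead fixes the scale: mm/px = diameter / (2·r) from
   a least-squares circle fit to the detected sticker boundary.
3. **Measurement.** MRD1 = (y_pupil − y_upperlid)·s and
   MRD2 = (y_lowerlid − y_pupil)·s (signed vertical distances);
   PFH = MRD1 + MRD2 exactly; HPA, IICD, OICD, IPD are Euclidean
   inter-landmark distances times the scale.
4. **Agreement.** Human-vs-automated agreement per metric: mean absolute
   error, Bland-Altman bias and 1.96·SD limits of agreement with 95% CIs,
   and ICC(A,1) (single measures, absolute agreement, two-way model) with
   the McGraw–Wong confidence interval, pooling left/right eyes for the
   bilateral metrics.

Detector quality is summarized by the normalized mean error — mean
landmark error over the inter-pupillary pixel distance — and the failure
rate at NME > 0.1.

Because clinical photographs cannot ship with the package, a synthetic
scene generator renders schematic faces (parabolic lid arcs, iris/pupil
discs, canthi, fiducial dot) with analytically exact landmark and
measurement ground truth, sampled from adult population statistics
(e.g. MRD1 3.66 ± 0.89 mm, IPD 61.2 ± 3.7 mm). All tests and the
reproduction script run on these scenes. See `docs/methods.md` for the
full model description and its limitations.

## Worked example

```python
import periopix as pp

scene = pp.render_scene(pp.sample_scene_params(7))     # synthetic face
circle = pp.detect_sticker(scene.image)                # find the 24 mm dot
scale = pp.scale_from_circle(circle)
rec = pp.compute_measurements(scene.landmarks_true, scale)
print(f"mm/px (true {scene.params.mm_per_px_true:.4f}) recovered {scale.mm_per_px:.4f}")
print(f"MRD1 R/L: {rec.mrd1_right:.2f}/{rec.mrd1_left:.2f} mm")
print(f"IPD {rec.ipd:.2f}  IICD {rec.iicd:.2f}  OICD {rec.oicd:.2f} mm")
```

prints

```
mm/px (true 0.2678) recovered 0.2678
MRD1 R/L: 4.10/5.07 mm
IPD 53.86  IICD 37.66  OICD 89.69 mm
```

— the fiducial calibration recovers the true scale to 4 decimals and the
measurements land within one pixel-equivalent (≈ 0.27 mm here) of the
scene's true parameters. Agreement statistics compare two raters' record
lists:

```python
pairs = pp.pool_bilateral(records_human, records_auto)
rep = pp.agreement_report(pairs["mrd1"])
```

On 40 synthetic faces with simulated rater noise (SD 0.25 mm) this prints
`n=80 MAE 0.21 mm, bias -0.11 [LoA -0.56, 0.34], ICC 0.968 (excellent)` —
eighty pooled eyes, sub-quarter-millimetre agreement, excellent
reliability.

The same workflow is scriptable from the shell:

```sh
periopix simulate --n 260 --seed 42 --out-dir data/
periopix train --data-dir data/ --out-model model.npz --epochs 20
periopix predict --model model.npz --out-dir pred/ data/*.png
periopix measure --model model.npz --out-csv auto.csv data/*.png
periopix evaluate --pred-dir pred/ --truth-dir data/
periopix agree human.csv auto.csv --out-dir agreement/
```

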