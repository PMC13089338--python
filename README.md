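# mesoquant

Quantitative image analysis of mesoglea biogenesis and aboral-valve
function in the sea anemone *Nematostella vectensis*.

During the larva-to-polyp transition, the body column elongates while the
mesoglea — the extracellular-matrix layer between ectoderm and endoderm,
imaged as a thin bright band of Col IV / laminin — is remodeled. At the
aboral pole a localized Col IV depletion zone marks a pressure-sensitive
valve that transiently expels cavity fluid ("aboral leakage"), visible as
an abrupt drop in body volume. `mesoquant` implements the measurements a
microscopist needs to quantify this process from calibrated 2D
fluorescence images:

- **Body-column morphometrics** — segmentation, moment-aligned bounding
  box giving length *l* (oral–aboral), width *w*, aspect ratio AR = *l*/*w*,
  and a solid-of-revolution volume estimate justified by the body plan's
  radial symmetry.
- **Morphospace trajectories** — (volume, AR) time series with
  leakage-onset detection: an event is a drop of ≥ 10% (configurable) of
  the median-smoothed volume relative to its recent running maximum, and
  the AR at onset is reported.
- **Mesoglea thickness profiling** — the image is straightened along a
  polyline ROI traced on the mesoglea; at each axial position the
  transverse peak's full width at half maximum (FWHM) is the local
  thickness and the baseline-subtracted signal within it the local Col IV
  amount; the column summary is mean ± SD. An extracellular/intracellular
  (mesoglea / endoderm) intensity ratio is computed from the same map.
- **Photoconverted-patch elongation** — for a patch mask of area *A* with
  skeleton length *l*, the elongation score is AR_patch = *l*/*w* = *l*²/*A*
  with the empirical width *w* = *A*/*l*.
- **Aboral profiles** — pore-centred line profiles (0 = pore), the
  depletion-zone width as full width at half depth, 0–50 µm pErk profiles
  at 5-µm line width, square-ROI mean intensities, and multi-animal
  mean ± SD ensembles.
- **Group comparison** — two-sided Wilcoxon rank-sum with exact
  enumeration for small samples (valid under ties).
- **Synthetic scenes** — a generator producing body columns, aboral bands,
  stadium patches and leakage trajectories with known ground truth, so
  every estimator above has a parameter-recovery test.

## Worked example

```python
import mesoquant as mq

# a synthetic body column: 60 x 30 um ellipse, 2-um mesoglea band,
# 5%-of-peak Gaussian noise, 0.1 um/px
cfg = mq.SceneConfig(mesoglea_thickness=2.0, noise_sigma=50.0, seed=1)
channels, mask, truth = mq.make_body_scene(cfg)
img = channels["ColIV"]

# morphometrics from the image alone
shape = mq.fit_bounding_box(mq.segment_body(img))
print(f"AR = {shape.ar:.3f}  volume = {shape.volume:.0f} um^3")

# FWHM thickness along the straightened mesoglea
smap = mq.straighten(img, truth.midline, half_width=6.0)
prof = mq.thickness_along_column(smap)
print(f"thickness = {prof.mean_thickness:.3f} +/- {prof.sd_thickness:.3f} um")
```

prints

```
AR = 2.000  volume = 28221 um^3
thickness = 1.984 +/- 0.037 um
```

i.e. the true aspect ratio 2.0, the true revolved-ellipsoid volume
28 274 µm³ within 0.2%, and the true 2.0-µm band FWHM within 1%, with
the axial spread of the per-position estimates as SD.

The same stages are available from the shell:

```sh
mesoquant simulate --kind body --seed 1 --out scene/
mesoquant mesoglea --image scene/ColIV.tif --roi scene/midline.json \
    --half-width 6 --out thickness.csv
mesoquant trajectory --shapes shapes.csv --drop-threshold 0.1 --out traj.csv
mesoquant compare --a dmso.csv --b bpy.csv --column thickness
```

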