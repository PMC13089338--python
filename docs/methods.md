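# Methods

This note documents the models, conventions and numerical choices behind
each estimator, what the synthetic scenes do and do not emulate, and the
known limitations.

## Coordinates and calibration

Pixel indices are 0-based with pixel centres at integer coordinates;
physical position is `(x, y) = (col, row) * pixel_size` in micrometres.
Only isotropic 2D calibration is supported — anisotropic TIFF resolution
tags are rejected rather than silently averaged. All analysis operates in
physical units; intensities are arbitrary units and no background is
subtracted unless an operation states so explicitly. A writer placeholder
resolution of 1:1 with no unit is treated as *missing* calibration, so
such files require an explicit pixel-size override.

## Body-column morphometrics

**Segmentation.** A Gaussian pre-filter (default 0.5 µm) suppresses shot
noise. The automatic threshold works in two steps because fluorescence
scenes here are effectively trimodal (background, tissue, a roughly
10-fold brighter mesoglea band): Otsu on log-compressed intensities first
separates background from signal — on the raw scale Otsu would instead
split off the bright band — and the final cut is placed midway between the
background mean and the lower-quartile signal level. The midpoint rule
puts the mask boundary at the half height of the blurred tissue edge
instead of at its outer skirt. The largest connected component is kept and
holes are filled. Tentacles are *not* removed; the caller must supply
body-column-only images or masks.

**Shape.** The oral–aboral axis is the principal axis of the mask's
second-order moments; length *l* and width *w* are the extents of the
minimal bounding rectangle aligned to it (one pixel is added per extent so
a one-pixel line has unit, not zero, width), with the tie-break *l* ≥ *w*.
AR = *l*/*w* is dimensionless and exactly invariant to uniform rescaling;
rotation changes it by < 2% (discretization only).

**Volume.** The body plan is radially symmetric about the oral–aboral
axis, so volume is estimated as a solid of revolution: foreground pixel
coordinates are rotated into the axis frame, binned into one-pixel axial
slices, and each slice contributes π r² Δs with r half the local
transverse extent. Closed-form checks (cylinder from a rectangle, sphere
from a disk, cylinder+sphere from a stadium) agree within 3%, and the
estimate scales exactly as s³ under uniform rescaling.

**Leakage detection.** The volume series is smoothed with a rolling median
(default window 5; window 1 disables smoothing; raw values are always
stored). A leakage event is declared at the first frame whose smoothed
volume lies ≥ `drop_threshold` (default 0.10) below the maximum of the
preceding `window` frames (default 3); consecutive below-threshold frames
belong to the same event, and a fresh event requires the reference maximum
to recover first. Both parameters are exposed in the CLI. On noiseless
monotone traces the detector provably never fires for any positive
threshold. Under the simulated study conditions (15% drop, 1% CV
multiplicative noise, 100 frames) the onset is localized to ±1 frame in
≥ 95% of 50 runs with zero false positives on matched no-drop traces.

**Group comparison.** Two-sided Wilcoxon rank-sum. For combined n ≤ 12
the p value is computed by full enumeration of all C(n, n_a) group
labellings on midranks — exact even under ties, where the classical exact
network algorithm is invalid. Tie-free samples up to combined n = 30 use
the exact U distribution; beyond that, or with ties, the tie-corrected
normal approximation with continuity correction is used. The normal
approximation alone is accurate mid-range but can err by tens of percent
for tail p at the study's group sizes (12 vs 6), which is why the exact
distribution is preferred whenever it is valid.

## Straightening and FWHM thickness

The polyline ROI is resampled at equal arc-length steps (default: the
pixel size); the image is sampled by bilinear interpolation at
`p(s) + d·n(s)` where `n` is the left-of-travel unit normal. The caller
orients the polyline so the endoderm lies to the left: positive transverse
offset d is endoderm, negative is ectoderm, d = 0 the polyline. Samples
outside the image are NaN and excluded — never zero-filled, which would
bias FWHM baselines. Axial position s is rescaled to [0, 1].

**FWHM.** The baseline is the mean of the outer 10% of samples on each
side of the profile (robust to tissue shoulders flanking the band); the
peak is the maximum after baseline subtraction; the half-maximum crossings
nearest the peak are located by linear interpolation on each flank. The
construction is exactly invariant to intensity gain and offset. Per-axial
estimates use bins of 5 axial samples (configurable) to stabilize noisy
flank crossings; the "amount" within the FWHM window is reported both as
a step-weighted sum (intensity × µm) and as a per-sample mean, since
either reading of the signal-within-the-window convention is defensible.

Accuracy, on synthetic bands at 0.1 µm/px: band FWHM of 1, 2 and 4 µm are
recovered within 5% noise-free and within 10% (mean over 20 seeds) at
noise of 5% of the band peak. A residual ~1–2% narrowing bias comes from
the asymmetric tissue plateaus (endoderm brighter than ectoderm) shifting
the two half-maximum crossings; it shrinks as the band-to-tissue contrast
grows.

**Extracellular/intracellular ratio.** Numerator: mean baseline-subtracted
intensity within the FWHM window of the column-averaged transverse
profile. Denominator: the same quantity over a caller-chosen endoderm band
on the positive-d side, disjoint from the window. The ratio is exactly
scale-invariant. Its generative truth on the synthetic scene has the
closed form `phi * P / (T(e-1)/2)` with `phi = sqrt(pi/(4 ln 2)) erf(sqrt(ln 2))
≈ 0.810` (mean of a Gaussian over its own FWHM), P the band peak, T the
ectoderm intensity and e the endoderm excess; recovery is within 10%.

**Axial profiles.** Intensity along an oral–aboral polyline with optional
perpendicular averaging, position normalized to [0, 1]. Source conventions
for the origin conflict (one states 0 = oral, another 0 = aboral), so the
origin is a flag, default `aboral`; the polyline is assumed drawn starting
at the oral pole.

## Patch elongation

AR_patch = *l*²/*A* with *A* the mask area and *l* the skeleton length.
The skeleton is obtained by thinning; its pixels form an 8-connected graph
(edge weights 1 and √2 px) whose longest geodesic path — found by a double
Dijkstra sweep, exact on trees — is the measured curve, automatically
discarding the short side branches thinning produces on discretized
outlines. Two numerical corrections matter at the 10% accuracy level:

1. *End correction.* The true medial endpoint of a rounded patch end sits
   where the free distance ahead of the curve equals the lateral half
   width. Thinning can overrun into the cap or stop short of its centre;
   the signed correction (forward free distance − maximum boundary
   distance along the path) handles both cases and is exact for circular
   caps.
2. *Chain-length bias.* Summing 1/√2 step weights overestimates oblique
   straight runs by up to ~8%; the path length is therefore the Euclidean
   arc length of the path subsampled every 4 pixels.

Against analytic stadium shapes (medial axis L − W, so
AR = (L−W)²/A) the worst error over L/W ∈ {2, 5, 10} at six orientations
is 7.6%. Near-circular patches collapse the skeleton toward a point; they
yield AR < 1 and a `DegenerateSkeletonWarning`. Patch "inversion" during
axial elongation is applied as the literal reciprocal of AR, flagged by
the caller — no automatic trigger exists in the source material, so none
is invented. Multi-component masks are rejected rather than merged.

## Aboral profiles

Profiles are sampled along a line ROI laid along the aboral mesoglea,
averaged across the full line width (default transverse sampling at pixel
resolution), and the position axis is *translated* so the pore sits at 0 —
translation, not normalization to [0, 1], is the only reading consistent
with a fixed 100-µm ROI length. The pErk variant fixes the span to
[0, 50] µm from outside toward the body cavity at 5-µm line width.

The depletion-zone score mirrors the FWHM convention: flank level = mean
of the outer 20% of samples per side, depth = 1 − min/flank, width = the
distance between the two crossings of flank·(1 − depth/2) nearest the
minimum, linearly interpolated. Dips shallower than a configurable noise
floor (default depth 0.05) raise a no-dip error instead of returning a
meaningless width. Recovery on synthetic pores (5 µm wide, depth 0.6):
within 4% noise-free, within 10% (20 seeds) at 5% noise.

Ensembles resample member profiles by linear interpolation onto the finest
common grid over their overlapping range and report per-position mean and
SD (ddof = 1; SD = 0 for a single member). Pore localization is the
caller's input; automatic pore detection is out of scope.

## Synthetic scenes

The generator emulates the study's imaging conditions at desk scale and is
the package's acceptance surface: every analysis has a recovery test
against its ground truth.

- **Body scene** (default 60 × 30 µm ellipse at 0.1 µm/px): the mesoglea
  midline is the inner parallel of the body outline at a constant ectoderm
  thickness (default 8 µm), realized through the Euclidean
  distance-to-boundary field; the band's transverse profile is Gaussian in
  that field with σ = T/(2√(2 ln 2)), so its FWHM equals the nominal
  thickness T (default 2 µm) everywhere — the distance field's unit
  gradient preserves physical widths. Plateaus: ectoderm 100, endoderm
  100 × excess (default 1.5), band peak 1000. The truth object carries the
  midline polyline (oriented endoderm-left), AR, the revolved-ellipsoid
  volume and the closed-form ec/ic ratio.
- **Aboral scene**: a straight horizontal band with the pore on a pixel
  centre; Col IV is attenuated multiplicatively by a Gaussian dip whose
  full width at half depth is the nominal 5 µm, so at depth 1 the signal
  reaches exactly 0 at the pore; the laminin channel carries a co-located
  50% band thickening instead of a dip.
- **Patch scene**: an analytic stadium (points within W/2 of a segment of
  length L − W) at arbitrary orientation; truth area and medial-axis
  length are closed-form.
- **Trajectories**: AR linear from start to end (default 1 → 8 over 100
  frames of 2 min); volume grows multiplicatively (default 0.5%/frame) and
  drops by the leakage fraction at the leakage frame, staying reduced;
  noise is multiplicative log-normal with unit mean and chosen CV.

Image noise is additive i.i.d. Gaussian, clipped at zero to keep
intensities physical; the source material states no noise model, so the
default is noise-free and tests set noise explicitly (the standard noisy
condition used throughout is σ = 5% of the band peak). Identical
(config, seed) yields bit-identical output.

What the scenes do **not** emulate: the mm scale of the real animal (all
geometry is scaled to tens of µm so the suite runs in seconds; every
estimator is resolution-invariant within interpolation tolerance, checked
explicitly), tentacles, optical blur and depth attenuation, structured
background, intracellular Col IV puncta, and any mechanics of muscular
hydraulics. Passing recovery tests therefore demonstrates correctness of
the estimators under known geometry and noise, not robustness to every
real-microscopy artifact.

## Known limitations

- Straightening assumes curvature radii ≳ 5× the half width; tighter
  curvature distorts the transverse metric (band mass is conserved within
  5% at the 5× bound).
- The FWHM thickness is biased when the band width approaches the optical
  resolution or the flanking plateaus differ strongly; both biases are
  quantified above on synthetic scenes.
- The patch end correction assumes near-uniform patch width near the ends;
  strongly tapering patches would be over- or under-corrected.
- Volume estimation treats every axial slice as a filled disk; concave
  cross sections violate the revolution assumption.
- The leakage detector reports fractional drops relative to a smoothed
  running maximum; during continued growth the reported drop fraction
  slightly underestimates the instantaneous fraction (the onset frame is
  unaffected).
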