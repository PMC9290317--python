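# Methods

`retimorph` measures clinically studied morphometric features of the
retinal vasculature and optic disc from segmentation maps of color
fundus photographs, with an ensemble-confidence quality gate in front
and agreement statistics behind. This note records the models,
numerical choices, and their limits.

## Pipeline model

A cohort run proceeds per image, with per-image failure isolation:

1. **Preprocessing.** The bright retinal field is separated from the
   dark border by luma-weighted grayscale conversion and a global
   threshold (default 10/255; Otsu fallback when the fixed threshold
   captures under 5% of the frame), cleaned by morphological opening
   then closing with a disk element of radius `max(3, 1% of the short
   side)`, reduced to the largest connected component, and hole-filled.
   The image is cropped to a square centered on the mask's bounding
   box. Under the default `pad` policy the square may extend past the
   frame (black fill) so no retina is lost; crop offsets are recorded
   and may then be negative, and `output + offset = input` holds
   exactly. The `clip` policy stays inside the frame.
2. **Quality gate.** Eight classifier outputs (3-class probabilities
   over good/usable/reject) collapse per model to
   P(gradable) = P(good) + P(usable). The ensemble prediction is the
   majority of per-model binary calls (tie → ungradable, the
   conservative direction); confidence is the mean and population SD
   (n = 8 divisor) of the eight probabilities of the predicted class.
   A gradable call with mean < 0.75 or SD > 0.1 is *rectified* to
   ungradable. Rectification is one-directional: it only ever removes
   images from the measurable pool, so tightening either threshold
   never promotes an image.
3. **Map ingestion.** Vessel probability maps threshold at 0.5 with
   ties counting as vessel; artery/vein maps take the per-pixel argmax
   over (artery, vein, uncertain, background) with ties broken in that
   fixed order for determinism. Segmentation models themselves are
   pluggable inputs, not part of the package.
4. **Morphometry** (below), then CSV reports.

## Vessel centerlines

The vessel mask is thinned to an 8-connected, topology-preserving
skeleton (`skimage.morphology.skeletonize`) and split at junction
pixels (≥ 3 skeleton neighbours) into maximal branch-free segments;
junction pixels belong to no segment, so each non-junction skeleton
pixel lands in exactly one segment. Terminal twigs shorter than 10 px
or twice the local caliber — thinning artifacts — are pruned
iteratively, re-thinning between passes because removing a spur can
leave a bump pixel on the parent path. Per-point caliber is twice the
Euclidean distance transform of the mask at the centerline, which on
constant-width synthetic ribbons recovers the drawn width within
±1 px for widths ≥ 3.

## Feature definitions and numerics

**Distance tortuosity** is arc/chord per segment. Summing per-pixel
steps (1 axial, √2 diagonal) overestimates the length of a smooth
digital curve by up to ~8% depending on orientation, which would
swamp the measure near 1; the arc length is therefore *rectified* by
resampling the chain to unit spacing and smoothing with a 5-point
moving average whose ends are padded by odd reflection (so a digital
straight line maps to itself and scores exactly 1). A rasterized
semicircle then lands within 0.2% of π/2. Closed loops (zero chord)
are excluded.

**Squared-curvature tortuosity** is ∫κ² ds along the centerline,
unnormalized (units 1/px; divide by length for the normalized
variant). Finite differences on rasterized chains are noise-dominated
even after moving-average smoothing (+74% on an r = 50 semicircle), so
curvature comes from a parametric cubic smoothing spline fitted over
the chain's arc-length parameter with a residual budget of 0.5 px² per
point, its analytic derivatives evaluated at unit spacing and
integrated over the *spline's* arc length (the chain parameter itself
carries the staircase inflation). Four pixels are dropped at each tip
before fitting: skeleton endpoints carry thinning jogs that would
otherwise bend the whole fit. Accuracy on rasterized arcs r = 25–100
is within ~6%, and the 1/scale similarity law holds within ~5%.

**Tortuosity density** partitions the centerline at inflection points
into n maximal constant-curvature-sign runs and computes
((n−1)/n)·(1/L)·Σᵢ(arcᵢ/chordᵢ − 1). Curvature signs come from the
same spline; magnitudes below 10⁻³ px⁻¹ count as straight, and sign
runs shorter than 5 px of arc are merged into their neighbour
(curvature flicker, not a twist — a spurious boundary splits a hump
and roughly halves its excess). A straight vessel and a single smooth
arc both score 0; on rasterized sine curves the value agrees with the
analytic continuous-curve computation within a few percent, dominated
by end subsegments whose excess depends on where the vessel happens to
terminate within a hump.

**Fractal dimension** is box-counting (Minkowski–Bouligand): occupied
boxes over a dyadic ladder from 2 px to a quarter of the short side,
least-squares slope of log N against log(1/ε), clamped to the planar
range [0, 2]; the fit R² is available as a quality diagnostic.

**Vessel density** is the exact pixel-count ratio |vessel ∩ region| /
|region|.

**Caliber equivalents.** The six widest arteries (veins) feed CRAE
(CRVE) by iterative pairing — sort, combine widest with narrowest, the
odd middle value carried, repeat until one value:

* revised (Knudtson): Ŵ = k·√(Wa² + Wb²), k = 0.88 arteries /
  0.95 veins — scale-invariant, so pixel units are safe;
* Parr–Hubbard: Ŵ = √(0.87Wa² + 1.01Wb² − 0.22·Wa·Wb − 10.76) for
  arteries (Wa the wider), Ŵ = √(0.72Wa² + 0.91Wb² + 450.05) for
  veins. The additive constants were calibrated in micrometers; with
  pixel widths their relative weight depends on image resolution, so
  pixel-unit Hubbard values are comparable only within one acquisition
  setup. A negative artery radicand (very thin vessels) rejects that
  pair with a diagnostic.

AVR = CRAE/CRVE. For identical artery/vein width sets the Knudtson
AVR equals (0.88/0.95)^r only when every pairing round is carry-free
(sets of 2, 4, 8, ... with r rounds); a six-width set carries one
value past round two and lands at ≈ 0.818 instead of the pure cube
0.7948. When fewer than six vessels qualify, all available are used
and the record is flagged — widths are never fabricated.

**Zones.** Zone B is the annulus 0.5–1.0 disc diameters from the disc
margin, Zone C 0.5–2.0; the scalar disc diameter is the mean of the
disc's bounding-box height and width, and a pixel belongs to a zone
when its center lies in [inner, outer). Pixel-level features
(density, fractal dimension, average width) use the vessel mask and
skeleton points clipped to the annulus. Segment-level tortuosities
use centerlines clipped to the annulus (maximal in-zone runs of at
least 10 points): radial trunks *cross* Zone B rather than lying
inside it, so any membership-by-fraction rule would leave the zone
empty. Caliber selection requires ≥ 5 in-zone centerline points and
ranks by the mean caliber over in-zone points only. Image-level
tortuosities are arc-length-weighted means over segments, so short
spurs do not dominate.

**Disc/cup.** Bounding-box height and width of each mask (largest
component), vertical and horizontal cup-to-disc ratios; an absent or
empty cup reports missing CDRs rather than zeros.

Segments inherit artery/vein labels by majority vote of the A/V
raster along their centerline; uncertain pixels count toward neither,
are excluded from caliber, but remain in the binary-vessel features.

## Synthetic scenes and what they show

The generator renders an elliptical disc and cup (cup/disc extent
ratio 0.5) centered in a 768×768 frame and 14 vessels radiating from
the margin of a diameter-100 disc — alternating artery/vein so both
caliber pools hold 7 vessels, widths stepping 15, 13, …, 3 px within
each label so caliber ranking is checkable — with a sinusoidal lateral
offset (amplitude 2 px, period 60 px) and extent 2.2 disc diameters,
comfortably covering Zone C. Tubes are stamped from continuous
centerline polylines, which makes arc length, chord, and labels exact
ledger quantities; the ledger's vessel area is the rendered mask's
pixel count, so density closure is exact by construction while width
and tortuosity closure are genuine measurements. All randomness
(angle jitter, waviness phase) flows from the single spec seed; a
scene is bit-reproducible.

Ensemble draws are Dirichlet with parameters 1 + c on the true class
and 1 elsewhere: c → ∞ gives certainty (mean 1, SD 0), c ≈ 2 yields
the disagreement that trips the confidence gate. The demo-dataset
writer can deterministically construct low-confidence scenes by
redrawing (seed-offset) until the default gate fires.

Not emulated: texture, illumination gradients, pathology, vessel
crossings, caliber taper, segmentation noise. Passing ledger-closure
tests therefore demonstrates that the *measurement* code is correct on
clean geometry, not that the pipeline is robust to imperfect
segmentation of real photographs.

## Agreement statistics

Classification metrics follow the standard confusion-count formulas
with zero-denominator cases reported missing, not zero. AUC is the
rank statistic (ties half-weighted), computed via scikit-learn and
cross-checked in tests against a brute-force pairwise oracle. IoU of
two empty masks is defined as 1. Bland–Altman reports mean difference
and MD ± 1.96·SD (sample SD) limits of agreement. The ICC is the
two-way, absolute-agreement, single-measurement form — ICC(A,1), the
natural choice for two fixed measurement methods on the same images —
computed via pingouin with its F-based 95% CI and cross-checked
against the raw ANOVA mean-squares formula in tests; zero variance in
both raters reports a missing ICC.

## Problem sizes

Default verification runs use 768² scenes (≈ 0.5 s each to render and
measure), 50 seeded scenes for ledger closure, 1000 random width
sextets for the caliber oracle, 10⁵ paired differences for the
Bland–Altman simulation, and 10⁴ pairs for the ICC noise floor.

## Known limitations

* Width from 2× the distance transform reads ≈ drawn width + 0.5–1 px
  on ribbons of even width and at tube caps; sub-pixel edge fitting is
  deliberately out of scope.
* Tortuosity density's end subsegments make the measure sensitive to
  where a vessel is truncated (by the frame, a junction, or a zone
  boundary); values are comparable across images processed with the
  same settings, less so across settings.
* Hubbard equivalents in pixel units inherit the resolution caveat
  above.
* A/V crossings are not disambiguated; a crossing splits segments at a
  junction and its pixels vote into both labels.
* The fundus-field threshold and morphology radii are package
  defaults chosen for robustness on synthetic and typical photographs;
  they are not fitted to any dataset.
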