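# Methods

## Problem and scope

`limbalign` measures frontal-plane lower-limb alignment from per-ROI binary
bone masks of a standing full-leg radiograph. It covers the *measurement*
stage of an automated system — landmark detection from masks, axis
construction, the 16 standard alignment parameters, normal-range
classification — together with the preprocessing operators such systems
apply to images, the statistics used to validate them, and a synthetic
phantom that stands in for the upstream detection/segmentation networks.
Producing the masks themselves (object detection, semantic segmentation) is
out of scope; masks come from the user or from the phantom.

## Coordinate and side conventions

All code uses 0-based `(row, col)` pixel coordinates, row increasing
downward (superior → inferior), half-open boxes, and a pixel spacing in
mm/px for unit conversion. For a left limb the lateral side is toward
smaller columns; right-side masks are mirrored into this convention before
detection and the results un-mirrored afterwards, so one set of
medial/lateral rules serves both sides and left/right symmetry is exact by
construction. Medial/lateral labels always derive from the side flag, never
from image content.

Axis lines are *oriented*: shaft and mechanical axes proximal → distal, the
femoral neck axis pointing toward the head centre. Each named clinical angle
is the angle in [0°, 180°] between two oriented rays:

| parameter | rays |
|---|---|
| mLPFA | femoral mech. axis (hip→knee) vs head-centre→trochanter-tip |
| mLDFA | femoral mech. axis (knee→hip) vs knee-centre→lateral condyle |
| mMPTA | tibial mech. axis (knee→ankle) vs knee-centre→medial plateau |
| mLDTA | tibial mech. axis (ankle→knee) vs ankle-centre→lateral plafond |
| mJLCA | condylar vs plateau joint lines (orientation-free, acute) |
| mTFA / aTFA | femoral vs tibial mechanical / anatomical axes |
| NSA | neck axis (toward head) vs femoral anatomical axis (prox→dist) |
| aMPFA / aLDFA / aMPTA / aLDTA | anatomical-axis analogues |

MAD is the perpendicular distance (mm) from the tibial knee centre to the
hip–ankle line, reported unsigned to match the published 0–3 mm range; a
signed variant (positive = knee centre lateral to the line, i.e. varus) is
available via `signed_mad=True`. Lengths: full leg = head apex → ankle
centre, femur = head apex → femoral knee centre, tibia = tibial knee centre
→ ankle centre, all ‖·‖₂ × spacing.

Normal ranges are closed intervals (boundary values classify as normal; the
sources do not state boundary handling, and closed intervals are the
conservative reading). The anatomical distal tibial angle is flagged against
86°–92°, the same interval as its mechanical counterpart: the tibial
anatomical and mechanical axes coincide, and the published table garbles
this row (it prints the aLDFA row twice). mJLCA is an angle in degrees
(its printed normal range is 0°–2°), even though some published result
tables label it "(mm)".

## The phantom

The phantom models each bone as a union of piecewise-analytic primitives
(discs, rectangles, convex quads) in a continuous millimetre frame, so every
landmark and every parameter has an exact closed-form value **before**
rasterisation; rasterisation error is charged to the measured pipeline, not
to the truth. Construction, for a left limb (right is an exact mirror):

- The tibial mechanical axis is vertical. The plateau line realises
  `mMPTA_true`; the condylar line is the plateau rotated by `jlca_true`;
  the femoral mechanical axis is placed so the lateral angle to the condylar
  line is `mLDFA_true`. The implied tibiofemoral angle is therefore
  `phi = mLDFA − mMPTA − jlca` (positive = varus).
- The femoral head is a disc of radius `head_radius` on the mechanical axis;
  the anatomical axis is the mechanical axis tilted laterally by the
  anatomical–mechanical angle (default 6°, the anatomically standard femoral
  value); the neck joins head centre to shaft at `neck_shaft_angle`; the
  greater trochanter is a disc whose tip realises `mLPFA_true`.
- Joint surfaces (condyles, plateau, plafond) are pairs of disc lobes whose
  extremal points lie **exactly** on the joint-orientation lines, joined by
  a quad that recedes from the joint line and creates the intercondylar
  notch. The knee mask therefore has two connected components (distal femur
  and proximal tibia) separated by an 8 mm joint space — as in real
  segmentations, where the articular surfaces of adjacent bones never touch.
  Each component is hole-free. A consequence worth noting: the knee and
  ankle *centres* (midpoints of joint lines) sit in the joint space, up to
  one lobe radius away from bone foreground.

Rasterisation samples pixel centres against the analytic union, so
mirroring maps pixel centres to pixel centres and left/right phantom pairs
are bitwise mirror images.

Default conditions emulate an adult population: femur ~460 ± 25 mm, tibia
~363 ± 20 mm (leg ≈ 800–840 mm), 0.48 mm/px spacing on a 2000×760 px canvas
(roughly a 4× downsample of a ~3000×7000 px full-leg radiograph, tall enough
for the upper tail of the length distribution). `sample_spec` draws from
four populations: `normal` keeps every parameterised angle inside its normal
range and |phi| ≤ 0.5°; `varus`/`valgus` set phi ∈ ±[3.5°, 8°] with matching
plateau/condyle tilts; `lld` keeps normal angles but shortens the limb by
roughly 6–12 cm. Because the anatomical–mechanical angle is fixed at its
anatomical 6°, the derived aTFA of a "normal" phantom (~6°) exceeds the
published 0°–3° normal range — the published population tables show the same
tension (mean aTFA 4.2°, mean aMPFA 78.8° vs range 80°–89°), so the
generator does not bend anatomy to the table.

**Boundary jitter** models segmentation noise: each mask's sub-pixel
boundary contour is displaced along its normals by zero-mean Gaussian noise
smoothed along arclength (correlation length 5 px, rescaled to the requested
sd) and re-rasterised. The truth is untouched. One seed governs spec
sampling, a second governs jitter.

## Landmark detectors

- **Femoral head**: initial centre/radius from the distance-transform
  maximum (largest inscribed disc); Kåsa algebraic circle fit to sub-pixel
  boundary points within ±2.5 px of the ring, excluding a 70° cone around
  the neck attachment (two fit-select iterations). Apex = top of the fitted
  disc. The neck axis is fitted from the corridor of mask pixels just beyond
  the head boundary: an initial direction from the thin band centroid, then
  a cross-section-midpoint regression along half a head radius, with a
  perpendicular-width cut and a bin-width guard so the trochanter never
  contaminates the fit. The trochanter tip is the most superior mask point
  outside 1.3× the fitted disc on the lateral side of the neck line, refined
  by a quadratic fit to the per-column extremal profile (the profile is
  quantised to integer rows; fitting a parabola over ±9 columns centred on
  the top plateau recovers the extremum to ~0.2 px). A bare-disc mask
  reports the trochanter and neck as absent rather than guessing.
- **Shaft axes**: for each occupied row in the central 60% of the mask's
  vertical extent (a config knob; the margin avoids metaphyseal flare), the
  midpoint of the foreground run; total-least-squares line via SVD. Masks
  with multiple runs in >20% of rows are rejected as fragmented.
- **Joint lines**: the knee mask is split into femoral/tibial components by
  connected components (fallback: a cut at the row-occupancy pinch, so a
  noise-bridged joint space still splits). Per component, the per-column
  extremal-row profile is smoothed (σ = 2 px) and its two most prominent
  peaks taken as the articular lobes; each extremal point is refined with
  the same quadratic sub-pixel fit. Fewer than two lobes raises a
  degeneracy error naming the bone.

All detectors operate in the mask's own cropped frame; `assemble()` applies
ROI offsets exactly, so landmark positions are exactly equivariant under
integer translation of the ROIs.

## Preprocessing operators

Pad-to-square (fill 0, content centred, remainder to bottom/right), bilinear
fixed-size resize, ROI crop, right→left flip, and [0,1] normalisation, each
publishing an exact affine coordinate transform (`out = in·s + t`,
pixel-centre convention for resize). CLAHE is implemented directly on
8-bit input: the image is divided into a `block = (8, 8)` grid (edge tiles
absorb the remainder), each tile's 256-bin histogram is clipped at
`clip = 2.0` times the uniform bin height with the excess redistributed
uniformly, and pixels are mapped by bilinear interpolation between the four
nearest tile transfer functions. A constant (single-bin) tile has no
contrast to equalise and keeps the identity map, which makes CLAHE exactly
idempotent on constant images. Defaults (8,8)/2.0 match the preprocessing
reported for radiograph segmentation pipelines of this kind.

## Evaluation statistics

- DSC = 2|A∩B|/(|A|+|B|), defined as 1 when both masks are empty.
- Hausdorff distance: undirected maximum over 4-connectivity boundary pixel
  sets, × spacing; a percentile variant (e.g. HD95) via `percentile=`.
  The maximum variant is the default because the comparison tables this
  toolkit reproduces report plain HD in mm.
- mAP: per class, greedy score-ordered matching at each IoU threshold
  0.50:0.05:0.95, all-point interpolated AP (area under the
  precision–recall envelope), averaged over thresholds then classes.
  Classes with detections but no ground truth are excluded with a warning.
- Agreement: Pearson r; Lin's CCC with biased (1/n) moments per Lin's
  original estimator; ICC via explicit two-way ANOVA mean squares —
  ICC(2,1) (two-way random effects, absolute agreement, single rater) by
  default, the standard choice for method comparison, with ICC(1,1) and
  ICC(3,1) selectable; MAE/MSE/RMSE on differences (system − reference);
  Bland–Altman bias ± 1.96·SD limits; mean absolute deviation of the
  differences. Zero-variance series yield `None` for the correlation
  coefficients instead of NaN. The dispersion statistic is named
  `mad_abs_dev` throughout to avoid any collision with the mechanical axis
  deviation (`MAD`, mm).

## Numerical choices and degenerate inputs

- Circle fits require ≥3 non-collinear points (singular-value ratio < 1e-9
  rejects collinear input). Extremal-point ties break toward smaller column
  in the left-convention frame (deterministic, mirrored for right).
- Sub-pixel extrema: quadratic LSQ over a ±9-column window; the fit falls
  back to the raw extremum when the parabola opens the wrong way.
- Angles are computed as arccos of clipped unit-vector dot products; report
  validation rejects non-finite or out-of-range values with the parameter
  named.
- Missing ROI classes, empty masks, fragmented shafts and single-lobed
  joints raise typed errors naming the structure.

## What the phantom does and does not show

Phantom tests demonstrate that the geometry engine recovers known ground
truth through rasterisation and boundary noise: over 100 noise-free
normal-population phantoms every angle is recovered within 0.5° and every
length within 1 mm, and with 1 px boundary jitter the mean absolute angle
error stays below 1° with no pipeline failures (recomputed by
`scripts/acceptance.py`). The phantom is piecewise-analytic: it has no bone
texture, osteophytes, soft-tissue shadow, patella overlap or pathological
morphology, and its articular surfaces are disc lobes rather than anatomical
condyles. Passing these tests therefore validates the measurement geometry
and its conventions, not the ability of any segmentation model to produce
good masks from real radiographs; on real data the overall error budget is
dominated by segmentation quality, which this package only evaluates
(DSC/HD), never produces.

## Known limitations

- Single-frame 2-D frontal-plane analysis only; no rotational profile, no
  sagittal parameters, no 3-D reconstruction.
- The trochanter detector assumes the greater trochanter lies clear of the
  fitted head disc (>1.3 r); dysplastic or implant-bearing hips violate
  this and are out of scope.
- The joint-line detector expects two articular lobes; severely eroded or
  single-lobed joints raise a degeneracy error rather than measuring.
- Normal-range flags implement the published table verbatim; they are not a
  clinical decision aid.
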