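# Methods

This note documents the models and numerical choices behind `depotmri`:
what the synthetic phantom emulates (and what it does not), how each
correction and measurement is computed, and where the design was
genuinely open.

## 1. Coordinate and acquisition model

Volumes are `(x, y, z)` arrays: `x` lateral in-plane, `y` the in-plane
depth axis (skin at small `y`, muscle at large `y`), `z` the
slice-stacking axis. Voxel centre of index `(i, j, k)` is
`origin + (i, j, k) · spacing` in mm. Defaults follow the imaging
protocol: 0.6 mm in-plane spacing (protocol range 0.5469–0.6641 mm),
4 mm slice pitch representing 3 mm slices with a 1 mm skip, ~10.8 cm
stack extent (27 slices). The slab nature of a slice is modelled by
averaging five geometry samples across the central 3 mm of each 4 mm
pitch; along `y` the tissue interfaces are rendered with analytic
partial-volume occupancy, so boundary positions are defined well below
the voxel size. Note that in axial slices the skin→muscle direction is
*in-plane*: depth measurements enjoy the 0.6 mm resolution, not the
4 mm pitch.

## 2. Phantom anatomy

All anatomy lives in a cannula-centred frame (`x = z = 0` at the
injection site) and is built from single-valued height fields:

* skin surface `y_skin(x) = skin_depth + curvature·(x/halfFOV)²`
  (default depth 14 mm, curvature 6 mm — a gentle body contour that also
  gives the lateral realignment something to lock onto);
* dermis of constant thickness (default 1.5 mm) rendered at background
  intensity — the sequence cannot see it, which is exactly the artifact
  the capsule-gap correction addresses;
* ID/SC interface at `y_skin + dermis`;
* SC/IM interface at `y_skin + dermis + T(x, z)` with
  `T = B·(1 + 0.05·sin(2πx/64)·sin(2πz/108))` plus an optional muscle
  undulation term; both modulations vanish at the cannula, so the
  baseline thickness `B` *is* the reference-point truth;
* muscle from the SC/IM interface to the bottom of the volume.

Intensity classes (arbitrary units): background/dermis 0, muscle 60, SC
fat 100, depot 200, capsule oil 255 — the T2-FSE ordering with the
depot strictly brighter than fat. Additive Gaussian noise (σ = 5 by
default; Rician available) and a multiplicative linear attenuation
field (±15 % across `x` by default) are applied on top.

### Tissue expansion (the conforming depot)

Injection lifts the skin and ID/SC surfaces by a **flat-top
(super-Gaussian) bump** `A·exp(−(r²/2σ²)²)`; the SC/IM interface stays
fixed (muscle is stiff relative to subcutis). The amplitude `A` is the
prescribed per-stage expansion percentage of the baseline thickness
(this is what calibrates the phantom to reported site means), and the
width `σ` is solved by bisection so the discrete integral of the bump
over the lateral grid equals the injected volume — the SC layer volume
increase therefore conserves the bolus volume by construction. The
flat top matters: the "deepest depot point" that anchors the thickness
track is only defined to within a few millimetres on near-parallel
surfaces, and a plateau guarantees the truth value holds across that
ambiguity, whereas a Gaussian peak would make the target ill-posed.
The abdomen preset uses a wider lateral field of view (168 mm vs
128 mm) because its small expansion percentages (0.7 % of 19 mm at
2 mL) need lateral room for volume conservation.

### Depot shape

The depot is one **star-shaped implicit body**: an oblate spheroid
(depth semi-axis = 0.35 × final thickness) whose radius is modulated by
seeded angular lobes, `f(u) = (|u| / R(û))²` with
`R = 1 + Σ aᵢ·exp(−(1 − û·dᵢ)/0.15)`. Star-shapedness makes every
injected-volume level set connected and nested — a union of separate
lobe spheroids sheds disconnected blobs at small volumes, which
connected-component selection would (correctly) discard. Lobe
directions avoid straight-down so the main bolus bottom remains the
deepest point. The mask is cut at the level that yields exactly
`round(V / voxel volume)` voxels inside the SC layer (1.5 mm standoff
from both interfaces), so the truth volume matches the target within
half a voxel; infeasible requests (a bolus the layer cannot hold)
raise an explicit error.

### Artifacts and stage frames

* **Void**: a cylinder (default radius 3 mm, optional insertion-angle
  tilt) about the cannula axis is set to background while the cannula
  is in situ (insertion through the maximum volume; never
  post-removal).
* **Breathing stair-step**: a per-slice in-plane `(x, y)` shift
  schedule (default alternating ±1 mm for the abdomen, none elsewhere).
  It is rendered *analytically at rasterisation* — each slice sees the
  anatomy at its own displacement, like a real acquisition — because
  resampling a finished volume blurs small depots enough to corrupt
  their volumes. `apply_artifacts` can still translate the slices of an
  arbitrary volume when given an explicit schedule.
* **Stage frames**: the naïve and post-removal scans carry small rigid
  offsets (translation + rotation about the depth axis) for subject
  repositioning; in-series stages share one frame because the infusion
  set stays in place. Restricting rotations to the depth axis keeps
  every interface an exact height field in every frame; the alignment
  code itself is fully general.
* Fiducial capsules (oil radius 4.5 mm inside a 0.5 mm invisible
  gelatin wall) ride on the skin at deliberately *irregular* positions:
  an exactly symmetric layout would make unlabelled fiducial
  correspondence ambiguous under half-turn flips.

## 3. Measurement chain

Per scan: polynomial bias correction → fiducial detection → ROI →
boundary extraction → slice realignment → (injected stages) threshold
selection, depot segmentation, void backfill → morphometrics. Ordering
rationale: the threshold must see a flat field, and realignment
operates on the extracted boundary sheets.

* **Bias correction** fits a total-degree ≤ order polynomial over the
  *lateral* plane to voxels of the dominant SC-fat mode (selected
  between the muscle/SC and SC/bright midpoints), normalises it to mean
  1 and divides. The fit region is a thin depth slab, so depth terms
  would be unconstrained extrapolation — the documented artifact is
  lateral shading.
* **Boundary extraction** classifies each depth column from the bottom:
  the contiguous muscle run anchors SC/IM; walking up through the
  tissue run until the invisible-dermis gap gives ID/SC (capsule oil is
  rejected by the gap, depot columns pass through because the depot is
  itself SC content). Sub-voxel localisation integrates partial-volume
  occupancy over a 4-voxel window — unlike two-point crossing
  interpolation it is unbiased for every edge phase relative to the
  grid (crossing interpolation is bistable when a flat interface sits
  near a voxel-centre phase and produces realisation-dependent,
  region-coherent offsets). Columns without a resolvable layer (the
  cannula void) are flagged invalid and filled by harmonic (Laplace)
  interpolation from the valid rim — an averaging fill that attenuates
  rim noise instead of amplifying it the way exact polynomial
  interpolants do.
* **Threshold selection**: exhaustive Otsu over the integer-rounded
  histogram of the SC band (voxels between the two interfaces — the
  region where SC fat and depot are the two classes); `valley` (minimum
  between the two brightest modes) and `fixed` are available. Otsu is
  the default because the original surface-determination settings are
  not documented.
* **Depot segmentation**: threshold, opening-by-reconstruction with a
  1-voxel (in mm, per-axis) element — erosion removes speckle,
  propagation restores surviving components to their exact thresholded
  extent so small depots are not shaved — then 26-connected components;
  the component intersecting a cylinder about the cannula axis wins
  (largest on ties). The closed mesh comes from marching cubes and
  agrees with the voxel count within 5 %.
* **Slice realignment** estimates each slice's in-plane shift against
  the average contour of its two neighbours (grid search with parabolic
  refinement in `x`, closed-form `y`), iterates with damping 0.5, then
  high-passes the schedule along `z` with a binomial [1,2,1]/4
  smoother — zero response to the slice-to-slice alternation that
  breathing produces, unity to smooth trends, so genuine anatomy is
  not smeared — enforces zero mean shift, and zeroes schedules below a
  0.2 mm RMS detection floor (artifact-free scans must not be
  roughened). Corrected fields are re-inpainted (the first fill ran on
  still-jagged data) and median+Gaussian smoothed; smoothing matters
  because a minimum distance against a noisy sheet is biased low.
* **Series alignment**: closed-form Kabsch on fiducial centroids with
  correspondence chosen by exhaustive permutation restricted to
  plausibly small transforms (< 20°, < 15 mm), refined by ICP between
  ID-surface samples with fiducials kept in the correspondence set.
  The post-removal scan is the default reference (the configurable
  reading of "the post-injection scan").
* **Void backfill** transfers occupancy from the aligned post-removal
  depot into the detected near-zero cylinder only — voxels outside the
  void mask never change.
* **Thickness** is the per-column minimum 3-D distance from the SC/IM
  point to the ID/SC sheet (vertical-gap mode available for sensitivity
  analysis); point-to-triangle distances use an exact closest-point
  primitive with a k-d-tree vertex prefilter. The reference-point track
  re-interpolates the mapped point onto each stage's SC/IM surface
  before measuring, which removes the depth component of residual rigid
  alignment error (tissue expansion is not rigid, and a rigid fit
  partially absorbs it).
* **Projection**: least-squares skin plane over the depot footprint,
  orthographic rasterisation of the mesh triangles (0.25 mm pixels),
  area = pixel sum; principal axes are the caliper extents along the
  footprint's principal directions (first axis the widest, ties broken
  toward the grid `x`).
* Dermal thickness = mean over capsules of (imaged oil lower surface →
  ID/SC gap) − capsule wall (default 0.5 mm, a caliper-style input),
  clamped at zero with a warning. The oil body is located by sphere fit
  (centroid + volume-radius), which is far less sensitive to the 4 mm
  slice quantisation than the deepest-voxel estimate.

Summary statistics are descriptive only (n, mean, SEM, SD, min, max)
— the underlying study was not powered for inferential comparisons.

## 4. Problem sizes and determinism

Acceptance-scale series use the full protocol geometry (e.g. abdomen
280 × 107 × 27 voxels per stage, six stages); a full series analyses in
roughly 10–20 s on one CPU, and the whole acceptance computation (six
series) in a few minutes. The test suite mostly runs on a reduced
lateral field of view (72 mm) with 1 + 3 mL stages, which preserves the
voxel geometry while keeping a full generate + analyse cycle under a
few seconds. All randomness flows from explicit integer seeds through
`numpy` generators; identical spec + seed reproduces volumes and
metrics byte-for-byte.

## 5. What passing on the phantom does and does not show

The generator reproduces the *structure* of the measurement problem:
anisotropic slabs, partial volume, noise, shading, the invisible
dermis, the metal void, breathing stair-step, repositioning offsets,
conforming tissue expansion and lobular depot shapes with exact ground
truth. It does not model MR physics (no k-space, susceptibility, or
coil profiles), interstitial flow (depot shapes are geometric, not
fluid-dynamic), non-rigid breathing within a slice, subject-to-subject
anatomical variability beyond its parameter ranges, or depots that
genuinely breach the muscle fascia. Recovery within ±0.5 mm / ±2
percentage points / ±10 % volume on these phantoms therefore validates
the analysis chain under controlled, truth-known conditions; it is not
a clinical accuracy claim for arbitrary in-vivo scans.

## 6. Open choices made here

* Threshold method defaults to Otsu; the original software's surface
  determination settings are undocumented, so the method is config.
* Alignment reference defaults to the post-removal scan ("the
  post-injection scan" is ambiguous); configurable.
* Realignment corrects the extracted surfaces by default; applying the
  shifts to the intensity volume is supported but off (whether the
  original analysis resampled intensities is not stated).
* The thickness-histogram region of interest defaults to the analysed
  ROI; bin width 1 mm, frequencies normalised to 100 %.
* The depot's in-plane field of view and the cannula insertion angle
  are free parameters of the phantom (neither is documented).
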