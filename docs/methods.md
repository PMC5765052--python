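# Methods

This note records the measurement definitions, the numerical choices
behind them, what the phantom generator does and does not emulate, and
the known limitations.

## Coordinate and unit conventions

Voxel arrays are indexed `(z, y, x)` with axis 0 the longitudinal
(scan/anatomical) axis. Spacing is `(sz, sy, sx)` in mm per voxel,
strictly positive; world coordinates are voxel centers,
`world = origin + index * spacing`, and the index↔world map round-trips
to 1e-12 mm. All outputs are mm / mm² / mm³. Slice ranges are half-open
`[start, stop)`. Millimetre offsets are converted to whole slices by
round-half-away-from-zero — some rounding rule is unavoidable on an
8.6 µm grid and this one is fixed and symmetric.

## Segmentation and the trabecular VOI

Bone is segmented by a global gray-level threshold, foreground iff
`value >= level`, default level 40 on the phantom gray scale
(foreground ≈ 100, background ≈ 20). Inclusivity is a fixed convention;
thresholding is antitone in the level. Component cleanup uses
26-connected foreground (6-connected background), the standard 3D
duality; size ties break toward the component containing the smallest
voxel index.

The trabecular VOI is referenced to the growth-plate plane (a supplied
slice index — locating the plate is an anatomical judgement, so it is an
input, not an image computation): the VOI starts `offset_mm` (default
0.1 mm) from the reference toward the diaphysis and spans `extent_mm`
(default 0.5 mm). At 8.6 µm spacing that is a 12-slice offset and a
58-slice slab.

## Trabecular outcomes

* **BV/TV** — `count(bone & VOI) / count(VOI)`; exact by construction.
* **Tb.Th** — model-independent local thickness: at each foreground
  voxel, the diameter of the largest sphere that fits inside the
  foreground and covers that voxel; Tb.Th is the foreground mean. The
  implementation computes the Euclidean distance transform in physical
  mm (anisotropic spacing respected), then sweeps candidate radii in
  descending order, marking coverage with one complement-distance
  transform per radius level. When the set of distinct radii is small
  (or the grid is small), every exact radius is swept and the result
  equals the brute-force definition exactly; on large grids the sweep is
  capped at 128 levels with radii snapped *down* to the retained level,
  a conservative error below one level gap (well under a voxel).
* **Tb.N** — plate model, `(BV/TV) / Tb.Th`. The plate model is exact on
  plate phantoms and deterministic; the choice is recorded in the result
  object (`tb_n_model`). The direct mid-axis alternative is not
  implemented.

Expected discretization behaviour: thickness values are quantized by the
voxel grid; a slab of n voxel layers reports exactly `n * spacing`
because the half-voxel overshoot of the distance transform at both faces
cancels the half-voxel inset of the voxel-center sampling. Spheres whose
analytic radius falls exactly on a voxel-shell boundary are the worst
case (up to one voxel of overestimate).

## Curved lengths and centerlines

A curved length is the piecewise-linear length of an ordered seed
polyline — deliberately no spline smoothing, so the number is exactly
what an interactive 3D length tool reports and is rigid-motion invariant
to 1e-9 relative. Refining seeds on a smooth curve converges to the
analytic arc length from below.

`centerline_from_mask` automates seed placement for tubular masks:
3D skeletonization, a 26-connected graph over skeleton voxels with
physical edge weights, tip detection (degree-1 nodes), geodesic farthest
tip pair (ties broken by coordinate order), and the geodesic path between
them. Two corrections matter numerically:

* the voxel path zig-zags at one-voxel amplitude, inflating its length
  by up to ~15%; the path is densely resampled and smoothed twice with a
  0.5 mm moving-average window (endpoints pinned) — large against a
  voxel, small against anatomical curvature radii (shortening error
  ~`w²/24R²`, about 0.1% at R ≈ 3 mm);
* thinning retracts the skeleton from tube ends by roughly one tube
  radius; both ends are extended along their local tangents until the
  ray exits the mask.

A tubularity guard rejects masks whose longest skeleton path is shorter
than four maximal inscribed radii (a sphere skeletonizes to a short spur,
not an axis). Recovery accuracy on phantoms: 0.3% on a helix, 0.6% on a
straight tube, both well inside the 2% test tolerance.

## Growth plate

Volume is the voxel-count volume of the supplied plate mask (plate
outlining is manual in practice, so segmentation is an input). The
two-surface thickness splits the mask's marching-cubes isosurface (at the
binary 0.5 level, degenerate faces removed) by the component of the
outward face normal along the plate axis: `>= rim_tolerance` (default
0.5) is the proximal sheet, `<= -rim_tolerance` the distal sheet, the
rest is rim and discarded. Marching-cubes winding is globally consistent,
so outwardness is fixed by a single majority vote from trilinear probes
either side of each face centroid — per-face probing alone misorients a
few percent of faces on staircased surfaces and would interleave the
sheets. A plate-ness guard rejects masks whose inscribed-sphere thickness
exceeds half the footprint extent (a ball is not a plate). For strongly
inclined plates the rim inclination `sin(tilt)` must stay below the
tolerance while the sheet normals stay above it; shell-cap tests
therefore use a 40° cap with `rim_tolerance = 0.7`.

Thickness samples are unsigned nearest-point distances from each proximal
vertex to the distal sheet (KD-tree over distal vertices, face centroids
and edge midpoints — resolution ~half an edge length), robust on curved
plates. The scalar summary is the **area-weighted mean** (vertex weight =
one third of adjacent face areas); the full histogram is retained in the
result, and a topographic map grids the samples over the orthographic
in-plane footprint (default bin: 2 voxels). The volume/thickness ratio is
a surface-area surrogate: exact for constant thickness, with error
bounded by the thickness coefficient of variation (within 5% on the
2:1-range wedge phantom). Thickness is symmetric under sheet swap to
within 2% on phantoms; whether one averages over one sheet or both is a
sub-voxel effect here.

## Craniofacial

Skull volume: threshold → largest 26-connected component → voxel-count
volume. Brain volume: per-slice segmented areas × slice thickness
(slice segmentation is an input, as in manual MRI workflows); with
0.5 mm slices this midpoint-rule reconstruction is ~0.3% accurate on an
ellipsoid. The foramen rim is the **longest closed loop of boundary
edges** (edges used by exactly one face) of the cropped skull mesh — the
rim is itself a closed curve on the surface, so its length *is* the
geodesic circumference; this requires an open mesh (a watertight mesh is
rejected). Diameters `D_t`, `D_s` are 3D extents of the loop along two
supplied orthonormal axes (anatomical axes are a user/config input;
phantom default: world y transverse, z sagittal), and the area is
`¼·π·D_t·D_s` — exact for planar elliptical apertures.

## Spine

KI = AB/CD with AB the landmark chord and CD the maximum perpendicular
distance from the chord to the dorsal profile between the landmark feet;
landmarks default to the profile endpoints and are configurable, since
published landmark conventions vary. A perfectly straight profile (CD=0)
returns +inf with a warning. Body length is the 2D landmark distance
(nasal tip → first caudal base); pedicle length is the mean of left and
right apex→base distances; the lumbar L4–L6 length reuses the curved
length on canal seed points. 2D measurements live on the lateral
projection plane (orthographic along left–right).

## Statistics

Welch's two-tailed unpaired t-test per (measurement, age), with
Welch–Satterthwaite df (not rounded) and no continuity corrections
anywhere; groups with n < 2 are skipped with a warning. Holm–Šídák
step-down adjustment (`max_{j<=k} 1-(1-p_(j))^(m-j+1)`, clipped, input
order preserved) serves timeline families such as body-weight curves.
Chi-square goodness of fit uses `Σ(O-E)²/E`, df = k−1. Summaries report
mean ± SEM (sd/√n) and the conventional star bands with strict
inequalities — boundary p-values (exactly 0.05 or 0.01) fall to the less
significant band. Delegations: Welch and chi-square call scipy.stats;
Holm–Šídák is implemented directly; all three are tested against
independent oracles (hand formulas, statsmodels) to 1e-10.

## Phantom generator

Phantoms are the package's study conditions, not tunable fixtures:

* gray levels — foreground N(100, σ), background N(20, σ), clipped to
  [0, 255], so threshold 40 is the correct operating point and segments
  noise-free phantoms exactly; σ defaults to 0 (exact tests) with 10–15
  used in robustness tests;
* all randomness flows from the spec's integer seed (bit-identical
  volumes under identical specs);
* every phantom carries closed-form ground truth for the measurables it
  supports (arc length, fill fraction, plate thickness, shell/cap
  volumes, ellipse metrics, chord/sagitta KI, arc length of the canal).

Geometry notes: the curved tube has **flat ends** (voxels whose nearest
curve point is a curve endpoint are excluded), so the analytic arc length
is exactly the end-to-end centerline length; plate lattices contain whole
plates with background padding, so the fill fraction is exactly
thickness/period; slab and wedge plates carry a 2-voxel background
margin; the ellipsoid is generated with anisotropic spacing matching a
0.5 mm MRI slice protocol.

Study tables simulate a two-genotype (WT/Ach), two-age (3/6 wk) design
with Gaussian measurement noise; the default catalogue (femur/tibia
length, BV/TV, growth-plate volume, brain volume, kyphosis index) uses
juvenile-mouse-scale means and SDs, and the default 14 animals per
genotype-age cell yields a 56-animal study. Effects are specified per
measurement in SD units per age.

What the phantoms do **not** emulate: CT physics (beam hardening, ring
artefacts, partial-volume blur), anatomically realistic shapes, cortical/
trabecular interfaces, or intra-animal correlation across measurements.
Passing recovery tests therefore demonstrates correctness of the
measurement definitions and their discretization behaviour, not
robustness to scanner artefacts.

## Problem sizes

Test and acceptance runs use grids between ~10⁵ and ~10⁷ voxels (e.g.
plate lattice 164×60×60 at 10 µm, skull shell 205³ at 50 µm), 1000
simulated studies for null calibration and 200 for the effect-pattern
power check — sizes chosen so exact/analytic tolerances are resolvable
while a full validation sweep completes in about a minute.

## Known limitations

* Tb.Sp, SMI, anisotropy and connectivity density are out of scope, as is
  BMD calibration (no density phantom).
* The growth-plate thickness map uses orthographic projection; strongly
  folded plates would alias.
* The end-to-end study simulation shows a ~94% per-run rate for the joint
  "significant at 3 wk AND not at 6 wk" pattern at a 2 SD effect with
  n=10/group — the product of ~98.8% power and the 95% null retention at
  α=0.05; simulations agree with the noncentral-t closed form.
* Automatic detection of the growth-plate reference plane, vertebra
  labelling, and skull landmarking are deliberately not attempted;
  these are anatomical judgements supplied as inputs.
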