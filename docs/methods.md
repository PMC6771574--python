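# Methods

## Planning model

The planner treats LITT trajectory design as deterministic constraint
filtering followed by ranking. The target point is fixed per method (an
anatomically parameterized translation of the amygdala centroid); the
search space is the set of outer-surface voxels of the chosen entry region.
This reflects how the clinical heuristics are stated — the target is
anatomical, the freedom is where to enter — and makes the search exhaustive
and reproducible: identical inputs give byte-identical ranked output, with
no stochastic optimizer to tune.

Coordinates are RAS millimetres throughout; voxel indices are 0-based and a
voxel is the closed unit cube centred on its index's world image. "Medial"
is resolved toward the mid-sagittal plane, taken from the skull-shell
bounding-box midpoint, so its sign follows the planned hemisphere.

### Hard constraints (defaults)

| constraint | default | unit | rationale |
|---|---|---|---|
| maximum length | 120 | mm | limit parenchymal transgression |
| drilling angle from skull normal | 30 | deg | prevent drill skiving |
| vessel clearance | 3 | mm | avascular corridor margin |
| sulcal clearance | 3 | mm | sulci carry vessels below imaging resolution |
| brainstem clearance | 7 | mm | limit heat transmission |
| no-entry structures | lateral ventricle | — | hemorrhage / CSF leak / heat sink |

Comparisons are inclusive at the printed bound (a 120.0 mm path passes; an
exactly-30° angle passes and is logged) to avoid floating-point knife
edges. Sulci share the 3 mm critical-structure margin by default but are
independently configurable (`d_safe_sulci`).

### Risk score

128 nodes are spaced equally along the path, endpoints inclusive; each
node's vessel distance *d* (trilinear interpolation of an anisotropic
Euclidean distance transform) maps to the per-node risk
*r(d) = (d_max − min(d, d_max))/(d_max − d_safe)*. The form is the simplest
continuous one satisfying the defining normalization: *r* = 0 at and beyond
the outer radius, *r* = 1 exactly at the safety margin, *r* > 1 inside it.
The aggregate is the arithmetic **mean** over nodes: a sum would
re-introduce the length dependence the fixed node count exists to remove,
and a mean lets cohort scores sit modestly above or below 1. A `max`
aggregation is exposed in `RiskParams` for users who want the strict
guarantee "score > 1 ⇔ some node inside the margin" at the trajectory
level. The outer radius *d_max* = 10 mm is a package default (it is not a
printed clinical constant): it keeps the risk zone local while making
*r(d_safe)* = 1 exact, and it is configurable.

### Ablation model

The cavity is a capsule — cylinder with hemispherical caps — of one uniform
configurable diameter (device range 5–15 mm, default 15). The distal
endpoint is the target; the proximal endpoint is the most proximal
trajectory point whose capsule cross-section still reaches the union of the
four mesial ROIs, optionally clipped at a posterior-limit plane (e.g. the
tectal level) supplied as point + normal. This proximity rule reproduces
"ablate back along the hippocampus" behaviour without landmark detection.
A capsule rather than a flat-ended cylinder is used because thermal
cavities are rounded at the fibre tip and the capsule has exact closed
forms (πr²h + 4/3πr³) against which voxelization is tested (within 2 % on a
0.5 mm grid; the discrepancy at least halves when the voxel size halves).
Overlap percentages divide by each structure's preoperative volume. No
bioheat simulation or heat-sink modelling is attempted: the capsule is a
geometric estimate, not a thermal-dose prediction.

### Ranking

Feasible candidates sort by (1) ascending risk score, (2) descending
amygdala + hippocampus ablation percentage, (3) ascending length, (4)
entry-enumeration index as a final deterministic tie-break — safety first,
then coverage, then invasiveness.

## Numerical choices

* Distance fields honour anisotropic spacing
  (`scipy.ndimage.distance_transform_edt(sampling=spacing)`); off-grid
  queries clamp to the nearest border voxel because scalp entry points sit
  near the grid edge. Interpolated values are accurate to within one voxel
  diagonal of the brute-force nearest-source distance (tested).
* Segment/mask intersection is sampled at 0.5 mm (configurable), with the
  point-in-voxel test done by nearest-integer rounding of fractional
  indices; agreement with 0.01 mm dense sampling is tested on adversarial
  random masks.
* The skull-surface normal is the gradient of a Gaussian-smoothed signed
  distance to the cranial cavity. Smoothing of σ = 2 voxels is the default:
  on a rasterized spherical shell σ = 1 leaves up to ≈4.6° of staircase
  error in the normal while σ = 2 keeps it under ≈1.5°, inside the 2°
  accuracy the tests demand. For open geometries with no enclosed cavity
  (a flat slab), the unsigned shell distance is used instead; the normal's
  line is still well defined and the drilling angle is
  orientation-insensitive.
* Degenerate inputs raise typed errors rather than returning sentinels:
  empty masks (centroid, distance field), zero-length trajectories,
  trajectories that never approach the ROI complex (ablation), zero-volume
  structures (overlap percentages).

## The synthetic phantom

`generate_phantom` emulates exactly the geometry the planner exercises, not
an MRI. The skull is a superellipsoid shell (exponents 4, 2, 4; inner
semi-axes 50 × 58 × 45 mm): elongated antero-posteriorly with a relatively
flat occipital pole, which is what lets a posterior entry reach a mesial
target within 30° of the surface normal, as on a real elongated skull — a
spherical phantom cannot satisfy that constraint. The amygdala is an
analytic ellipsoid (painted first, so its rasterized centroid and volume
match the closed form), the hippocampus a curved tube with a head bulge,
the entorhinal cortex and parahippocampal gyrus inferomedial sheets, the
ventricle's temporal horn a thin superomedial tube, the brainstem a central
cylinder. Entry regions are patches of a cortical band just inside the
inner table. Structures are painted first-wins so ROI labels are never
overwritten.

Vasculature is the adversarial part: seeded random tortuous cortical tubes
plus a deliberate vessel curtain between the entry regions and the target.
In `corridor="open"` scenes, all vessel voxels within a 7 mm clearance
radius of each method's ground-truth trajectory are carved away — this
*guarantees* one avascular corridor per entry region and makes the set of
feasible entries a small neighbourhood of the recorded ground-truth entry
(the recorded corridor patch radius, 12 mm, conservatively bounds that
neighbourhood). In `corridor="blocked"` scenes the curtain is intact and no
feasible trajectory exists, by construction. A per-seed jitter (±1.5 mm on
the amygdala centre) plus the random vessels vary the scenes across seeds.

What the phantom does **not** model — and hence what passing tests do not
show about clinical data: realistic cortical folding (sulci are two planar
sheets), MRI intensities and segmentation error, vessel calibre
distributions, hippocampal sclerosis, CSF spaces, or anatomically faithful
entry-region extents. Tests on phantoms demonstrate correctness of the
geometry, constraint logic and ranking, and the qualitative between-method
ordering of ablation profiles; they say nothing about cohort-level clinical
values.

## Problem sizes

The default phantom grid is 128³ voxels at 1 mm. The validation cohort is
20 open-corridor plus 20 blocked seeds, planned for all three methods with
rank depth 3 and re-audited by independently coded checkers (brute-force
voxel-centre distances, 0.05 mm dense segment sampling, the analytic
superellipsoid normal); oracle-equivalence suites run on ≤ 32³ grids where
exhaustive brute force is exact. These sizes keep the full suite around a
few minutes on one CPU while leaving the audited safety margins far from
their bounds (worst observed: drilling angle ≈ 22° of 30°, vessel clearance
≈ 5.9 mm of 3 mm).

## Known limitations

* Single-trajectory planning only; staged multi-trajectory ablations and
  SEEG-style multi-electrode planning are out of scope.
* The ablation model is geometric; thermal nonlinearity and heat sinks are
  not modelled, so percentages are planning estimates, not dose predictions.
* Image registration, parcellation and vessel segmentation are upstream:
  the package consumes a labeled volume and vessel mask it trusts.
* The between-method statistics (`compare_methods`) are deliberately plain
  one-way ANOVA + Bonferroni pairwise t tests for convenience reporting;
  rater-preference modelling (mixed-effects/ordinal regression) is out of
  scope.
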