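"""Seeded synthetic head scenes for exercising every planner stage.

The phantom is a schematic left or right hemisphere planning problem on a
128 mm^3 grid:

* the skull is a superellipsoid shell (exponents 4, 2, 4) — elongated
  antero-posteriorly with a relatively flat occipital pole, so that
  posterior entries reach the mesial target at a realistic drilling angle;
* the amygdala is an ellipsoid, the hippocampus a curved tube with an
  anterior head bulge, the entorhinal cortex and parahippocampal gyrus are
  inferomedial sheets, the temporal horn of the lateral ventricle a thin
  curved tube superomedial to the hippocampus, and the brainstem a central
  cylinder;
* entry regions (inferior occipital gyrus, temporo-occipital junction) are
  patches of a cortical band just inside the inner table of the skull;
* vessels are seeded random tortuous cortical tubes plus a deliberate
  "curtain" slab between the entry regions and the target.  With
  ``corridor="open"`` all vessel voxels within a clearance radius of the
  ground-truth trajectories are carved away, guaranteeing one avascular
  corridor per entry region; with ``corridor="blocked"`` the curtain is left
  intact and no feasible trajectory exists.

Structures are painted first-wins, so earlier ROI labels are never
overwritten; the amygdala is painted first and therefore matches its
analytic ellipsoid exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .io_models import (
    BinaryMask,
    LabelVolume,
    LittPlanError,
    StructureRoleMap,
)

__all__ = ["PhantomSpec", "GenerationError", "LABELS", "generate_phantom", "perturb_vessels"]


class GenerationError(LittPlanError):
    """The requested phantom cannot be rasterized with disjoint structures."""


#: Label IDs used by generated phantoms (role map is still explicit).
LABELS = {
    "amygdala": 1,
    "hippocampus": 2,
    "entorhinal_cortex": 3,
    "parahippocampal_gyrus": 4,
    "lateral_ventricle": 5,
    "brainstem": 6,
    "sulci": 7,
    "entry_region_IOG": 9,
    "entry_region_TOJ": 10,
    "skull_shell": 11,
    "vessels": 8,
}

#: inner-table semi-axes of the superellipsoid skull (mm); shell is +3 mm
SKULL_INNER = np.array([50.0, 58.0, 45.0])
SKULL_THICKNESS = 3.0
#: cortical band (fraction of the inner-table superellipsoid) holding entries
ENTRY_BAND = (0.90, 0.98)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic planning scene.

    All geometry is expressed in left-hemisphere world mm and mirrored in x
    for ``side="right"``.  ``corridor`` chooses whether a guaranteed
    avascular corridor is carved from each entry region to the target
    ("open") or the vessel curtain is left intact ("blocked").
    """

    seed: int = 0
    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    side: str = "left"
    corridor: str = "open"
    # mesial temporal geometry (mm, left-hemisphere coordinates)
    amygdala_center: tuple[float, float, float] = (-22.0, 2.0, -15.0)
    amygdala_semi_axes: tuple[float, float, float] = (8.0, 6.5, 7.0)
    hippocampus_radius: float = 4.5
    hippocampus_head_radius: float = 6.5
    sheet_thickness: float = 6.0
    ventricle_radius: float = 3.5
    brainstem_radius: float = 7.0
    # vasculature
    vessel_count: int = 6
    vessel_radius: float = 1.2
    vessel_tortuosity: float = 0.35
    corridor_clearance_mm: float = 7.0
    # per-seed random jitter applied to the amygdala centre (mm per axis)
    jitter_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise GenerationError("side must be 'left' or 'right'")
        if self.corridor not in ("open", "blocked"):
            raise GenerationError("corridor must be 'open' or 'blocked'")
        if min(self.shape) < 32:
            raise GenerationError("grid too small for the phantom anatomy")
        if (
            min(self.amygdala_semi_axes) <= 0
            or self.hippocampus_radius <= 0
            or self.vessel_radius <= 0
            or self.brainstem_radius <= 0
        ):
            raise GenerationError("all radii and semi-axes must be positive")


# ---------------------------------------------------------------------------
# rasterization helpers


def _affine_for(spec: PhantomSpec) -> np.ndarray:
    affine = np.eye(4)
    spacing = np.asarray(spec.spacing, dtype=float)
    shape = np.asarray(spec.shape, dtype=float)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = -spacing * np.floor(shape / 2.0)
    return affine


def _world_grids(spec: PhantomSpec, affine: np.ndarray):
    axes = [np.arange(n, dtype=float) for n in spec.shape]
    i, j, k = np.meshgrid(*axes, indexing="ij", sparse=True)
    a = affine
    x = a[0, 0] * i + a[0, 1] * j + a[0, 2] * k + a[0, 3]
    y = a[1, 0] * i + a[1, 1] * j + a[1, 2] * k + a[1, 3]
    z = a[2, 0] * i + a[2, 1] * j + a[2, 2] * k + a[2, 3]
    return np.broadcast_to(x, spec.shape), np.broadcast_to(y, spec.shape), np.broadcast_to(z, spec.shape)


def _superellipsoid(x, y, z, semi: np.ndarray) -> np.ndarray:
    """f < 1 inside; exponents (4, 2, 4): box-like in x/z, round in y."""
    return (
        (np.abs(x) / semi[0]) ** 4
        + (np.abs(y) / semi[1]) ** 2
        + (np.abs(z) / semi[2]) ** 4
    )


def _ellipsoid_mask(x, y, z, center, semi) -> np.ndarray:
    cx, cy, cz = center
    return (
        ((x - cx) / semi[0]) ** 2 + ((y - cy) / semi[1]) ** 2 + ((z - cz) / semi[2]) ** 2
    ) <= 1.0


def _box_mask(x, y, z, lo, hi) -> np.ndarray:
    return (
        (x >= lo[0]) & (x <= hi[0]) & (y >= lo[1]) & (y <= hi[1]) & (z >= lo[2]) & (z <= hi[2])
    )


def _paint_tube(out: np.ndarray, affine: np.ndarray, polyline: np.ndarray, radius) -> None:
    """OR into ``out`` all voxels within ``radius`` of the polyline.

    ``radius`` may be a scalar or per-vertex array (linearly interpolated
    along each segment via the max of its endpoints for the crop, exact
    per-point distance test against the segment with endpoint-max radius).
    """
    inv = np.linalg.inv(affine)
    shape = np.asarray(out.shape)
    polyline = np.asarray(polyline, dtype=float)
    radii = np.broadcast_to(np.asarray(radius, dtype=float), (len(polyline),))
    for a, b, ra, rb in zip(polyline[:-1], polyline[1:], radii[:-1], radii[1:]):
        r = max(ra, rb)
        lo_w = np.minimum(a, b) - r
        hi_w = np.maximum(a, b) + r
        corners = np.array(np.meshgrid(*zip(lo_w, hi_w), indexing="ij")).reshape(3, -1).T
        ijk = corners @ inv[:3, :3].T + inv[:3, 3]
        lo = np.maximum(np.floor(ijk.min(axis=0)).astype(int), 0)
        hi = np.minimum(np.ceil(ijk.max(axis=0)).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        ii, jj, kk = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
        pts = pts @ affine[:3, :3].T + affine[:3, 3]
        ab = b - a
        denom = float(np.dot(ab, ab))
        if denom < 1e-24:
            d = np.linalg.norm(pts - a, axis=-1)
            rr = ra
        else:
            t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
            d = np.linalg.norm(pts - (a + t[:, None] * ab), axis=-1)
            rr = ra + t * (rb - ra)
        sub = (d <= rr).reshape(ii.shape)
        out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= sub


# ---------------------------------------------------------------------------
# generation


def generate_phantom(
    spec: PhantomSpec = PhantomSpec(), verify: bool = False
) -> tuple[LabelVolume, StructureRoleMap, dict]:
    """Generate a labeled head phantom, its role map and a ground-truth record.

    Deterministic for a given spec (one seeded generator drives all random
    geometry).  The ground truth contains analytic amygdala geometry, measured
    centroids/volumes of every structure, the per-method targets and
    guaranteed-corridor entry points, and the corridor clearance radius.
    With ``verify=True`` the ground-truth trajectories are additionally
    re-checked against the default hard constraints (costs four distance
    transforms).
    """
    rng = np.random.default_rng(spec.seed)
    affine = _affine_for(spec)
    x, y, z = _world_grids(spec, affine)
    mirror = -1.0 if spec.side == "right" else 1.0
    xs = mirror * x  # left-hemisphere coordinates regardless of side

    jitter = rng.uniform(-spec.jitter_mm, spec.jitter_mm, size=3)
    amy_center = np.asarray(spec.amygdala_center) + jitter
    amy_semi = np.asarray(spec.amygdala_semi_axes)

    labels = np.zeros(spec.shape, dtype=np.int32)
    # every intracranial structure is clipped to the cavity so nothing can
    # puncture the skull shell (which must stay watertight)
    f_inner = _superellipsoid(xs, y, z, SKULL_INNER)
    cavity = f_inner < 1.0

    def paint(mask: np.ndarray, label: int, clip: bool = True) -> None:
        if clip:
            mask = mask & cavity
        labels[mask & (labels == 0)] = label

    # --- mesial temporal ROI complex (first-wins: amygdala exact) ---
    paint(_ellipsoid_mask(xs, y, z, amy_center, amy_semi), LABELS["amygdala"])

    hippo_line = np.array(
        [
            [-25.0, -6.0, -17.0],
            [-28.0, -16.0, -16.0],
            [-30.0, -26.0, -13.0],
            [-31.0, -34.0, -9.0],
        ]
    )
    hippo = np.zeros(spec.shape, dtype=bool)
    _paint_tube(
        hippo,
        affine,
        np.array([hippo_line[0], hippo_line[0] + 1e-6]) * [mirror, 1, 1],
        spec.hippocampus_head_radius,
    )
    _paint_tube(hippo, affine, hippo_line * [mirror, 1, 1], spec.hippocampus_radius)
    paint(hippo, LABELS["hippocampus"])

    th = spec.sheet_thickness
    paint(
        _box_mask(xs, y, z, (-20.0, -8.0, -21.0 - th), (-13.0, 4.0, -21.0)),
        LABELS["entorhinal_cortex"],
    )
    paint(
        _box_mask(xs, y, z, (-27.0, -36.0, -22.0 - th), (-19.0, -9.0, -22.0)),
        LABELS["parahippocampal_gyrus"],
    )

    # --- ventricle (temporal horn), brainstem ---
    vent = np.zeros(spec.shape, dtype=bool)
    vent_line = np.array([[-31.0, -30.0, -2.0], [-26.0, -16.0, 0.0], [-20.0, -4.0, 2.0]])
    _paint_tube(vent, affine, vent_line * [mirror, 1, 1], spec.ventricle_radius)
    paint(vent, LABELS["lateral_ventricle"])

    bs = ((xs - 0.0) ** 2 + (y + 18.0) ** 2 <= spec.brainstem_radius**2) & (z >= -45) & (z <= -5)
    paint(bs, LABELS["brainstem"])

    # --- sulci: two thin para-sagittal sheets lateral to the corridor ---
    sulci = _box_mask(xs, y, z, (-34.0, -30.0, -25.0), (-31.0, -5.0, -10.0)) | _box_mask(
        xs, y, z, (-45.0, -35.0, -20.0), (-42.0, 0.0, 10.0)
    )
    paint(sulci, LABELS["sulci"])

    # --- cortical entry band and patches ---
    band = (f_inner >= ENTRY_BAND[0]) & (f_inner <= ENTRY_BAND[1]) & (y < 0)
    iog = band & (xs >= -32) & (xs <= -14) & (z >= -24) & (z <= -10) & (y <= -40)
    toj = band & (xs >= -34) & (xs <= -20) & (z >= -7) & (z <= 6) & (y <= -40)
    paint(iog, LABELS["entry_region_IOG"])
    paint(toj, LABELS["entry_region_TOJ"])

    # --- skull shell ---
    f_outer = _superellipsoid(xs, y, z, SKULL_INNER + SKULL_THICKNESS)
    paint((f_inner >= 1.0) & (f_outer <= 1.0), LABELS["skull_shell"], clip=False)

    # --- targets and ground-truth entries (world coordinates) ---
    world_amy_center = amy_center * [mirror, 1.0, 1.0]
    medial_sign = 1.0 if spec.side == "left" else -1.0
    targets = {
        "centroid_T2": world_amy_center.copy(),
        "expert_T3": world_amy_center + [medial_sign * 3.0, 3.0, -3.0],
        "ml_T4": world_amy_center + [medial_sign * 3.0, 3.0, 0.0],
    }

    def gt_entry(patch: np.ndarray, target: np.ndarray) -> np.ndarray:
        idx = np.argwhere(patch)
        if idx.size == 0:
            raise GenerationError("entry patch rasterized empty")
        pts = idx @ affine[:3, :3].T + affine[:3, 3]
        aim = pts.mean(axis=0) - target
        aim /= np.linalg.norm(aim)
        rel = pts - target
        lateral = rel - np.outer(rel @ aim, aim)
        return pts[np.argmin(np.linalg.norm(lateral, axis=1))]

    entries = {
        "centroid_T2": gt_entry(iog, targets["centroid_T2"]),
        "expert_T3": gt_entry(iog, targets["expert_T3"]),
        "ml_T4": gt_entry(toj, targets["ml_T4"]),
    }

    # --- vasculature: random cortical tubes + curtain slab, painted last ---
    vessels = np.zeros(spec.shape, dtype=bool)
    for _ in range(spec.vessel_count):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        p = direction * SKULL_INNER * rng.uniform(0.55, 0.8)
        heading = rng.normal(size=3)
        heading /= np.linalg.norm(heading)
        pts = [p.copy()]
        for _ in range(12):
            heading = heading + spec.vessel_tortuosity * rng.normal(size=3)
            heading /= np.linalg.norm(heading)
            p = p + 4.0 * heading
            # keep the vessel inside the cortical mantle
            f = float(_superellipsoid(p[0], p[1], p[2], SKULL_INNER))
            if f > 0.88:
                p *= (0.88 / f) ** 0.25
            pts.append(p.copy())
        _paint_tube(vessels, affine, np.asarray(pts), spec.vessel_radius)

    curtain = (
        _box_mask(xs, y, z, (-48.0, -41.0, -38.0), (-6.0, -39.0, 10.0)) & (f_inner < 1.0)
    )
    vessels |= curtain

    if spec.corridor == "open":
        clear = np.zeros(spec.shape, dtype=bool)
        for method, target in targets.items():
            _paint_tube(
                clear,
                affine,
                np.array([entries[method], target]),
                spec.corridor_clearance_mm,
            )
        vessels &= ~clear
    paint(vessels, LABELS["vessels"])

    for role, lid in LABELS.items():
        if not np.any(labels == lid):
            raise GenerationError(f"structure {role!r} rasterized empty")

    vol = LabelVolume(labels=labels, affine=affine)
    role_map = StructureRoleMap(
        roles={role: frozenset([lid]) for role, lid in LABELS.items()}, side=spec.side
    )

    voxvol = float(abs(np.linalg.det(affine[:3, :3])))
    structures_gt = {}
    for role, lid in LABELS.items():
        idx = np.argwhere(labels == lid)
        c = (idx.mean(axis=0) @ affine[:3, :3].T) + affine[:3, 3]
        structures_gt[role] = {
            "centroid_mm": c.tolist(),
            "volume_mm3": float(len(idx)) * voxvol,
        }

    ground_truth = {
        "seed": spec.seed,
        "side": spec.side,
        "corridor": spec.corridor,
        "amygdala": {
            "center_mm": world_amy_center.tolist(),
            "semi_axes_mm": amy_semi.tolist(),
            "volume_mm3": float(4.0 / 3.0 * np.pi * np.prod(amy_semi)),
        },
        "structures": structures_gt,
        "targets": {m: t.tolist() for m, t in targets.items()},
        "entries": {m: e.tolist() for m, e in entries.items()},
        "corridor_clearance_mm": spec.corridor_clearance_mm,
        "entry_patch_radius_mm": 12.0,
    }

    if verify and spec.corridor == "open":
        from .geometry import Trajectory
        from .planner import PlanningConstraints, build_scene, check_feasibility

        scene = build_scene(vol, role_map)
        constraints = PlanningConstraints()
        for method, target in targets.items():
            traj = Trajectory(entries[method], target)
            violations = check_feasibility(traj, scene, constraints)
            if violations:
                raise GenerationError(
                    f"ground-truth trajectory for {method} violates {violations}"
                )
        ground_truth["verified"] = True

    return vol, role_map, ground_truth


def perturb_vessels(
    vol: LabelVolume, role_map: StructureRoleMap, dilation_mm: float
) -> LabelVolume:
    """Dilate the vessel label into unlabeled background by ``dilation_mm``.

    All other labels are preserved exactly; vessel voxels only grow, so any
    trajectory's vessel distances can only shrink (risk never decreases).
    """
    if dilation_mm < 0:
        raise GenerationError("dilation_mm must be non-negative")
    if dilation_mm == 0:
        return vol
    vessel_ids = sorted(role_map.roles["vessels"])
    vmask = np.isin(vol.labels, vessel_ids)
    spacing = vol.spacing
    dist = ndimage.distance_transform_edt(~vmask, sampling=spacing)
    grown = dist <= dilation_mm
    labels = vol.labels.copy()
    labels[grown & (labels == 0)] = vessel_ids[0]
    return LabelVolume(labels=labels, affine=vol.affine)
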