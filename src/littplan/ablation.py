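"""Capsule-model estimation of the thermal-ablation cavity.

The cavity produced by the laser fibre is modelled as a capsule — a cylinder
of uniform diameter with hemispherical caps — along the distal portion of
the trajectory.  The distal endpoint is the trajectory target; the proximal
endpoint is pulled back along the trajectory as long as the capsule still
touches the mesial temporal ROI complex (amygdala, hippocampus, entorhinal
cortex, parahippocampal gyrus), optionally clipped at a user-supplied
posterior limit plane (e.g. the level of the tectum).  Overlap volumes with
each structure are divided by the structure's preoperative volume to give
percentage ablation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .geometry import DistanceField, Trajectory
from .io_models import BinaryMask, GeometryError, ParameterError, volume_mm3

#: Structures reported in an AblationEstimate, in fixed order.
ABLATION_STRUCTURES = (
    "amygdala",
    "hippocampus",
    "entorhinal_cortex",
    "parahippocampal_gyrus",
)


@dataclass(frozen=True)
class AblationParams:
    """diameter: cavity diameter in mm (device range 5-15, default 15);
    posterior_limit: optional (point, normal) plane clipping the proximal
    extent, with the normal pointing away from the kept (target) side."""

    diameter: float = 15.0
    posterior_limit: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ParameterError("diameter must be positive")
        if not (5.0 <= self.diameter <= 15.0):
            warnings.warn(
                f"ablation diameter {self.diameter} mm is outside the 5-15 mm device range",
                stacklevel=2,
            )
        if self.posterior_limit is not None:
            point, normal = self.posterior_limit
            point = np.asarray(point, dtype=float).reshape(3)
            normal = np.asarray(normal, dtype=float).reshape(3)
            if np.linalg.norm(normal) < 1e-12:
                raise ParameterError("posterior_limit normal must be nonzero")
            object.__setattr__(self, "posterior_limit", (point, normal / np.linalg.norm(normal)))

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class AblationEstimate:
    """Capsule geometry plus per-structure overlap volumes and percentages."""

    proximal: np.ndarray
    distal: np.ndarray
    ablation_length: float
    capsule: BinaryMask
    total_volume: float
    overlap_volumes: Mapping[str, float] = field(default_factory=dict)
    overlap_percents: Mapping[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "proximal_mm": np.asarray(self.proximal).tolist(),
                "distal_mm": np.asarray(self.distal).tolist(),
                "ablation_length_mm": self.ablation_length,
                "total_volume_mm3": self.total_volume,
                "overlap_volumes_mm3": dict(self.overlap_volumes),
                "overlap_percents": dict(self.overlap_percents),
            }
        )

    def to_rows(self) -> list[dict]:
        """One CSV-ready row per structure."""
        return [
            {
                "structure": s,
                "overlap_volume_mm3": self.overlap_volumes[s],
                "percent_ablation": self.overlap_percents[s],
            }
            for s in self.overlap_volumes
        ]


def ablation_segment(
    traj: Trajectory,
    roi_distance: DistanceField,
    params: AblationParams = AblationParams(),
    step: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Proximal/distal endpoints of the ablated trajectory segment.

    ``roi_distance`` is the distance field of the union of the mesial ROIs.
    The distal endpoint is the target; the proximal endpoint is the most
    proximal trajectory point whose capsule cross-section still reaches the
    ROI union (distance <= radius), clipped at the posterior-limit plane if
    one is configured.
    """
    n = max(2, int(np.ceil(traj.length / step)) + 1)
    s = np.linspace(0.0, traj.length, n)
    pts = traj.point_at(s)
    within = roi_distance.query(pts) <= params.radius
    if not within.any():
        raise GeometryError(
            "trajectory never comes within one capsule radius of the ROI complex"
        )
    s_prox = float(s[np.argmax(within)])  # first (most proximal) touching point
    if params.posterior_limit is not None:
        # kept half-space: (p - point) . normal <= 0 (normal faces away from
        # the target side); a proximal endpoint beyond the plane is clamped
        # to the crossing, never past the target
        point, normal = params.posterior_limit
        prox_side = float(np.dot(traj.point_at(s_prox) - point, normal))
        if prox_side > 0:
            denom = float(np.dot(traj.direction, normal))
            if abs(denom) > 1e-12:
                s_plane = float(np.dot(point - traj.entry, normal)) / denom
                s_prox = float(np.clip(s_plane, s_prox, traj.length))
            else:
                s_prox = traj.length
    proximal = traj.point_at(s_prox)
    return proximal, traj.target.copy()


def capsule_voxelize(
    segment: tuple[np.ndarray, np.ndarray],
    radius: float,
    grid_affine: np.ndarray,
    grid_shape: tuple[int, int, int],
) -> BinaryMask:
    """Rasterize a capsule: voxels whose world centre is within ``radius``
    of the segment (a zero-length segment yields a sphere)."""
    if radius <= 0:
        raise ParameterError("radius must be positive")
    a = np.asarray(segment[0], dtype=float).reshape(3)
    b = np.asarray(segment[1], dtype=float).reshape(3)
    affine = np.asarray(grid_affine, dtype=float)
    inv = np.linalg.inv(affine)
    spacing = np.linalg.norm(affine[:3, :3], axis=0)

    # crop to the capsule's bounding box (in voxel space) for speed
    lo_w = np.minimum(a, b) - radius
    hi_w = np.maximum(a, b) + radius
    corners = np.array(np.meshgrid(*zip(lo_w, hi_w), indexing="ij")).reshape(3, -1).T
    ijk_corners = corners @ inv[:3, :3].T + inv[:3, 3]
    lo = np.maximum(np.floor(ijk_corners.min(axis=0)).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(ijk_corners.max(axis=0)).astype(int) + 2, grid_shape)
    mask = np.zeros(grid_shape, dtype=bool)
    if np.any(lo >= hi):
        return BinaryMask(mask, affine)

    ii, jj, kk = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    pts = ijk @ affine[:3, :3].T + affine[:3, 3]
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = (
        _point_segment_distance(pts, a, b) <= radius
    ).reshape(ii.shape)
    return BinaryMask(mask, affine)


def _point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(np.dot(ab, ab))
    if denom < 1e-24:
        return np.linalg.norm(points - a, axis=-1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(points - closest, axis=-1)


def overlap_stats(
    capsule: BinaryMask,
    structures: Mapping[str, BinaryMask],
    segment: tuple[np.ndarray, np.ndarray] | None = None,
) -> AblationEstimate:
    """Per-structure overlap volume and percentage of preoperative volume."""
    overlap_volumes: dict[str, float] = {}
    overlap_percents: dict[str, float] = {}
    vox = capsule.voxel_volume
    for name, mask in structures.items():
        if mask.shape != capsule.shape:
            raise GeometryError(f"structure {name!r} is not on the capsule grid")
        struct_vol = volume_mm3(mask)
        if struct_vol <= 0:
            raise GeometryError(f"structure {name!r} has zero volume")
        ov = float(np.count_nonzero(capsule.data & mask.data)) * vox
        overlap_volumes[name] = ov
        overlap_percents[name] = 100.0 * ov / struct_vol
    if segment is None:
        segment = (np.full(3, np.nan), np.full(3, np.nan))
    proximal = np.asarray(segment[0], dtype=float)
    distal = np.asarray(segment[1], dtype=float)
    length = float(np.linalg.norm(distal - proximal)) if np.all(np.isfinite(proximal)) else float("nan")
    return AblationEstimate(
        proximal=proximal,
        distal=distal,
        ablation_length=length,
        capsule=capsule,
        total_volume=volume_mm3(capsule),
        overlap_volumes=overlap_volumes,
        overlap_percents=overlap_percents,
    )


def estimate_ablation(
    traj: Trajectory,
    roi_distance: DistanceField,
    structures: Mapping[str, BinaryMask],
    grid_affine: np.ndarray,
    grid_shape: tuple[int, int, int],
    params: AblationParams = AblationParams(),
) -> AblationEstimate:
    """Full pipeline: segment determination, voxelization, overlap statistics."""
    segment = ablation_segment(traj, roi_distance, params)
    capsule = capsule_voxelize(segment, params.radius, grid_affine, grid_shape)
    return overlap_stats(capsule, structures, segment=segment)
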