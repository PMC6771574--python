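"""Geometric substrate: distance fields, trajectory sampling, skull normals.

Distances are always in world millimetres and honour anisotropic voxel
spacing.  Off-grid queries are clamped to the nearest border voxel so that
entry points sitting on the scalp near the grid edge remain measurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_models import BinaryMask, GeometryError, ParameterError


@dataclass(frozen=True)
class Trajectory:
    """Straight path from an entry point to a target point (world mm)."""

    entry: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        entry = np.asarray(self.entry, dtype=float).reshape(3)
        target = np.asarray(self.target, dtype=float).reshape(3)
        if not (np.all(np.isfinite(entry)) and np.all(np.isfinite(target))):
            raise GeometryError("trajectory endpoints must be finite")
        if np.linalg.norm(target - entry) <= 0.0:
            raise GeometryError("trajectory has zero length")
        object.__setattr__(self, "entry", entry)
        object.__setattr__(self, "target", target)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.target - self.entry))

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from entry toward target."""
        d = self.target - self.entry
        return d / np.linalg.norm(d)

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Point at arc length ``s`` mm from the entry."""
        s = np.asarray(s, dtype=float)
        return self.entry + np.multiply.outer(s, self.direction)


class DistanceField:
    """Euclidean distance (mm) to a source mask, trilinearly interpolable.

    The grid stores the exact anisotropic Euclidean distance transform; a
    query at an arbitrary world point interpolates between the eight
    surrounding voxel centres, which keeps the field 1-Lipschitz up to one
    voxel diagonal of interpolation error.
    """

    def __init__(self, data: np.ndarray, affine: np.ndarray):
        self.data = np.asarray(data, dtype=float)
        self.affine = np.asarray(affine, dtype=float)
        self._inv = np.linalg.inv(self.affine)

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def query(self, points: np.ndarray) -> np.ndarray:
        """Distance at (..., 3) world points; outside the grid, clamps."""
        pts = np.asarray(points, dtype=float)
        ijk = pts @ self._inv[:3, :3].T + self._inv[:3, 3]
        flat = ijk.reshape(-1, 3).T
        vals = ndimage.map_coordinates(self.data, flat, order=1, mode="nearest")
        return vals.reshape(pts.shape[:-1])


def distance_field(mask: BinaryMask) -> DistanceField:
    """Anisotropic Euclidean distance transform of a non-empty mask."""
    if not mask.data.any():
        raise GeometryError("distance field of an empty mask is undefined")
    dist = ndimage.distance_transform_edt(~mask.data, sampling=mask.spacing)
    return DistanceField(dist, mask.affine)


def sample_nodes(traj: Trajectory, n: int) -> np.ndarray:
    """``n`` equally spaced points including both endpoints, shape (n, 3).

    The node count is fixed regardless of trajectory length so that derived
    per-node statistics do not grow with length.
    """
    if n < 2:
        raise ParameterError(f"need at least 2 nodes, got {n}")
    t = np.linspace(0.0, 1.0, n)
    return traj.entry + t[:, None] * (traj.target - traj.entry)


class SkullSurface:
    """Smoothed signed-distance representation of the skull shell.

    The signed distance is negative inside the cranial cavity and positive
    in the shell and beyond; its Gaussian-smoothed gradient gives a robust
    outward surface normal on voxelized shells.  Two voxels of smoothing
    suppress the staircase noise of rasterized curved shells to well under
    2 degrees of normal error.
    """

    def __init__(self, skull: BinaryMask, sigma_voxels: float = 2.0):
        if not skull.data.any():
            raise GeometryError("skull mask is empty")
        self.affine = skull.affine
        self._inv = np.linalg.inv(self.affine)
        spacing = skull.spacing
        solid = ndimage.binary_fill_holes(skull.data)
        cavity = solid & ~skull.data
        if cavity.any():
            # closed shell: signed distance to the cranial cavity — negative
            # inside, zero at the inner table, increasing outward
            outside = ndimage.distance_transform_edt(~cavity, sampling=spacing)
            inside = ndimage.distance_transform_edt(cavity, sampling=spacing)
            sdf = outside - inside
        else:
            # open geometry (e.g. a flat slab): signed distance to the shell
            # itself; the normal line is still well defined, its sign is not
            outside = ndimage.distance_transform_edt(~skull.data, sampling=spacing)
            inside = ndimage.distance_transform_edt(skull.data, sampling=spacing)
            sdf = inside - outside
        sdf = ndimage.gaussian_filter(sdf, sigma=sigma_voxels)
        self.sdf = sdf
        # world-space gradient: per-axis voxel gradient divided by spacing
        self._grad = np.stack(np.gradient(sdf), axis=0) / spacing[:, None, None, None]
        self._shell_dist = ndimage.distance_transform_edt(~skull.data, sampling=spacing)

    def _voxel(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self._inv[:3, :3].T + self._inv[:3, 3]

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        ijk = self._voxel(points).reshape(-1, 3).T
        out = ndimage.map_coordinates(self.sdf, ijk, order=1, mode="nearest")
        return out.reshape(np.asarray(points).shape[:-1])

    def shell_distance(self, points: np.ndarray) -> np.ndarray:
        """Unsigned distance (mm) to the nearest shell voxel."""
        ijk = self._voxel(points).reshape(-1, 3).T
        out = ndimage.map_coordinates(self._shell_dist, ijk, order=1, mode="nearest")
        return out.reshape(np.asarray(points).shape[:-1])

    def normals(self, points: np.ndarray) -> np.ndarray:
        """Outward unit normals at (..., 3) world points."""
        pts = np.asarray(points, dtype=float)
        ijk = self._voxel(pts).reshape(-1, 3).T
        g = np.stack(
            [ndimage.map_coordinates(self._grad[a], ijk, order=1, mode="nearest") for a in range(3)],
            axis=-1,
        )
        norms = np.linalg.norm(g, axis=-1, keepdims=True)
        if np.any(norms < 1e-12):
            raise GeometryError("degenerate surface gradient (point too far from skull?)")
        return (g / norms).reshape(pts.shape)


def skull_normal(
    skull: BinaryMask | SkullSurface, entry: np.ndarray, max_surface_dist_voxels: float = 2.0
) -> np.ndarray:
    """Outward unit normal of the skull shell at an entry point.

    ``entry`` must lie within ``max_surface_dist_voxels`` voxels of the shell
    surface; farther points have no well-defined drilling site.
    """
    surf = skull if isinstance(skull, SkullSurface) else SkullSurface(skull)
    entry = np.asarray(entry, dtype=float).reshape(3)
    spacing = np.linalg.norm(surf.affine[:3, :3], axis=0)
    tol = max_surface_dist_voxels * float(np.max(spacing))
    if surf.shell_distance(entry[None, :])[0] > tol:
        raise GeometryError(
            f"entry point {entry} is more than {tol:.1f} mm from the skull surface"
        )
    return surf.normals(entry[None, :])[0]


def drilling_angle(traj: Trajectory, normal: np.ndarray) -> float:
    """Angle in degrees between the trajectory and the surface-normal line.

    Orientation-insensitive: 0 deg means the drill is perfectly orthogonal to
    the skull surface, 90 deg means it grazes the tangent plane.
    """
    normal = np.asarray(normal, dtype=float).reshape(3)
    n = normal / np.linalg.norm(normal)
    c = abs(float(np.dot(traj.direction, n)))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def segment_intersects(mask: BinaryMask, traj: Trajectory, step: float = 0.5) -> bool:
    """True iff any sample point at spacing <= ``step`` lies in a true voxel.

    A point lies in a voxel iff the voxel's index is the nearest-integer
    rounding of the point's fractional index (voxels are closed unit cubes
    centred on their index).
    """
    if step <= 0:
        raise ParameterError("step must be positive")
    n = max(2, int(np.ceil(traj.length / step)) + 1)
    pts = sample_nodes(traj, n)
    inv = np.linalg.inv(mask.affine)
    ijk = np.rint(pts @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    shape = np.asarray(mask.shape)
    inside = np.all((ijk >= 0) & (ijk < shape), axis=1)
    if not inside.any():
        return False
    sel = ijk[inside]
    return bool(mask.data[sel[:, 0], sel[:, 1], sel[:, 2]].any())


def min_distance_along(traj: Trajectory, field: DistanceField, n: int = 128) -> float:
    """Minimum of the distance field over ``n`` equally spaced trajectory nodes."""
    return float(field.query(sample_nodes(traj, n)).min())
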