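"""Labeled volumes, structure-role resolution and basic ROI measurements.

Conventions used throughout the package:

* World space is RAS millimetres.
* Voxel indices are 0-based; a voxel occupies the closed unit cube (in index
  space) centred on its index, so its world-space centre is ``affine @ (i, j,
  k, 1)``.
* "Medial" means toward the mid-sagittal plane, whose x-coordinate is taken
  from the midpoint of the skull-shell bounding box; its sign therefore
  depends on the hemisphere being planned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import yaml


class LittPlanError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(LittPlanError):
    """Unreadable or malformed input file."""


class ConfigurationError(LittPlanError):
    """Inconsistent role map or planning configuration."""


class GeometryError(LittPlanError):
    """Degenerate geometric input (empty mask, zero-length trajectory, ...)."""


class ParameterError(LittPlanError):
    """Out-of-range numeric parameter."""


#: Roles a planning scene needs.  The four mesial temporal ROIs come first;
#: they must map to pairwise-disjoint label sets.
MESIAL_ROI_ROLES = (
    "amygdala",
    "hippocampus",
    "entorhinal_cortex",
    "parahippocampal_gyrus",
)

ALL_ROLES = MESIAL_ROI_ROLES + (
    "lateral_ventricle",
    "brainstem",
    "sulci",
    "vessels",
    "entry_region_IOG",
    "entry_region_TOJ",
    "skull_shell",
)


@dataclass(frozen=True)
class LabelVolume:
    """Integer label grid plus a voxel-to-world affine (mm)."""

    labels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        affine = np.asarray(self.affine, dtype=float)
        if labels.ndim != 3 or min(labels.shape) < 1:
            raise FormatError(f"label grid must be 3-D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise FormatError("label grid must have an integer dtype")
        if labels.min() < 0:
            raise FormatError("labels must be non-negative")
        if affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise FormatError("affine is singular")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_from_voxel(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxel_from_world(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) world mm coordinates to (fractional) voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass(frozen=True)
class BinaryMask:
    """Boolean grid sharing a parent :class:`LabelVolume`'s affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.dtype != bool:
            data = data.astype(bool)
        if data.ndim != 3:
            raise FormatError("mask must be 3-D")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_from_voxel(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxel_from_world(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass(frozen=True)
class StructureRoleMap:
    """Mapping from anatomical roles to label IDs, plus the planned side."""

    roles: Mapping[str, frozenset[int]]
    side: str

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ConfigurationError(f"side must be 'left' or 'right', got {self.side!r}")
        roles = {str(k): frozenset(int(v) for v in vals) for k, vals in dict(self.roles).items()}
        for role, ids in roles.items():
            if not ids:
                raise ConfigurationError(f"role {role!r} maps to no label IDs")
        object.__setattr__(self, "roles", roles)

    def labels_for(self, role_names: Iterable[str]) -> frozenset[int]:
        names = list(role_names)
        out: set[int] = set()
        for name in names:
            if name not in self.roles:
                raise ConfigurationError(f"unknown role {name!r}")
            out |= self.roles[name]
        return frozenset(out)

    def validate_against(self, vol: LabelVolume) -> None:
        """Check every role's labels exist in the volume and ROIs are disjoint."""
        present = set(np.unique(vol.labels).tolist())
        for role, ids in self.roles.items():
            if not (ids & present):
                raise ConfigurationError(
                    f"role {role!r} has no label present in the volume (ids {sorted(ids)})"
                )
        for i, a in enumerate(MESIAL_ROI_ROLES):
            for b in MESIAL_ROI_ROLES[i + 1 :]:
                if a in self.roles and b in self.roles and (self.roles[a] & self.roles[b]):
                    raise ConfigurationError(f"roles {a!r} and {b!r} share label IDs")


# ---------------------------------------------------------------------------
# File I/O


def load_label_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI label image into a :class:`LabelVolume`.

    Floating-point data are accepted if every value is within 1e-6 of an
    integer (many tools save label maps as float).
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D volume, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise FormatError(f"volume {path} contains non-integer label values")
        data = rounded.astype(np.int32)
    return LabelVolume(labels=np.ascontiguousarray(data), affine=np.asarray(img.affine))


def save_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write a :class:`LabelVolume` as NIfTI (int32)."""
    img = nib.Nifti1Image(vol.labels.astype(np.int32), vol.affine)
    nib.save(img, str(path))


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as a 0/1 NIfTI image."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def load_role_map(path: str | Path) -> StructureRoleMap:
    """Read a YAML/JSON role-map document.

    Expected schema::

        side: left
        roles:
          amygdala: [3]
          hippocampus: [4]
          ...
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return role_map_from_dict(doc)


def role_map_from_dict(doc: Mapping) -> StructureRoleMap:
    if not isinstance(doc, Mapping) or "roles" not in doc or "side" not in doc:
        raise ConfigurationError("role map document needs 'side' and 'roles' keys")
    roles = {k: frozenset(np.atleast_1d(v).astype(int).tolist()) for k, v in doc["roles"].items()}
    return StructureRoleMap(roles=roles, side=str(doc["side"]))


def save_role_map(role_map: StructureRoleMap, path: str | Path) -> None:
    doc = {
        "side": role_map.side,
        "roles": {k: sorted(v) for k, v in role_map.roles.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# ROI extraction and measurement


def extract_mask(
    vol: LabelVolume, roles: Iterable[str], role_map: StructureRoleMap
) -> BinaryMask:
    """Binary mask of all voxels whose label belongs to any of the roles."""
    names = list(roles)
    if not names:
        raise ConfigurationError("at least one role is required")
    ids = role_map.labels_for(names)
    data = np.isin(vol.labels, sorted(ids))
    return BinaryMask(data=data, affine=vol.affine)


def centroid_mm(mask: BinaryMask) -> np.ndarray:
    """Mean world-mm coordinate of all true voxel centres."""
    idx = np.argwhere(mask.data)
    if idx.size == 0:
        raise GeometryError("centroid of an empty mask is undefined")
    return mask.world_from_voxel(idx.mean(axis=0))


def volume_mm3(mask: BinaryMask) -> float:
    """Mask volume: true-voxel count times the voxel volume."""
    return float(np.count_nonzero(mask.data)) * mask.voxel_volume
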