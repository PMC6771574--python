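"""Constraint-based search for LITT trajectories.

Three automated trajectory types are supported, differing in entry region
and in how the amygdala centroid is translated to form the target:

* ``centroid_T2`` — inferior occipital gyrus entry, amygdala centroid target.
* ``expert_T3``   — inferior occipital gyrus entry, centroid translated 3 mm
  anterior, 3 mm medial and 3 mm inferior (expert-consensus parameters).
* ``ml_T4``       — temporo-occipital junction entry, centroid translated
  3 mm anterior and 3 mm medial (machine-learning-derived parameters).

The target is fixed per method; the search enumerates candidate entry points
on the outer surface of the entry region, filters them by hard constraints
(length, drilling angle, ventricle avoidance, vessel/sulcal/brainstem
clearance) and ranks the survivors by ascending risk score, then descending
amygdala+hippocampus ablation percentage, then ascending length.  The whole
pipeline is deterministic: identical scene and configuration give identical
ranked output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .ablation import AblationParams, estimate_ablation
from .geometry import (
    DistanceField,
    SkullSurface,
    Trajectory,
    distance_field,
    drilling_angle,
    min_distance_along,
    segment_intersects,
)
from .io_models import (
    BinaryMask,
    ConfigurationError,
    GeometryError,
    LabelVolume,
    StructureRoleMap,
    centroid_mm,
    extract_mask,
)
from .risk import RiskParams, RiskProfile, risk_score

logger = logging.getLogger(__name__)

#: target parameterizations and the entry region each uses
TARGET_METHODS = ("centroid_T2", "expert_T3", "ml_T4")
ENTRY_ROLE_FOR_METHOD = {
    "centroid_T2": "entry_region_IOG",
    "expert_T3": "entry_region_IOG",
    "ml_T4": "entry_region_TOJ",
}
#: (anterior, medial, inferior) translation magnitudes in mm per method
TARGET_TRANSLATIONS = {
    "centroid_T2": (0.0, 0.0, 0.0),
    "expert_T3": (3.0, 3.0, 3.0),
    "ml_T4": (3.0, 3.0, 0.0),
}


@dataclass(frozen=True)
class TargetSpec:
    """Which amygdala-centroid translation defines the target point."""

    method: str = "centroid_T2"

    def __post_init__(self) -> None:
        if self.method not in TARGET_METHODS:
            raise ConfigurationError(
                f"method must be one of {TARGET_METHODS}, got {self.method!r}"
            )

    @property
    def translation_ami(self) -> tuple[float, float, float]:
        """(anterior, medial, inferior) translation in mm."""
        return TARGET_TRANSLATIONS[self.method]

    @property
    def entry_role(self) -> str:
        return ENTRY_ROLE_FOR_METHOD[self.method]


@dataclass(frozen=True)
class PlanningConstraints:
    """Hard constraints applied to every automated trajectory.

    Defaults follow standard LITT planning practice: trajectories no longer
    than 120 mm, drilling angle within 30 degrees of the skull normal, at
    least 3 mm clearance from vessels and sulci, at least 7 mm from the
    brainstem, and no ventricular transgression.
    """

    max_length: float = 120.0
    max_drill_angle: float = 30.0
    d_safe_critical: float = 3.0
    d_safe_sulci: float | None = None  # defaults to d_safe_critical
    d_min_brainstem: float = 7.0
    no_entry_roles: tuple[str, ...] = ("lateral_ventricle",)
    critical_roles: tuple[str, ...] = ("vessels", "sulci", "brainstem")
    risk: RiskParams = field(default_factory=RiskParams)
    ablation: AblationParams = field(default_factory=AblationParams)
    entry_stride: int = 2
    intersect_step: float = 0.5

    def __post_init__(self) -> None:
        if self.max_length <= 0 or self.d_safe_critical <= 0 or self.d_min_brainstem <= 0:
            raise ConfigurationError("all margins must be positive")
        if not (0.0 < self.max_drill_angle <= 90.0):
            raise ConfigurationError("max_drill_angle must be in (0, 90]")
        if self.entry_stride < 1:
            raise ConfigurationError("entry_stride must be >= 1")

    @property
    def sulci_margin(self) -> float:
        return self.d_safe_critical if self.d_safe_sulci is None else self.d_safe_sulci


def constraints_from_dict(doc: Mapping | None) -> "PlanningConstraints":
    """Build PlanningConstraints (with nested risk/ablation params) from a
    plain config dictionary, e.g. one parsed from YAML."""
    if not doc:
        return PlanningConstraints()
    doc = dict(doc)
    risk = RiskParams(**doc.pop("risk", {}))
    ablation = AblationParams(**doc.pop("ablation", {}))
    return PlanningConstraints(risk=risk, ablation=ablation, **doc)


@dataclass(frozen=True)
class Violation:
    """One failed hard constraint: its name, the measured value, the bound."""

    constraint: str
    measured: float
    limit: float


@dataclass(frozen=True)
class CandidatePlan:
    trajectory: Trajectory
    feasible: bool
    violations: tuple[Violation, ...]
    risk_profile: RiskProfile | None = None
    metrics: Mapping[str, float] | None = None
    entry_index: int = -1


@dataclass(frozen=True)
class Scene:
    """Role-resolved masks, distance fields and derived geometry for one
    hemisphere's planning problem."""

    volume: LabelVolume
    role_map: StructureRoleMap
    masks: Mapping[str, BinaryMask]
    vessel_field: DistanceField
    sulci_field: DistanceField
    brainstem_field: DistanceField
    roi_field: DistanceField  # union of the four mesial ROIs
    skull: SkullSurface
    mid_sagittal_x: float

    @property
    def side(self) -> str:
        return self.role_map.side

    @property
    def structures(self) -> dict[str, BinaryMask]:
        """The four mesial ROI masks reported in ablation estimates."""
        from .ablation import ABLATION_STRUCTURES

        return {s: self.masks[s] for s in ABLATION_STRUCTURES}


def build_scene(vol: LabelVolume, role_map: StructureRoleMap) -> Scene:
    """Resolve roles into masks and precompute every distance field."""
    role_map.validate_against(vol)
    masks = {role: extract_mask(vol, [role], role_map) for role in role_map.roles}
    roi_union_data = np.zeros(vol.shape, dtype=bool)
    for name in ("amygdala", "hippocampus", "entorhinal_cortex", "parahippocampal_gyrus"):
        roi_union_data |= masks[name].data
    roi_union = BinaryMask(roi_union_data, vol.affine)
    skull_mask = masks["skull_shell"]
    idx = np.argwhere(skull_mask.data)
    bbox_mid_ijk = (idx.min(axis=0) + idx.max(axis=0)) / 2.0
    mid_x = float(skull_mask.world_from_voxel(bbox_mid_ijk)[0])
    return Scene(
        volume=vol,
        role_map=role_map,
        masks=masks,
        vessel_field=distance_field(masks["vessels"]),
        sulci_field=distance_field(masks["sulci"]),
        brainstem_field=distance_field(masks["brainstem"]),
        roi_field=distance_field(roi_union),
        skull=SkullSurface(skull_mask),
        mid_sagittal_x=mid_x,
    )


def compute_target(
    amygdala: BinaryMask,
    spec: TargetSpec,
    side: str,
    mid_sagittal_x: float | None = None,
) -> np.ndarray:
    """Target point: amygdala centroid plus the method's translation.

    Axes are RAS: anterior is +y, inferior is -z.  Medial is toward the
    mid-sagittal plane, so +x for a left-hemisphere structure and -x for a
    right-hemisphere one; when ``mid_sagittal_x`` is supplied the sign is
    derived from the centroid's position relative to it, otherwise from
    ``side``.
    """
    c = centroid_mm(amygdala)
    anterior, medial, inferior = spec.translation_ami
    if mid_sagittal_x is not None:
        medial_sign = 1.0 if c[0] < mid_sagittal_x else -1.0
    else:
        medial_sign = 1.0 if side == "left" else -1.0
    return c + np.array([medial_sign * medial, anterior, -inferior])


def enumerate_entries(
    entry_mask: BinaryMask, skull: BinaryMask | SkullSurface, stride: int = 1
) -> np.ndarray:
    """World-mm centres of the entry region's outer-surface voxels.

    A region voxel is an outer-surface voxel if one of its six face
    neighbours lies outside the region and at least as close to the skull
    shell (i.e. toward the scalp).  Voxels are returned in lexicographic
    index order, subsampled by ``stride`` — fully deterministic.
    """
    if stride < 1:
        raise ConfigurationError("stride must be >= 1")
    data = entry_mask.data
    if not data.any():
        raise GeometryError("entry region mask is empty")
    surf = skull if isinstance(skull, SkullSurface) else SkullSurface(skull)
    idx = np.argwhere(data)
    shell = surf._shell_dist
    shape = np.asarray(data.shape)
    keep = np.zeros(len(idx), dtype=bool)
    here = shell[idx[:, 0], idx[:, 1], idx[:, 2]]
    for axis in range(3):
        for sign in (-1, 1):
            nb = idx.copy()
            nb[:, axis] += sign
            inside = (nb[:, axis] >= 0) & (nb[:, axis] < shape[axis])
            sel = np.where(inside)[0]
            n = nb[sel]
            outside_region = ~data[n[:, 0], n[:, 1], n[:, 2]]
            toward_scalp = shell[n[:, 0], n[:, 1], n[:, 2]] <= here[sel]
            keep[sel] |= outside_region & toward_scalp
    surface = idx[keep][::stride]
    if surface.size == 0:
        raise GeometryError("entry region has no outer-surface voxels")
    return entry_mask.world_from_voxel(surface)


def check_feasibility(
    traj: Trajectory, scene: Scene, constraints: PlanningConstraints
) -> list[Violation]:
    """Evaluate every hard constraint; return all violations, not just the first."""
    violations: list[Violation] = []

    length = traj.length
    if length > constraints.max_length:
        violations.append(Violation("max_length", length, constraints.max_length))

    normal = scene.skull.normals(traj.entry[None, :])[0]
    angle = drilling_angle(traj, normal)
    if angle > constraints.max_drill_angle:
        violations.append(Violation("max_drill_angle", angle, constraints.max_drill_angle))
    elif abs(angle - constraints.max_drill_angle) < 1e-9:
        logger.warning("drilling angle exactly at the %.1f deg bound", constraints.max_drill_angle)

    for role in constraints.no_entry_roles:
        if role not in scene.masks:
            raise ConfigurationError(f"scene has no mask for no-entry role {role!r}")
        if segment_intersects(scene.masks[role], traj, step=constraints.intersect_step):
            violations.append(Violation(f"no_entry:{role}", 0.0, 0.0))

    n = constraints.risk.n_nodes
    margins = {
        "vessels": (scene.vessel_field, constraints.d_safe_critical),
        "sulci": (scene.sulci_field, constraints.sulci_margin),
        "brainstem": (scene.brainstem_field, constraints.d_min_brainstem),
    }
    for role in constraints.critical_roles:
        if role not in margins:
            raise ConfigurationError(f"no distance field for critical role {role!r}")
        fld, margin = margins[role]
        d = min_distance_along(traj, fld, n=n)
        if d < margin:
            name = "d_min_brainstem" if role == "brainstem" else f"d_safe:{role}"
            violations.append(Violation(name, d, margin))
    return violations


def measure_trajectory(
    scene: Scene,
    traj: Trajectory,
    constraints: PlanningConstraints,
) -> tuple[dict[str, float], RiskProfile, list[Violation]]:
    """Full metric record for one trajectory (shared by planner and reports)."""
    violations = check_feasibility(traj, scene, constraints)
    normal = scene.skull.normals(traj.entry[None, :])[0]
    profile = risk_score(traj, scene.vessel_field, constraints.risk)
    metrics: dict[str, float] = {
        "length_mm": traj.length,
        "drilling_angle_deg": drilling_angle(traj, normal),
        "risk_score": profile.score,
        "brainstem_distance_mm": min_distance_along(
            traj, scene.brainstem_field, n=constraints.risk.n_nodes
        ),
    }
    try:
        est = estimate_ablation(
            traj,
            scene.roi_field,
            scene.structures,
            scene.volume.affine,
            scene.volume.shape,
            constraints.ablation,
        )
        metrics["ablation_length_mm"] = est.ablation_length
        metrics["ablation_volume_mm3"] = est.total_volume
        for name, pct in est.overlap_percents.items():
            metrics[f"percent_{name}"] = pct
    except GeometryError:
        metrics["ablation_length_mm"] = float("nan")
        metrics["ablation_volume_mm3"] = float("nan")
        for name in scene.structures:
            metrics[f"percent_{name}"] = float("nan")
    return metrics, profile, violations


def plan(
    scene: Scene,
    constraints: PlanningConstraints = PlanningConstraints(),
    spec: TargetSpec = TargetSpec(),
    k: int = 10,
) -> list[CandidatePlan]:
    """Rank the top-``k`` feasible trajectories for one target method.

    Returns an empty list (not an error) when no entry yields a feasible
    trajectory.
    """
    target = compute_target(
        scene.masks["amygdala"], spec, scene.side, scene.mid_sagittal_x
    )
    entry_mask = scene.masks.get(spec.entry_role)
    if entry_mask is None:
        raise ConfigurationError(f"scene has no mask for entry role {spec.entry_role!r}")
    entries = enumerate_entries(entry_mask, scene.skull, stride=constraints.entry_stride)
    logger.info("planning %s: %d candidate entries", spec.method, len(entries))

    feasible: list[CandidatePlan] = []
    for i, entry in enumerate(entries):
        try:
            traj = Trajectory(entry, target)
        except GeometryError:
            continue
        violations = check_feasibility(traj, scene, constraints)
        if violations:
            continue
        metrics, profile, _ = measure_trajectory(scene, traj, constraints)
        feasible.append(
            CandidatePlan(
                trajectory=traj,
                feasible=True,
                violations=(),
                risk_profile=profile,
                metrics=metrics,
                entry_index=i,
            )
        )

    def sort_key(c: CandidatePlan):
        m = c.metrics
        abl = m.get("percent_amygdala", 0.0) + m.get("percent_hippocampus", 0.0)
        if not np.isfinite(abl):
            abl = 0.0
        return (m["risk_score"], -abl, m["length_mm"], c.entry_index)

    feasible.sort(key=sort_key)
    return feasible[:k]
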