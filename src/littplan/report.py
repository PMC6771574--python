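"""Per-trajectory metric records and simple between-method comparisons.

One :class:`MetricsRecord` per (case, method) mirrors the summary tables a
planning study reports: trajectory length, drilling angle, risk score,
brainstem clearance, ablation length and volume, and percentage ablation of
each mesial temporal structure.  :func:`compare_methods` provides a one-way
ANOVA with Bonferroni-corrected pairwise comparisons as convenience
reporting.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import Trajectory
from .io_models import GeometryError, ParameterError
from .planner import CandidatePlan, PlanningConstraints, Scene, Violation, measure_trajectory

#: canonical method labels, manual first
METHOD_LABELS = ("manual_1", "centroid_2", "expert_3", "ml_4")

_NUMERIC_FIELDS = (
    "length_mm",
    "drilling_angle_deg",
    "risk_score",
    "brainstem_distance_mm",
    "ablation_length_mm",
    "ablation_volume_mm3",
    "percent_amygdala",
    "percent_hippocampus",
    "percent_entorhinal_cortex",
    "percent_parahippocampal_gyrus",
)


@dataclass(frozen=True)
class MetricsRecord:
    case: str
    method: str
    length_mm: float
    drilling_angle_deg: float
    risk_score: float
    brainstem_distance_mm: float
    ablation_length_mm: float
    ablation_volume_mm3: float
    percent_amygdala: float
    percent_hippocampus: float
    percent_entorhinal_cortex: float
    percent_parahippocampal_gyrus: float
    violations: tuple[Violation, ...] = field(default=(), compare=False)

    def to_row(self) -> dict:
        row = asdict(self)
        row["violations"] = ";".join(
            f"{v.constraint}={v.measured:.6g}" for v in self.violations
        )
        return row


def evaluate_trajectory(
    scene: Scene,
    entry: np.ndarray,
    target: np.ndarray,
    constraints: PlanningConstraints = PlanningConstraints(),
    case: str = "",
    method: str = "manual_1",
) -> MetricsRecord:
    """Metric record for a user-supplied entry/target pair (world mm).

    Uses exactly the operations the automated planner uses, so a record for
    a planner-produced entry/target reproduces the planner's stored metrics
    bit for bit.  Hard-constraint violations are reported on the record but
    are not fatal — manually planned trajectories may violate them.
    """
    target = np.asarray(target, dtype=float).reshape(3)
    ijk = scene.volume.voxel_from_world(target)
    if np.any(ijk < -0.5) or np.any(ijk > np.asarray(scene.volume.shape) - 0.5):
        raise ParameterError(f"target {target} lies outside the image grid")
    traj = Trajectory(entry, target)  # raises GeometryError when degenerate
    metrics, _, violations = measure_trajectory(scene, traj, constraints)
    return MetricsRecord(
        case=case,
        method=method,
        violations=tuple(violations),
        **{f: float(metrics[f]) for f in _NUMERIC_FIELDS},
    )


def record_from_plan(plan: CandidatePlan, case: str = "", method: str = "centroid_2") -> MetricsRecord:
    """Wrap a planner candidate's stored metrics into a MetricsRecord."""
    m = plan.metrics or {}
    return MetricsRecord(
        case=case,
        method=method,
        violations=plan.violations,
        **{f: float(m.get(f, float("nan"))) for f in _NUMERIC_FIELDS},
    )


def records_to_dataframe(records: Iterable[MetricsRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records])


def dataframe_to_records(df: pd.DataFrame) -> list[MetricsRecord]:
    out = []
    for _, row in df.iterrows():
        out.append(
            MetricsRecord(
                case=str(row["case"]),
                method=str(row["method"]),
                **{f: float(row[f]) for f in _NUMERIC_FIELDS},
            )
        )
    return out


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_difference: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class ComparisonSummary:
    metric: str
    group_stats: dict  # label -> {"n": int, "mean": float, "sd": float}
    anova_f: float
    anova_p: float
    pairwise: tuple[PairwiseComparison, ...]


def compare_methods(records: Sequence[MetricsRecord], metric: str) -> ComparisonSummary:
    """Group means +/- SD, one-way ANOVA, Bonferroni pairwise comparisons.

    Bonferroni adjustment is p_adj = min(1, m * p) with m the number of
    pairs.  Degenerate zero-variance groups are handled explicitly: equal
    means give p = 1, unequal means with zero variance give p = 0.
    """
    if metric not in _NUMERIC_FIELDS:
        raise ParameterError(f"unknown metric {metric!r}")
    groups: dict[str, list[float]] = {}
    for r in records:
        groups.setdefault(r.method, []).append(float(getattr(r, metric)))
    if len(groups) < 2:
        raise ParameterError("need at least two methods to compare")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ParameterError(f"method {label!r} has fewer than 2 cases")

    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    stats_out = {
        k: {"n": int(v.size), "mean": float(v.mean()), "sd": float(v.std(ddof=1))}
        for k, v in arrays.items()
    }

    values = list(arrays.values())
    means = np.array([v.mean() for v in values])
    within_var = sum(float(((v - v.mean()) ** 2).sum()) for v in values)
    if within_var <= 0.0:
        anova_f, anova_p = (0.0, 1.0) if np.allclose(means, means[0]) else (float("inf"), 0.0)
    else:
        f, p = stats.f_oneway(*values)
        anova_f, anova_p = float(f), float(p)

    labels = sorted(arrays)
    pairs = list(combinations(labels, 2))
    m = len(pairs)
    pairwise = []
    for a, b in pairs:
        va, vb = arrays[a], arrays[b]
        diff = float(va.mean() - vb.mean())
        pooled = float(((va - va.mean()) ** 2).sum() + ((vb - vb.mean()) ** 2).sum())
        if pooled <= 0.0:
            p_raw = 1.0 if abs(diff) < 1e-300 else 0.0
        else:
            _, p_raw = stats.ttest_ind(va, vb)
            p_raw = float(p_raw)
        pairwise.append(
            PairwiseComparison(a, b, diff, p_raw, min(1.0, m * p_raw))
        )
    return ComparisonSummary(
        metric=metric,
        group_stats=stats_out,
        anova_f=anova_f,
        anova_p=anova_p,
        pairwise=tuple(pairwise),
    )
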