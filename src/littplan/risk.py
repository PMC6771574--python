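"""Avascular-corridor risk score.

The risk score summarizes the size of the avascular corridor around a
trajectory.  A fixed number of nodes (128 by default) is placed equally
spaced along the path and the distance from each node to the nearest
segmented vessel is read off a Euclidean distance field.  Each distance d is
mapped to a unitless per-node risk

    r(d) = (d_max - min(d, d_max)) / (d_max - d_safe)

which is 0 at and beyond the outer radius d_max, exactly 1 at the safety
margin d_safe, and rises linearly above 1 as the vessel distance falls below
the margin.  The aggregate score is the mean over nodes, so trajectories of
different lengths are directly comparable: the node count never grows with
length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import DistanceField, Trajectory, sample_nodes
from .io_models import ParameterError


@dataclass(frozen=True)
class RiskParams:
    """Parameters of the vessel-distance risk model.

    n_nodes: nodes sampled along the trajectory (fixed regardless of length).
    d_safe: safety margin in mm; a node closer than this scores above 1.
    d_max: outer radius in mm beyond which a vessel contributes zero risk.
    aggregation: 'mean' (default) or 'max' over the per-node risks.
    """

    n_nodes: int = 128
    d_safe: float = 3.0
    d_max: float = 10.0
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ParameterError("n_nodes must be >= 2")
        if not (0.0 < self.d_safe < self.d_max):
            raise ParameterError("need 0 < d_safe < d_max")
        if self.aggregation not in ("mean", "max"):
            raise ParameterError("aggregation must be 'mean' or 'max'")


@dataclass(frozen=True)
class RiskProfile:
    """Per-node vessel distances and risks, plus the aggregate score."""

    node_distances: np.ndarray
    node_risks: np.ndarray
    score: float
    params: RiskParams = field(default_factory=RiskParams)

    def to_json(self) -> str:
        return json.dumps(
            {
                "node_distances_mm": np.asarray(self.node_distances).tolist(),
                "node_risks": np.asarray(self.node_risks).tolist(),
                "score": self.score,
                "params": {
                    "n_nodes": self.params.n_nodes,
                    "d_safe_mm": self.params.d_safe,
                    "d_max_mm": self.params.d_max,
                    "aggregation": self.params.aggregation,
                },
            }
        )


def node_risk(d: float | np.ndarray, params: RiskParams = RiskParams()) -> float | np.ndarray:
    """Per-node risk of a vessel distance ``d`` (mm); see module docstring."""
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ParameterError("distances must be non-negative")
    r = (params.d_max - np.minimum(arr, params.d_max)) / (params.d_max - params.d_safe)
    return float(r) if np.isscalar(d) or arr.ndim == 0 else r


def risk_score(
    traj: Trajectory, vessels: DistanceField, params: RiskParams = RiskParams()
) -> RiskProfile:
    """Risk profile of a trajectory against a vessel distance field."""
    nodes = sample_nodes(traj, params.n_nodes)
    distances = vessels.query(nodes)
    risks = node_risk(distances, params)
    agg = np.mean if params.aggregation == "mean" else np.max
    return RiskProfile(
        node_distances=distances,
        node_risks=np.asarray(risks),
        score=float(agg(risks)),
        params=params,
    )
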