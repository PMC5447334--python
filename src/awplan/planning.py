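"""Probe pose planning: hard constraints, transmission maximisation, baselines.

A pose candidate for target P_t is a surface point s satisfying two hard
constraints: the target must be within penetration depth (|P_t - s| < d_y)
and the probe may tilt at most alpha away from the inward surface normal
(<d_a, -n_s> >= cos alpha, with d_a = (P_t - s)/|P_t - s|), which keeps the
target in the image plane and maintains acoustic coupling with the skin.

The planner then maximises the mean transmission t_bar over candidates and
the roll angle phi about d_a, in two stages that are together equivalent to
the exhaustive joint argmax over the (candidate x roll-grid) product set:
the roll grid covers [0, 180) degrees (the image plane is pi-periodic in
roll).  Multi-view plans share one base point admissible for every target
and maximise the product of per-target best transmissions.  Ties are broken
deterministically: lowest surface-point index, then smallest roll.

The naive baseline ignores internal anatomy: it picks the surface point
nearest the target, aims the axial axis at the target and keys the roll to
the surface normal (single view) or to an input trajectory direction
(multi view, parallel image planes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .probe import ProbeGeometry, ProbePose, pose_from, pose_from_frame
from .surface import SurfacePointCloud
from .transmission import (
    DEFAULT_NU,
    AttenuationField,
    mean_transmission,
    mean_transmission_batch,
)

__all__ = [
    "PlannerConfig",
    "CandidateSet",
    "PlanResult",
    "NoAcousticWindowError",
    "candidate_surface_points",
    "plan_single_view",
    "plan_multi_view",
    "plan_naive_single",
    "plan_naive_multi",
]

log = logging.getLogger(__name__)


class NoAcousticWindowError(RuntimeError):
    """No surface point satisfies the hard constraints; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class PlannerConfig:
    """Planner parameters.

    alpha_deg
        Maximum angle between the probe axis and the inward surface normal,
        degrees (acoustic-coupling constraint).
    angle_step_deg
        Roll-grid step over [0, 180); must divide 180.
    ray_step_mm
        Depth sampling step along scan-lines; ``None`` means half the
        minimum voxel spacing of the attenuation field.
    nu
        Log-compression factor.
    reference_up
        World direction defining roll = 0 (default: patient superior axis).
    """

    alpha_deg: float = 30.0
    angle_step_deg: float = 5.0
    ray_step_mm: float | None = None
    nu: float = DEFAULT_NU
    reference_up: tuple[float, float, float] = (0.0, 0.0, 1.0)
    skip_lead_in_air: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha_deg < 90:
            raise ValueError("alpha_deg must be in (0, 90)")
        if not np.isclose(180.0 / self.angle_step_deg, round(180.0 / self.angle_step_deg)):
            raise ValueError("angle_step_deg must divide 180")

    def roll_grid(self) -> np.ndarray:
        return np.deg2rad(np.arange(0.0, 180.0, self.angle_step_deg))

    def step_for(self, field: AttenuationField) -> float:
        if self.ray_step_mm is not None:
            return float(self.ray_step_mm)
        return float(field.volume.spacing.min() / 2.0)


@dataclass
class CandidateSet:
    """Constraint-satisfying surface points for one target (sorted by index)."""

    surface: SurfacePointCloud
    indices: np.ndarray  # indices into surface, ascending
    distances_mm: np.ndarray
    normal_angles_deg: np.ndarray
    target: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def points(self) -> np.ndarray:
        return self.surface.points[self.indices]


@dataclass
class PlanResult:
    """Planned pose(s) with scores and per-candidate diagnostics."""

    method: str  # "ours" | "naive"
    poses: list[ProbePose]
    targets: np.ndarray  # (n_t, 3)
    scores: np.ndarray  # per-pose t_bar (nan if not evaluated)
    candidates: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["target_idx", "surface_index", "x_mm", "y_mm", "z_mm", "best_phi_deg", "t_bar"]
        )
    )
    score_log_sum: float | None = None  # multi-view objective (sum of log t_bar)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "score_log_sum": self.score_log_sum,
            "poses": [
                {
                    "target": np.asarray(self.targets[i]).tolist(),
                    "base_point": p.base_point.tolist(),
                    "rotation": p.rotation.ravel().tolist(),
                    "phi_deg": float(np.rad2deg(p.phi)),
                    "t_bar": None if np.isnan(self.scores[i]) else float(self.scores[i]),
                }
                for i, p in enumerate(self.poses)
            ],
        }


def candidate_surface_points(
    surface: SurfacePointCloud,
    target: np.ndarray,
    geometry: ProbeGeometry,
    config: PlannerConfig,
) -> CandidateSet:
    """Surface points admissible for ``target`` under the hard constraints."""
    if len(surface) == 0:
        raise NoAcousticWindowError("surface is empty")
    target = np.asarray(target, dtype=float)
    diff = target - surface.points
    dist = np.linalg.norm(diff, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_a = diff / dist[:, None]
    cos_in = -np.einsum("ij,ij->i", d_a, surface.normals)  # <d_a, -n_s>
    cos_in = np.clip(cos_in, -1.0, 1.0)
    ok = (dist < geometry.depth_mm) & (cos_in >= np.cos(np.deg2rad(config.alpha_deg))) & (dist > 0)
    idx = np.nonzero(ok)[0]
    angles = np.rad2deg(np.arccos(cos_in))
    if len(idx) == 0:
        raise NoAcousticWindowError(
            "no admissible acoustic window for target "
            f"{np.round(target, 1).tolist()} "
            f"(min distance {dist.min():.1f} mm vs depth {geometry.depth_mm} mm; "
            f"min normal angle {np.nanmin(angles):.1f} deg vs alpha {config.alpha_deg} deg)",
            diagnostics={
                "min_distance_mm": float(dist.min()),
                "min_normal_angle_deg": float(np.nanmin(angles)),
            },
        )
    return CandidateSet(surface, idx, dist[idx], angles[idx], target)


def _grid_scores(
    field: AttenuationField,
    geometry: ProbeGeometry,
    candidates: CandidateSet,
    config: PlannerConfig,
) -> np.ndarray:
    """t_bar on the full (candidate x roll) grid, shape (n_cand, n_roll)."""
    rolls = config.roll_grid()
    pts = candidates.points
    rots = np.empty((len(pts), len(rolls), 3, 3))
    for i, s in enumerate(pts):
        for j, phi in enumerate(rolls):
            rots[i, j] = pose_from(s, candidates.target, phi, config.reference_up).rotation
    bases = np.repeat(pts, len(rolls), axis=0)
    tbar = mean_transmission_batch(
        field,
        geometry,
        rots.reshape(-1, 3, 3),
        bases,
        config.step_for(field),
        config.nu,
        config.skip_lead_in_air,
    )
    return tbar.reshape(len(pts), len(rolls))


def _diagnostics_frame(candidates: CandidateSet, tbar: np.ndarray, rolls: np.ndarray, target_idx: int) -> pd.DataFrame:
    best_j = np.argmax(tbar, axis=1)
    pts = candidates.points
    return pd.DataFrame(
        {
            "target_idx": target_idx,
            "surface_index": candidates.indices,
            "x_mm": pts[:, 0],
            "y_mm": pts[:, 1],
            "z_mm": pts[:, 2],
            "best_phi_deg": np.rad2deg(rolls[best_j]),
            "t_bar": tbar[np.arange(len(pts)), best_j],
        }
    )


def plan_single_view(
    field: AttenuationField,
    surface: SurfacePointCloud,
    target: np.ndarray,
    geometry: ProbeGeometry,
    config: PlannerConfig | None = None,
) -> PlanResult:
    """Best single-view pose: argmax of t_bar over (candidates x roll grid).

    Stage 1 keeps the best roll per candidate, stage 2 the best candidate;
    with the exhaustive roll grid this equals the joint argmax.  Ties break
    to the lowest surface index, then the smallest roll.
    """
    config = config or PlannerConfig()
    target = np.asarray(target, dtype=float)
    cands = candidate_surface_points(surface, target, geometry, config)
    rolls = config.roll_grid()
    tbar = _grid_scores(field, geometry, cands, config)
    best_j = np.argmax(tbar, axis=1)  # first max -> smallest roll
    best_val = tbar[np.arange(len(cands)), best_j]
    best_i = int(np.argmax(best_val))  # first max -> lowest surface index
    pose = pose_from(cands.points[best_i], target, float(rolls[best_j[best_i]]), config.reference_up)
    log.info(
        "single-view plan: %d candidates, best t_bar %.4f at surface index %d, phi %.1f deg",
        len(cands), best_val[best_i], cands.indices[best_i], np.rad2deg(rolls[best_j[best_i]]),
    )
    return PlanResult(
        method="ours",
        poses=[pose],
        targets=target[None, :],
        scores=np.array([best_val[best_i]]),
        candidates=_diagnostics_frame(cands, tbar, rolls, 0),
    )


def plan_multi_view(
    field: AttenuationField,
    surface: SurfacePointCloud,
    targets: np.ndarray,
    geometry: ProbeGeometry,
    config: PlannerConfig | None = None,
) -> PlanResult:
    """Best shared-base-point multi-view plan.

    The base point must be admissible for *every* target; given the base
    point the product objective factorises, so each target's roll is
    optimised independently and the base point maximising the sum of log
    per-target best transmissions is returned.  Equals the brute-force joint
    argmax over (common candidates x roll-grid^N_t).
    """
    config = config or PlannerConfig()
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    per_target = []
    counts = []
    for t in targets:
        try:
            c = candidate_surface_points(surface, t, geometry, config)
        except NoAcousticWindowError:
            c = None
        per_target.append(c)
        counts.append(0 if c is None else len(c))
    if any(c is None for c in per_target):
        raise NoAcousticWindowError(
            f"no common acoustic window: per-target candidate counts {counts}"
        )
    common = per_target[0].indices
    for c in per_target[1:]:
        common = np.intersect1d(common, c.indices)
    if len(common) == 0:
        raise NoAcousticWindowError(
            f"no common acoustic window: per-target candidate counts {counts}"
        )

    rolls = config.roll_grid()
    n_t = len(targets)
    best_phi = np.empty((len(common), n_t))
    best_val = np.empty((len(common), n_t))
    frames = []
    for i, t in enumerate(targets):
        cset = CandidateSet(
            surface,
            common,
            np.linalg.norm(t - surface.points[common], axis=1),
            np.zeros(len(common)),
            t,
        )
        tbar = _grid_scores(field, geometry, cset, config)
        j = np.argmax(tbar, axis=1)
        best_phi[:, i] = rolls[j]
        best_val[:, i] = tbar[np.arange(len(common)), j]
        frames.append(_diagnostics_frame(cset, tbar, rolls, i))

    with np.errstate(divide="ignore"):
        obj = np.sum(np.log(best_val), axis=1)  # -inf where any t_bar == 0
    best_s = int(np.argmax(obj))
    poses = [
        pose_from(surface.points[common[best_s]], t, float(best_phi[best_s, i]), config.reference_up)
        for i, t in enumerate(targets)
    ]
    log.info(
        "multi-view plan: %d common candidates for %d targets, objective %.4f",
        len(common), n_t, obj[best_s],
    )
    return PlanResult(
        method="ours",
        poses=poses,
        targets=targets,
        scores=best_val[best_s].copy(),
        candidates=pd.concat(frames, ignore_index=True),
        score_log_sum=float(obj[best_s]),
    )


def _naive_frame(surface: SurfacePointCloud, target: np.ndarray, reference_up) -> tuple[int, np.ndarray, np.ndarray]:
    target = np.asarray(target, dtype=float)
    dist = np.linalg.norm(target - surface.points, axis=1)
    i = int(np.argmin(dist))  # first min -> lowest index on ties
    s = surface.points[i]
    d_a = (target - s) / np.linalg.norm(target - s)
    return i, s, d_a


def _phi_of(pose: ProbePose, target: np.ndarray, reference_up) -> float:
    """Roll of ``pose`` relative to the phi = 0 frame for the same axis, in [0, pi)."""
    ref = pose_from(pose.base_point, target, 0.0, reference_up)
    c = float(pose.lateral @ ref.lateral)
    s = float(pose.lateral @ ref.elevational)
    return float(np.mod(np.arctan2(s, c), np.pi))


def plan_naive_single(
    surface: SurfacePointCloud,
    target: np.ndarray,
    geometry: ProbeGeometry,
    field: AttenuationField | None = None,
    config: PlannerConfig | None = None,
) -> PlanResult:
    """Naive baseline: nearest surface point, axis to target, roll from the
    surface normal (d_l = n x d_a).  No transmission is used to *choose* the
    pose; when an attenuation field is supplied the pose's t_bar is still
    reported for comparison."""
    config = config or PlannerConfig()
    target = np.asarray(target, dtype=float)
    i, s, d_a = _naive_frame(surface, target, config.reference_up)
    n_s = surface.normals[i]
    d_l = np.cross(n_s, d_a)
    if np.linalg.norm(d_l) < 1e-8:
        log.info("surface normal parallel to probe axis at naive base; using reference-up roll")
        pose = pose_from(s, target, 0.0, config.reference_up)
    else:
        pose = pose_from_frame(s, d_a, d_l)
    pose = ProbePose(pose.rotation, pose.base_point, phi=_phi_of(pose, target, config.reference_up))
    score = np.nan
    if field is not None:
        score = mean_transmission(
            field, geometry, pose, config.step_for(field), config.nu, config.skip_lead_in_air
        ).mean
    return PlanResult(
        method="naive",
        poses=[pose],
        targets=target[None, :],
        scores=np.array([score]),
    )


def plan_naive_multi(
    surface: SurfacePointCloud,
    targets: np.ndarray,
    geometry: ProbeGeometry,
    trajectory_direction: np.ndarray | None = None,
    field: AttenuationField | None = None,
    config: PlannerConfig | None = None,
) -> PlanResult:
    """Naive multi-view baseline: per-target nearest base point and target-
    aimed axis, with the elevational axis set to the rejection of the
    trajectory direction d_T from d_a (parallel image planes).

    ``trajectory_direction`` defaults to the first-to-last target direction.
    """
    config = config or PlannerConfig()
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if trajectory_direction is None:
        d_T = targets[-1] - targets[0]
        if np.linalg.norm(d_T) < 1e-12:
            raise ValueError("cannot infer a trajectory direction from coincident targets")
    else:
        d_T = np.asarray(trajectory_direction, dtype=float)
    d_T = d_T / np.linalg.norm(d_T)

    poses = []
    scores = []
    for k, t in enumerate(targets):
        _, s, d_a = _naive_frame(surface, t, config.reference_up)
        rej = d_T - d_a * (d_a @ d_T)
        nrm = np.linalg.norm(rej)
        if nrm < 1e-9:
            raise DegenerateRejectionError(
                f"trajectory direction parallel to the probe axis for target {k}"
            )
        d_e = rej / nrm
        d_l = np.cross(d_e, d_a)
        pose = ProbePose(np.column_stack([d_l, d_e, d_a]), s)
        pose = ProbePose(pose.rotation, pose.base_point, phi=_phi_of(pose, t, config.reference_up))
        poses.append(pose)
        if field is not None:
            scores.append(
                mean_transmission(
                    field, geometry, pose, config.step_for(field), config.nu, config.skip_lead_in_air
                ).mean
            )
        else:
            scores.append(np.nan)
    return PlanResult(method="naive", poses=poses, targets=targets, scores=np.asarray(scores))


class DegenerateRejectionError(ValueError):
    """Trajectory direction parallel to a probe axis: no elevational axis."""
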