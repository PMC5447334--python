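"""Curvilinear probe geometry and pose algebra.

Probe-frame convention: +z axial (into tissue), +x lateral, +y elevational.
The physical curved array has its central element at the probe-frame origin;
element i sits on an arc of radius ``array_radius`` whose centre is at
(0, 0, -array_radius), at angle theta_i from the axial axis, and fires along
the outward radial direction (sin theta_i, 0, cos theta_i).  Scan-lines are
confined to the axial-lateral plane (2D image model); volumetric sweeps are
sequences of such planes.

A pose is a rigid transform (R, s): rotation from probe frame to world plus
a base surface point.  Poses are built from a base point, a target point
(fixing the axial axis d_a), and a roll angle phi about d_a.  phi = 0 is
keyed to a world "up" reference so results are reproducible; the image plane
is invariant under phi -> phi + pi, so phi lives in [0, pi).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProbeGeometry",
    "ProbePose",
    "DegeneratePoseError",
    "scanlines",
    "pose_from",
    "fan_points",
    "rotation_about_axis",
]

log = logging.getLogger(__name__)

#: Planning defaults for a 4DC7-3/40-class curvilinear transducer
#: (140 mm depth); 64 planning scan-lines subsample the physical 128.
DEFAULT_N_ELEMENTS = 64
DEFAULT_ARRAY_RADIUS_MM = 40.0
DEFAULT_FOV_DEG = 70.0
DEFAULT_DEPTH_MM = 140.0


class DegeneratePoseError(ValueError):
    pass


@dataclass(frozen=True)
class ProbeGeometry:
    """Curvilinear array description.

    Parameters
    ----------
    n_elements
        Number of planning scan-lines (>= 1).
    array_radius_mm
        Radius of curvature of the array, mm.
    fov_deg
        Total angular aperture, degrees; must be positive unless a single
        scan-line is requested.
    depth_mm
        Penetration depth d_y, mm.
    """

    n_elements: int = DEFAULT_N_ELEMENTS
    array_radius_mm: float = DEFAULT_ARRAY_RADIUS_MM
    fov_deg: float = DEFAULT_FOV_DEG
    depth_mm: float = DEFAULT_DEPTH_MM
    name: str = "curvilinear"

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise ValueError("n_elements must be >= 1")
        if self.array_radius_mm <= 0 or self.depth_mm <= 0:
            raise ValueError("array radius and depth must be positive")
        if self.n_elements == 1:
            if self.fov_deg < 0:
                raise ValueError("fov_deg must be >= 0")
        elif not 0 < self.fov_deg < 180:
            raise ValueError("fov_deg must be in (0, 180) for a multi-element array")

    @classmethod
    def from_dict(cls, d: dict) -> "ProbeGeometry":
        return cls(
            n_elements=int(d.get("n_elements", DEFAULT_N_ELEMENTS)),
            array_radius_mm=float(d.get("array_radius_mm", DEFAULT_ARRAY_RADIUS_MM)),
            fov_deg=float(d.get("fov_deg", DEFAULT_FOV_DEG)),
            depth_mm=float(d.get("depth_mm", DEFAULT_DEPTH_MM)),
            name=str(d.get("name", "curvilinear")),
        )


@dataclass(frozen=True)
class ProbePose:
    """Rigid probe pose: rotation (probe frame -> world) and base point (mm)."""

    rotation: np.ndarray
    base_point: np.ndarray
    phi: float = 0.0  # roll about d_a used to construct the pose, radians

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "base_point", np.asarray(self.base_point, dtype=float))
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-9
        ):
            raise ValueError("rotation must be orthonormal with determinant +1")

    @property
    def lateral(self) -> np.ndarray:
        return self.rotation[:, 0]

    @property
    def elevational(self) -> np.ndarray:
        return self.rotation[:, 1]

    @property
    def axial(self) -> np.ndarray:
        return self.rotation[:, 2]


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    k = axis / np.linalg.norm(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def scanlines(geometry: ProbeGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Scan-line origins b_i and unit directions v_i in the probe frame.

    Element angles are uniform over [-fov/2, +fov/2]; the central element of
    an odd-count array sits exactly at the frame origin with direction
    (0, 0, 1).  All origins have zero elevational (y) coordinate.
    """
    n = geometry.n_elements
    if n == 1:
        theta = np.zeros(1)
    else:
        half = np.deg2rad(geometry.fov_deg) / 2.0
        theta = np.linspace(-half, half, n)
    r = geometry.array_radius_mm
    dirs = np.column_stack([np.sin(theta), np.zeros_like(theta), np.cos(theta)])
    origins = r * dirs + np.array([0.0, 0.0, -r])
    return origins, dirs


def pose_from(
    base: np.ndarray,
    target: np.ndarray,
    roll: float = 0.0,
    reference_up: np.ndarray = (0.0, 0.0, 1.0),
) -> ProbePose:
    """Construct a pose whose axial axis points from ``base`` to ``target``.

    At roll = 0 the lateral axis is the normalised rejection of
    ``reference_up`` from d_a; a general roll applies the axis-angle
    rotation about d_a.  If the reference is (numerically) parallel to d_a
    the next world axis is used instead, deterministically.
    """
    base = np.asarray(base, dtype=float)
    target = np.asarray(target, dtype=float)
    d = target - base
    dist = np.linalg.norm(d)
    if dist < 1e-12:
        raise DegeneratePoseError("target coincides with the base point")
    d_a = d / dist

    up = np.asarray(reference_up, dtype=float)
    lat = up - d_a * (d_a @ up)
    if np.linalg.norm(lat) < 1e-8:
        for axis in (np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0])):
            lat = axis - d_a * (d_a @ axis)
            if np.linalg.norm(lat) >= 1e-8:
                log.debug("reference up parallel to axial axis; fell back to %s", axis)
                break
    d_l = lat / np.linalg.norm(lat)
    if abs(roll) > 1e-15:
        d_l = rotation_about_axis(d_a, roll) @ d_l
    d_e = np.cross(d_a, d_l)
    R = np.column_stack([d_l, d_e, d_a])
    # re-orthonormalise against accumulated rounding
    u, _, vt = np.linalg.svd(R)
    return ProbePose(u @ vt, base, phi=float(roll))


def pose_from_frame(base: np.ndarray, d_a: np.ndarray, d_l: np.ndarray, phi: float = 0.0) -> ProbePose:
    """Pose from explicit axial and lateral axes (used by the naive planner)."""
    d_a = np.asarray(d_a, dtype=float)
    d_l = np.asarray(d_l, dtype=float)
    d_a = d_a / np.linalg.norm(d_a)
    d_l = d_l - d_a * (d_a @ d_l)
    d_l = d_l / np.linalg.norm(d_l)
    d_e = np.cross(d_a, d_l)
    return ProbePose(np.column_stack([d_l, d_e, d_a]), base, phi=phi)


def fan_points(
    geometry: ProbeGeometry, pose: ProbePose, samples_per_line: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World sample points over the imaging fan.

    Returns ``(points, line_index, depth_mm)`` where ``points`` has shape
    ``(n_elements, samples_per_line, 3)`` and depths run uniformly over
    [0, depth_mm] inclusive along each scan-line.
    """
    if samples_per_line < 2:
        raise ValueError("need at least 2 samples per scan-line")
    origins, dirs = scanlines(geometry)
    depths = np.linspace(0.0, geometry.depth_mm, samples_per_line)
    pts_probe = origins[:, None, :] + depths[None, :, None] * dirs[:, None, :]
    pts = pts_probe @ pose.rotation.T + pose.base_point
    line_idx = np.broadcast_to(np.arange(geometry.n_elements)[:, None], pts.shape[:2])
    return pts, line_idx, np.broadcast_to(depths, pts.shape[:2])
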