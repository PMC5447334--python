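"""Acoustic-window quality evaluation of planned poses on CT.

A planned pose is scored by resampling the CT on the oblique plane of the
ultrasound image (spanned by the lateral and axial axes, through the base
point) and restricting to the curvilinear fan region the probe would
actually insonify.  Two ratios are computed over the n in-fan pixels:

* ``r_ct``  — fraction of pixels outside the soft-tissue HU band
  [beta1, beta2] (defaults -100 and 150 HU).  Bone and air impair
  transmission, so lower is better.
* ``r_seg`` — fraction of pixels inside the target-organ segmentation;
  higher means more anatomical context of the target in the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .probe import ProbeGeometry, ProbePose
from .volume import CtVolume, LabelVolume, sample_nearest, sample_trilinear

__all__ = [
    "PoseSlice",
    "EvaluationReport",
    "EvaluationError",
    "extract_pose_slice",
    "ratio_non_soft_tissue",
    "ratio_segmentation",
    "compare_plans",
]

DEFAULT_BETA1_HU = -100.0
DEFAULT_BETA2_HU = 150.0


class EvaluationError(RuntimeError):
    pass


@dataclass
class PoseSlice:
    """CT resampled on the image plane of a pose, with the fan mask."""

    pixels: np.ndarray  # (n_v, n_u) HU, rows = depth v, cols = lateral u
    fan_mask: np.ndarray  # (n_v, n_u) bool
    pixel_spacing_mm: float
    u_coords_mm: np.ndarray  # (n_u,) lateral offsets
    v_coords_mm: np.ndarray  # (n_v,) depths
    world_points: np.ndarray  # (n_v, n_u, 3)

    @property
    def n(self) -> int:
        return int(self.fan_mask.sum())


@dataclass
class EvaluationReport:
    """Per-pose quality rows and per-method aggregates."""

    rows: pd.DataFrame  # method, target_idx, r_ct, r_seg, t_bar, phi_deg
    beta1: float
    beta2: float

    def aggregates(self) -> dict:
        out = {}
        for method, grp in self.rows.groupby("method", sort=True):
            out[method] = {
                "r_ct_mean": float(grp["r_ct"].mean()),
                "r_ct_sd": float(grp["r_ct"].std(ddof=0)),
                "r_seg_mean": float(grp["r_seg"].mean()),
                "r_seg_sd": float(grp["r_seg"].std(ddof=0)),
            }
        return out


def _fan_test(u: np.ndarray, v: np.ndarray, geometry: ProbeGeometry) -> np.ndarray:
    """Curvilinear-sector membership for image-plane coords (u lateral, v axial).

    The fan is the set of points at radial distance [R, R + d_y] from the
    array's centre of curvature (at v = -R on the axial axis), within the
    angular aperture.
    """
    R = geometry.array_radius_mm
    rho = np.sqrt(u**2 + (v + R) ** 2)
    theta = np.abs(np.arctan2(u, v + R))
    half = np.deg2rad(geometry.fov_deg) / 2.0
    return (rho >= R) & (rho <= R + geometry.depth_mm) & (theta <= half)


def extract_pose_slice(
    volume: CtVolume,
    pose: ProbePose,
    geometry: ProbeGeometry,
    pixel_spacing_mm: float | None = None,
) -> PoseSlice:
    """Resample ``volume`` on the image plane of ``pose``.

    Pixel (u, v) maps to ``base + u * d_l + v * d_a`` with v in [0, d_y] and
    u spanning the widest fan row; HU by trilinear sampling (outside reads
    as air), fan mask by the curvilinear sector test.
    """
    if pixel_spacing_mm is None:
        pixel_spacing_mm = float(volume.spacing.min())
    R = geometry.array_radius_mm
    u_max = (R + geometry.depth_mm) * np.sin(np.deg2rad(geometry.fov_deg) / 2.0)
    u = np.arange(-u_max, u_max + pixel_spacing_mm / 2, pixel_spacing_mm)
    v = np.arange(0.0, geometry.depth_mm + pixel_spacing_mm / 2, pixel_spacing_mm)
    U, V = np.meshgrid(u, v)  # (n_v, n_u)
    world = (
        pose.base_point[None, None, :]
        + U[..., None] * pose.lateral[None, None, :]
        + V[..., None] * pose.axial[None, None, :]
    )
    pixels = sample_trilinear(volume, world)
    mask = _fan_test(U, V, geometry)
    if not mask.any():
        raise EvaluationError("empty fan mask (degenerate geometry)")
    return PoseSlice(pixels, mask, float(pixel_spacing_mm), u, v, world)


def ratio_non_soft_tissue(
    slc: PoseSlice, beta1: float = DEFAULT_BETA1_HU, beta2: float = DEFAULT_BETA2_HU
) -> float:
    """Fraction of in-fan pixels with HU < beta1 or HU > beta2."""
    if beta1 >= beta2:
        raise ValueError("beta1 must be less than beta2")
    if slc.n == 0:
        raise EvaluationError("empty fan")
    hu = slc.pixels[slc.fan_mask]
    return float(np.count_nonzero((hu < beta1) | (hu > beta2)) / slc.n)


def ratio_segmentation(slc: PoseSlice, labels: LabelVolume, organ_label: int = 1) -> float:
    """Fraction of in-fan pixels inside the organ segmentation.

    The label volume is sampled nearest-neighbour at the identical pixel
    grid (labels are categorical)."""
    if labels.label_map and organ_label not in labels.label_map:
        raise ValueError(f"label {organ_label} not in label map {labels.label_map}")
    if slc.n == 0:
        raise EvaluationError("empty fan")
    lab = sample_nearest(labels, slc.world_points)
    return float(np.count_nonzero(lab[slc.fan_mask] == organ_label) / slc.n)


def compare_plans(
    volume: CtVolume,
    labels: LabelVolume | None,
    plans: list,
    geometry: ProbeGeometry,
    beta1: float = DEFAULT_BETA1_HU,
    beta2: float = DEFAULT_BETA2_HU,
    pixel_spacing_mm: float | None = None,
    organ_label: int = 1,
) -> EvaluationReport:
    """Evaluate every pose of every plan; aggregate mean and SD per method."""
    if not plans:
        raise ValueError("need at least one plan")
    records = []
    for plan in plans:
        for i, pose in enumerate(plan.poses):
            slc = extract_pose_slice(volume, pose, geometry, pixel_spacing_mm)
            r_ct = ratio_non_soft_tissue(slc, beta1, beta2)
            r_seg = (
                ratio_segmentation(slc, labels, organ_label) if labels is not None else np.nan
            )
            records.append(
                {
                    "method": plan.method,
                    "target_idx": i,
                    "r_ct": r_ct,
                    "r_seg": r_seg,
                    "t_bar": float(plan.scores[i]),
                    "phi_deg": float(np.rad2deg(pose.phi)),
                }
            )
    return EvaluationReport(pd.DataFrame.from_records(records), beta1, beta2)
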