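"""Patient-surface extraction: body mask, surface points and outward normals.

The planner searches over a discrete set of skin points with outward unit
normals.  The surface is taken as the 0.5 iso-surface of a Gaussian-smoothed
(sigma = 1 voxel) body mask via marching cubes, with vertex normals from the
smoothed-field gradient, sign-fixed to point away from the body.  Vertices
are then subsampled approximately uniformly by voxel-grid binning to a
requested areal density, which bounds the candidate-set size (planning cost
is linear in the number of surface points).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import (
    binary_dilation,
    binary_erosion,
    gaussian_filter,
    generate_binary_structure,
    label as cc_label,
    map_coordinates,
)
from skimage.measure import marching_cubes

from .volume import CtVolume

__all__ = [
    "SurfacePointCloud",
    "SurfaceExtractionError",
    "extract_body_mask",
    "extract_surface_points",
    "write_ply",
]

DEFAULT_SKIN_THRESHOLD_HU = -300.0
DEFAULT_DENSITY_PER_MM2 = 0.25


class SurfaceExtractionError(RuntimeError):
    pass


@dataclass
class SurfacePointCloud:
    """Discrete body surface: world points (mm) with outward unit normals."""

    points: np.ndarray  # (n, 3) mm
    normals: np.ndarray  # (n, 3) unit, outward
    source_spacing: np.ndarray  # (3,) mm of the source grid

    def __len__(self) -> int:
        return len(self.points)


def extract_body_mask(volume: CtVolume, threshold_hu: float = DEFAULT_SKIN_THRESHOLD_HU) -> np.ndarray:
    """Binary body mask: largest connected component of ``HU > threshold``,
    morphologically closed (1-voxel radius) to remove skin holes."""
    raw = volume.values > threshold_hu
    if not raw.any():
        raise SurfaceExtractionError(f"no body found at threshold {threshold_hu} HU")
    struct = generate_binary_structure(3, 1)
    labeled, n = cc_label(raw, structure=struct)
    if n > 1:
        sizes = np.bincount(labeled.ravel())
        sizes[0] = 0
        raw = labeled == int(np.argmax(sizes))
    # closing = dilation then erosion; erode with border_value=1 so that a
    # body touching the volume boundary is not trimmed at the faces
    closed = binary_dilation(raw, structure=struct)
    return binary_erosion(closed, structure=struct, border_value=1)


def _subsample_grid(points: np.ndarray, pitch_mm: float) -> np.ndarray:
    """Keep one point per occupied 3D cell of size ``pitch_mm`` (the point
    nearest the cell centroid; ties by lowest index).  Returns kept indices
    in ascending order."""
    cells = np.floor(points / pitch_mm).astype(np.int64)
    # lexicographic cell key
    order = np.lexsort((cells[:, 2], cells[:, 1], cells[:, 0]))
    sc = cells[order]
    boundaries = np.any(np.diff(sc, axis=0) != 0, axis=1)
    starts = np.concatenate([[0], np.nonzero(boundaries)[0] + 1, [len(sc)]])
    keep = []
    for s, e in zip(starts[:-1], starts[1:]):
        grp = order[s:e]
        centroid = points[grp].mean(axis=0)
        d = np.linalg.norm(points[grp] - centroid, axis=1)
        keep.append(grp[np.lexsort((grp, d))[0]])
    return np.sort(np.asarray(keep))


def extract_surface_points(
    mask: np.ndarray,
    volume: CtVolume,
    density_per_mm2: float = DEFAULT_DENSITY_PER_MM2,
) -> SurfacePointCloud:
    """Extract surface points and outward normals from a binary body mask.

    Parameters
    ----------
    mask
        Binary body mask on the grid of ``volume``.
    volume
        Supplies the world geometry (spacing, origin, direction).
    density_per_mm2
        Target areal point density; subsampling pitch is ``1/sqrt(density)``.
    """
    if mask.sum() < 2:
        raise SurfaceExtractionError("mask is degenerate (fewer than 2 voxels)")
    smoothed = gaussian_filter(mask.astype(np.float32), sigma=1.0)
    if not (smoothed.min() < 0.5 < smoothed.max()):
        raise SurfaceExtractionError("mask has no 0.5 iso-surface after smoothing")
    verts, _, _, _ = marching_cubes(smoothed, level=0.5)
    # outward normal = -gradient of the smoothed occupancy (high inside)
    grads = np.stack(np.gradient(smoothed), axis=-1)
    normals = -np.stack(
        [map_coordinates(grads[..., d], verts.T, order=1) for d in range(3)], axis=-1
    )
    norm = np.linalg.norm(normals, axis=1)
    ok = norm > 1e-8
    verts, normals, norm = verts[ok], normals[ok], norm[ok]
    normals /= norm[:, None]

    # voxel index space -> world (normals transform by direction only; the
    # per-axis spacing scaling of the gradient preserves outwardness but not
    # direction under anisotropy, so rescale then renormalise)
    spacing = volume.spacing
    points_w = volume.index_to_world(verts)
    normals_w = (normals / spacing) @ volume.direction.T
    normals_w /= np.linalg.norm(normals_w, axis=1)[:, None]

    # subsample in grid-attached physical coordinates so that rigidly moving
    # the volume moves the selected points with it (equivariance)
    pitch = float(1.0 / np.sqrt(density_per_mm2))
    keep = _subsample_grid(verts * spacing, pitch)
    return SurfacePointCloud(points_w[keep], normals_w[keep], spacing.copy())


def write_ply(
    cloud: SurfacePointCloud,
    path: str | Path,
    scalars: np.ndarray | None = None,
    scalar_name: str = "quality",
) -> None:
    """Write the cloud as ASCII PLY (with normals, optional per-point scalar)."""
    n = len(cloud)
    header = [
        "ply",
        "format ascii 1.0",
        f"element vertex {n}",
        "property float x",
        "property float y",
        "property float z",
        "property float nx",
        "property float ny",
        "property float nz",
    ]
    cols = [cloud.points, cloud.normals]
    if scalars is not None:
        header.append(f"property float {scalar_name}")
        cols.append(np.asarray(scalars, dtype=float).reshape(-1, 1))
    header.append("end_header")
    data = np.hstack(cols)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, data, fmt="%.6f")
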