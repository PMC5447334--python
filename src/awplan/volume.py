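"""CT and label volumes with world geometry and interpolation.

Volumes are stored with array axes in ``(x, y, z)`` index order; a voxel's
world position refers to its *centre*, in millimetres:

    world = origin + direction @ (spacing * index)

``direction`` is an orthonormal, right-handed 3x3 matrix whose columns are
the world directions of the voxel axes.  This matches the geometry model of
NIfTI and MetaImage headers as exposed by SimpleITK.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

__all__ = [
    "CtVolume",
    "LabelVolume",
    "GeometryError",
    "read_volume",
    "read_label_volume",
    "write_volume",
    "sample_trilinear",
    "sample_nearest",
]

log = logging.getLogger(__name__)

HU_MIN = -1024.0
HU_MAX = 4000.0

#: HU value assumed for points outside the volume (air).
OUTSIDE_HU = -1024.0


class GeometryError(ValueError):
    """Raised for invalid volume geometry (dimensionality, direction matrix)."""


def _check_direction(direction: np.ndarray) -> None:
    if direction.shape != (3, 3):
        raise GeometryError("direction must be a 3x3 matrix")
    if not np.allclose(direction.T @ direction, np.eye(3), atol=1e-6):
        raise GeometryError("direction matrix is not orthonormal")
    if np.linalg.det(direction) < 0:
        raise GeometryError("direction matrix is not right-handed")


@dataclass
class CtVolume:
    """A 3D CT volume in Hounsfield units with world geometry."""

    values: np.ndarray  # (nx, ny, nz) float32, HU
    spacing: np.ndarray  # (3,) mm, > 0
    origin: np.ndarray  # (3,) mm, world position of voxel (0,0,0) centre
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise GeometryError(
                f"expected a 3D volume, got {self.values.ndim} dimensions"
            )
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if np.any(self.spacing <= 0):
            raise GeometryError("spacing must be strictly positive")
        _check_direction(self.direction)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices (..., 3) to world mm."""
        index = np.asarray(index, dtype=float)
        return self.origin + (index * self.spacing) @ self.direction.T

    def world_to_index(self, point: np.ndarray) -> np.ndarray:
        """Map world points (..., 3) to continuous voxel indices."""
        point = np.asarray(point, dtype=float)
        return ((point - self.origin) @ self.direction) / self.spacing

    def same_grid(self, other: "CtVolume | LabelVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin, atol=1e-3)
            and np.allclose(self.direction, other.direction, atol=1e-6)
        )


@dataclass
class LabelVolume(CtVolume):
    """Integer organ-label volume co-registered with a :class:`CtVolume`.

    Label 0 is reserved for background.
    """

    label_map: dict[int, str] = field(default_factory=dict)


def _from_sitk(img: sitk.Image, clamp: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if img.GetDimension() != 3:
        raise GeometryError(
            f"expected a 3D image, got {img.GetDimension()} dimensions"
        )
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # (z,y,x) -> (x,y,z)
    spacing = np.array(img.GetSpacing(), dtype=float)
    origin = np.array(img.GetOrigin(), dtype=float)
    direction = np.array(img.GetDirection(), dtype=float).reshape(3, 3)
    _check_direction(direction)
    if clamp:
        arr = arr.astype(np.float32)
        n_out = int(np.count_nonzero((arr < HU_MIN) | (arr > HU_MAX)))
        if n_out:
            log.info("clamped %d voxels outside [%g, %g] HU", n_out, HU_MIN, HU_MAX)
        arr = np.clip(arr, HU_MIN, HU_MAX)
        if not np.all(np.isfinite(arr)):
            raise ValueError("volume contains non-finite values")
    return arr, spacing, origin, direction


def read_volume(path: str | Path) -> CtVolume:
    """Read a 3D NIfTI or MetaImage scalar volume as a :class:`CtVolume`.

    Intensities are passed through unchanged except clamping to the plausible
    HU range [-1024, 4000] (the number of clamped voxels is logged).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps all reader failures
        raise IOError(f"could not read volume {path}: {exc}") from exc
    arr, spacing, origin, direction = _from_sitk(img, clamp=True)
    return CtVolume(arr, spacing, origin, direction)


def read_label_volume(path: str | Path, label_map: dict[int, str] | None = None) -> LabelVolume:
    """Read an integer label volume (no HU clamping, dtype preserved)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"label file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise IOError(f"could not read labels {path}: {exc}") from exc
    arr, spacing, origin, direction = _from_sitk(img, clamp=False)
    if not np.issubdtype(arr.dtype, np.integer):
        arr = np.rint(arr).astype(np.int32)
    return LabelVolume(arr, spacing, origin, direction, label_map or {})


def write_volume(volume: CtVolume, path: str | Path) -> None:
    """Write a volume to NIfTI (.nii/.nii.gz) or MetaImage (.mhd/.mha).

    The file re-reads to an identical grid and geometry; integer label
    volumes keep an integer dtype on disk.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"output directory does not exist: {path.parent}")
    arr = volume.values
    if isinstance(volume, LabelVolume):
        arr = arr.astype(np.int16, copy=False)
    else:
        arr = arr.astype(np.float32, copy=False)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    img.SetDirection(tuple(volume.direction.ravel()))
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:
        raise IOError(f"could not write volume {path}: {exc}") from exc


def sample_trilinear(
    volume: CtVolume,
    points: np.ndarray,
    outside_value: float = OUTSIDE_HU,
) -> np.ndarray:
    """Trilinearly interpolate ``volume`` at world points (..., 3).

    Points outside the grid return ``outside_value`` (default -1024 HU, air);
    rays legitimately start at the skin and fans may clip the volume
    boundary, and air maps to near-total reflection downstream.
    """
    points = np.asarray(points, dtype=float)
    idx = volume.world_to_index(points.reshape(-1, 3))
    out = map_coordinates(
        volume.values.astype(np.float64, copy=False),
        idx.T,
        order=1,
        mode="constant",
        cval=outside_value,
    )
    return out.reshape(points.shape[:-1])


def sample_nearest(
    volume: CtVolume,
    points: np.ndarray,
    outside_value: float = 0,
) -> np.ndarray:
    """Nearest-neighbour sampling, for categorical label volumes."""
    points = np.asarray(points, dtype=float)
    idx = volume.world_to_index(points.reshape(-1, 3))
    out = map_coordinates(
        volume.values, idx.T, order=0, mode="constant", cval=outside_value
    )
    return out.reshape(points.shape[:-1])
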