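"""Synthetic torso-like CT phantoms with rib arcs and a labeled target organ.

The generator produces the structure an acoustic-window planner must
exploit: an air background, a soft-tissue elliptic-cylinder body, a set of
bone-density rib arcs near the anterior surface, and a liver-like ellipsoid
inclusion behind them.  The intercostal gaps between ribs are the acoustic
windows; a planner that ignores internal anatomy will happily image through
a rib, one that models transmission will not.

Default HU palette: air -1000, soft body 40, organ 60, ribs 900, Gaussian
noise sigma 10 HU.  These place soft tissue inside the [-100, 150] HU band
conventionally separating soft from hard tissue, with bone far above it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

from .volume import CtVolume, LabelVolume

__all__ = [
    "PhantomConfig",
    "PhantomConfigError",
    "generate_phantom",
    "generate_two_layer_slab",
]

ORGAN_LABEL = 1


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration violates its invariants."""


@dataclass
class PhantomConfig:
    """Parameters of the synthetic torso phantom.

    The body is an elliptic cylinder along z, centred at the world origin.
    Anterior is +y.  Ribs are arc segments of the (shrunken) body ellipse in
    axial planes, spaced along z with a configurable intercostal gap.
    """

    volume_shape: tuple[int, int, int] = (96, 96, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    # body
    body_half_axes_mm: tuple[float, float] = (80.0, 62.0)
    body_hu: float = 40.0
    # organ (liver-like ellipsoid)
    organ_center_mm: tuple[float, float, float] = (0.0, 12.0, 0.0)
    organ_half_axes_mm: tuple[float, float, float] = (46.0, 30.0, 42.0)
    organ_hu: float = 60.0
    # ribs
    rib_count: int = 5
    rib_radius_mm: float = 4.0
    rib_gap_mm: float = 14.0
    rib_arc_deg: float = 130.0
    rib_inset_mm: float = 8.0
    rib_hu: float = 900.0
    # background and noise
    background_hu: float = -1000.0
    noise_sigma_hu: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        a, b = self.body_half_axes_mm
        cx, cy, cz = self.organ_center_mm
        oa, ob, oc = self.organ_half_axes_mm
        ext = np.asarray(self.volume_shape) * np.asarray(self.spacing_mm)
        if self.rib_gap_mm <= 0:
            raise PhantomConfigError("intercostal gap must be positive")
        if self.rib_count and self.rib_hu <= 300:
            raise PhantomConfigError("rib HU must exceed 300 (bone density)")
        for hu in (self.body_hu, self.organ_hu):
            if not -100 <= hu <= 150:
                raise PhantomConfigError("body/organ HU must be soft tissue (-100..150)")
        # organ strictly inside the body ellipse (x-y) and the z extent
        if (abs(cx) + oa) >= a or (abs(cy) + ob) >= b or (abs(cz) + oc) >= ext[2] / 2:
            raise PhantomConfigError("organ ellipsoid must lie strictly inside the body")
        if a >= ext[0] / 2 or b >= ext[1] / 2:
            raise PhantomConfigError("body ellipse must fit inside the volume")


def _world_grid(shape, spacing):
    """Voxel-centre world coordinates for a volume centred at the origin."""
    shape = np.asarray(shape)
    spacing = np.asarray(spacing, dtype=float)
    origin = -(shape - 1) * spacing / 2.0
    ax = [origin[d] + spacing[d] * np.arange(shape[d]) for d in range(3)]
    return origin, np.meshgrid(*ax, indexing="ij")


def _rib_mask(cfg: PhantomConfig, X, Y, Z) -> np.ndarray:
    """Voxels within ``rib_radius_mm`` of any rib arc centreline."""
    a, b = cfg.body_half_axes_mm
    ar, br = a - cfg.rib_inset_mm, b - cfg.rib_inset_mm
    half_arc = np.deg2rad(cfg.rib_arc_deg) / 2.0
    # arcs centred on the anterior (+y) direction; ellipse angle measured from +y
    theta = np.linspace(-half_arc, half_arc, 361)
    period = 2 * cfg.rib_radius_mm + cfg.rib_gap_mm
    z0 = -(cfg.rib_count - 1) * period / 2.0
    pts = []
    for j in range(cfg.rib_count):
        zj = z0 + j * period
        pts.append(
            np.column_stack(
                [ar * np.sin(theta), br * np.cos(theta), np.full_like(theta, zj)]
            )
        )
    if not pts:
        return np.zeros(X.shape, dtype=bool)
    tree = cKDTree(np.concatenate(pts))
    # restrict the query to a bounding shell around the rib band
    vox = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    d, _ = tree.query(vox, workers=-1)
    return (d.reshape(X.shape) <= cfg.rib_radius_mm)


def generate_phantom(
    config: PhantomConfig | None = None, n_targets: int = 5
) -> tuple[CtVolume, LabelVolume, np.ndarray]:
    """Build the phantom CT, its organ label volume, and target points.

    Returns ``(ct, labels, targets)`` where ``targets`` is an ``(n_targets, 3)``
    array of world points (mm) drawn uniformly from organ voxels after a
    2-voxel erosion margin (boundary targets have ambiguous coverage).
    The result is fully determined by ``config.seed``.
    """
    cfg = config or PhantomConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    origin, (X, Y, Z) = _world_grid(cfg.volume_shape, cfg.spacing_mm)
    a, b = cfg.body_half_axes_mm
    body = (X / a) ** 2 + (Y / b) ** 2 <= 1.0

    cx, cy, cz = cfg.organ_center_mm
    oa, ob, oc = cfg.organ_half_axes_mm
    organ = ((X - cx) / oa) ** 2 + ((Y - cy) / ob) ** 2 + ((Z - cz) / oc) ** 2 <= 1.0

    hu = np.full(X.shape, cfg.background_hu, dtype=np.float32)
    hu[body] = cfg.body_hu
    hu[organ] = cfg.organ_hu
    if cfg.rib_count:
        ribs = _rib_mask(cfg, X, Y, Z) & body & ~organ
        hu[ribs] = cfg.rib_hu
    if cfg.noise_sigma_hu > 0:
        hu = hu + rng.normal(0.0, cfg.noise_sigma_hu, size=hu.shape).astype(np.float32)

    spacing = np.asarray(cfg.spacing_mm, dtype=float)
    ct = CtVolume(hu.astype(np.float32), spacing, origin)
    labels = LabelVolume(
        organ.astype(np.int16) * ORGAN_LABEL,
        spacing,
        origin,
        label_map={ORGAN_LABEL: "organ"},
    )

    interior = binary_erosion(organ, iterations=2)
    idx = np.argwhere(interior)
    if len(idx) == 0:
        raise PhantomConfigError("organ too small to place targets after erosion")
    pick = rng.choice(len(idx), size=min(n_targets, len(idx)), replace=False)
    targets = ct.index_to_world(idx[pick].astype(float))
    return ct, labels, np.atleast_2d(targets)


def generate_two_layer_slab(
    hu_values: tuple[float, float],
    interface_depth_mm: float,
    shape: tuple[int, int, int] = (40, 40, 60),
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> CtVolume:
    """Axis-aligned two-layer slab: HU ``hu_values[0]`` for voxel centres with
    z < ``interface_depth_mm``, ``hu_values[1]`` beyond.

    The single sharp interface perpendicular to z has a closed-form
    transmission, which makes this the canonical fixture for checking the
    ray integrator against the two-impedance reflection formula.
    """
    shape = tuple(shape)
    spacing = np.asarray(spacing_mm, dtype=float)
    z = spacing[2] * np.arange(shape[2])
    col = np.where(z < interface_depth_mm, hu_values[0], hu_values[1]).astype(np.float32)
    values = np.broadcast_to(col, shape).copy()
    return CtVolume(values, spacing, origin=np.zeros(3))
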