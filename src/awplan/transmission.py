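"""Acoustic transmission estimation from CT along probe scan-lines.

The planner's quality metric is the mean log-compressed transmission t_bar
of an ultrasound pulse travelling from the probe into the tissue.  CT
Hounsfield units are mapped to an X-ray attenuation proxy mu, which is
approximately proportional to mass density and hence (at constant speed of
sound) to acoustic impedance; only impedance *ratios* enter, so the
proportionality constant cancels.

For a single interface between impedances Z1, Z2 the intensity transmission
coefficient is

    t(Z1, Z2) = 1 - ((Z2 - Z1) / (Z2 + Z1))^2,

and a ray crossing several interfaces accumulates

    t = exp(-sum_j r_j^2),    r_j = |mu_b - mu_a| / (mu_a + mu_b),

over the interfaces j it crosses, with exp(-r^2) ~= 1 - r^2 for the weak
reflections typical of soft tissue (the two agree to O(r^4)).  Interfaces
are detected on the sampled mu profile by coalescing consecutive
same-direction changes into a single transition evaluated from its endpoint
values, which makes one sharp interface contribute exactly r^2 regardless
of the sampling step (the discretisation is otherwise ill-posed at sharp
jumps).  A log-compression  t_hat = log(1 + nu t) / log(1 + nu)  mimics the
dynamic-range mapping of US imaging pipelines; nu defaults to 0.5.

Straight rays and a constant speed of sound are assumed: no refraction and
no frequency-dependent absorption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .probe import ProbeGeometry, ProbePose, scanlines
from .volume import CtVolume

__all__ = [
    "AttenuationField",
    "TransmissionResult",
    "hu_to_mu",
    "interface_transmission",
    "log_compress",
    "ray_transmission",
    "mean_transmission",
    "mean_transmission_batch",
    "surface_transmission_map",
]

DEFAULT_EPSILON = 1e-3
DEFAULT_NU = 0.5
#: mu below this is treated as not-yet-coupled lead-in (air in front of the
#: skin for lateral elements of the curved array); corresponds to -100 HU.
LEAD_IN_MU_THRESHOLD = 0.9
#: maximum gel-standoff distance: leading air within this many mm of the ray
#: origin is attributed to coupling gel (lateral elements of a 40 mm-radius
#: array sit up to ~7 mm off the skin); beyond it, air is real air.
LEAD_IN_MAX_MM = 12.0
#: attenuation proxy of the coupling gel (water-like) at the transducer face.
MU_GEL = 1.0


@dataclass
class AttenuationField:
    """X-ray attenuation proxy ``mu = max(1 + HU/1000, epsilon)`` on the CT grid."""

    mu: np.ndarray
    epsilon: float
    volume: CtVolume  # supplies world geometry

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear mu at world points; outside the grid reads as air (mu = epsilon)."""
        points = np.asarray(points, dtype=float)
        idx = self.volume.world_to_index(points.reshape(-1, 3))
        out = map_coordinates(
            self.mu, idx.T, order=1, mode="constant", cval=self.epsilon
        )
        return out.reshape(points.shape[:-1])


@dataclass
class TransmissionResult:
    """Per-scan-line log-compressed transmission profiles and their mean."""

    per_scanline: np.ndarray  # (n_lines, n_samples) t_hat in [0, 1]
    mean: float  # t_bar in [0, 1]
    pose: ProbePose


def hu_to_mu(volume: CtVolume, epsilon: float = DEFAULT_EPSILON) -> AttenuationField:
    """Map HU to the attenuation proxy, floored at ``epsilon`` (> 0).

    Water (0 HU) maps to 1, air (-1000 HU and below) to the floor; the floor
    keeps the reflection-ratio denominator positive and makes tissue/air
    interfaces reflect nearly totally, as they should.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    mu = np.maximum(1.0 + volume.values.astype(np.float64) / 1000.0, epsilon)
    return AttenuationField(mu, float(epsilon), volume)


def interface_transmission(z1: float, z2: float) -> float:
    """Intensity transmission through one interface: ``1 - ((z2-z1)/(z2+z1))^2``."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if np.any(z1 <= 0) or np.any(z2 <= 0):
        raise ValueError("impedances must be positive")
    r = (z2 - z1) / (z2 + z1)
    out = 1.0 - r**2
    return float(out) if out.ndim == 0 else out


def log_compress(t, nu: float = DEFAULT_NU):
    """Log-compression ``log(1 + nu t) / log(1 + nu)``; maps 0 -> 0, 1 -> 1."""
    if nu <= 0:
        raise ValueError("nu must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < -1e-12) or np.any(t > 1 + 1e-12):
        raise ValueError("t must lie in [0, 1]")
    out = np.log1p(nu * np.clip(t, 0.0, 1.0)) / np.log1p(nu)
    return float(out) if out.ndim == 0 else out


def _accumulate_exponent(
    mu: np.ndarray, skip_lead_in_air: bool, lead_max_samples: int | None = None
) -> np.ndarray:
    """Reflection exponent ``E_k = sum of r^2`` accumulated up to each sample.

    ``mu`` has shape (..., n_samples).  Consecutive same-direction changes
    are coalesced into one transition scored from its endpoints; an
    in-progress transition contributes its partial jump, so E is
    non-decreasing in depth.

    With ``skip_lead_in_air`` the coupling of the probe is modelled: leading
    samples below the tissue threshold are forward-filled from the first
    tissue sample when that entry lies within ``lead_max_samples`` of the
    origin (coupling gel fills the standoff of lateral array elements), and
    rays that are still in air beyond the standoff start from a virtual
    gel sample (mu = 1), charging the near-total gel/air reflection at the
    transducer face.
    """
    mu = np.asarray(mu, dtype=np.float64)
    if skip_lead_in_air:
        mu = mu.copy()
        if lead_max_samples is None:
            lead_max_samples = mu.shape[-1]
        in_tissue = mu >= LEAD_IN_MU_THRESHOLD
        any_tissue = in_tissue.any(axis=-1)
        first = np.argmax(in_tissue, axis=-1)
        coupled = any_tissue & (first <= lead_max_samples)
        k = np.arange(mu.shape[-1])
        lead = (k < first[..., None]) & coupled[..., None]
        fill = np.take_along_axis(mu, first[..., None], axis=-1)
        mu = np.where(lead, fill, mu)
        # uncoupled rays: insonify from gel into whatever the first sample is
        virt = np.where(
            mu[..., :1] < LEAD_IN_MU_THRESHOLD, MU_GEL, mu[..., :1]
        )
        mu = np.concatenate([virt, mu], axis=-1)
        E = _run_exponent(mu)[..., 1:]
        return E
    return _run_exponent(mu)


def _run_exponent(mu: np.ndarray) -> np.ndarray:
    n = mu.shape[-1]
    E = np.zeros(mu.shape, dtype=np.float64)
    closed = np.zeros(mu.shape[:-1], dtype=np.float64)  # sum over finished runs
    run_start = mu[..., 0].copy()
    run_sign = np.zeros(mu.shape[:-1], dtype=np.int8)  # 0 = no active run
    for k in range(1, n):
        prev = mu[..., k - 1]
        cur = mu[..., k]
        d = cur - prev
        sign = np.sign(d).astype(np.int8)
        # a direction flip or a flat step closes the active run
        close = (run_sign != 0) & (sign != run_sign)
        if close.any():
            r = (prev - run_start) / (prev + run_start)
            closed = np.where(close, closed + r**2, closed)
            run_start = np.where(close, prev, run_start)
            run_sign = np.where(close, 0, run_sign)
        opening = (run_sign == 0) & (sign != 0)
        run_sign = np.where(opening, sign, run_sign)
        r_part = (cur - run_start) / (cur + run_start)
        E[..., k] = closed + np.where(run_sign != 0, r_part**2, 0.0)
    return E


def ray_transmission(
    field: AttenuationField,
    origin: np.ndarray,
    direction: np.ndarray,
    depth_mm: float,
    step_mm: float,
    nu: float = DEFAULT_NU,
    skip_lead_in_air: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Transmission profile along one ray.

    Returns ``(depths_mm, t_raw, t_hat)``: cumulative raw transmission
    ``exp(-E)`` and its log-compressed counterpart at depths ``k * step_mm``
    up to ``depth_mm``.  Both profiles are non-increasing with depth and lie
    in [0, 1].
    """
    if step_mm <= 0:
        raise ValueError("step must be positive")
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    n = int(np.floor(depth_mm / step_mm)) + 1
    depths = step_mm * np.arange(n)
    pts = np.asarray(origin, dtype=float) + depths[:, None] * direction
    mu = field.sample(pts)
    lead = int(LEAD_IN_MAX_MM // step_mm)
    E = _accumulate_exponent(mu[None, :], skip_lead_in_air, lead)[0]
    t_raw = np.exp(-E)
    return depths, t_raw, log_compress(t_raw, nu)


def mean_transmission_batch(
    field: AttenuationField,
    geometry: ProbeGeometry,
    rotations: np.ndarray,
    base_points: np.ndarray,
    step_mm: float,
    nu: float = DEFAULT_NU,
    skip_lead_in_air: bool = True,
    chunk_size: int = 256,
) -> np.ndarray:
    """t_bar for many poses at once.

    ``rotations`` is (m, 3, 3), ``base_points`` (m, 3); returns (m,) means.
    This is the planner's hot path: all scan-lines and depth samples of a
    chunk of poses are interpolated in one call.
    """
    if step_mm <= 0:
        raise ValueError("step must be positive")
    rotations = np.asarray(rotations, dtype=float)
    base_points = np.asarray(base_points, dtype=float)
    m = len(rotations)
    origins, dirs = scanlines(geometry)  # (L, 3)
    n = int(np.floor(geometry.depth_mm / step_mm)) + 1
    depths = step_mm * np.arange(n)
    pts_probe = origins[:, None, :] + depths[None, :, None] * dirs[:, None, :]  # (L,n,3)
    out = np.empty(m, dtype=np.float64)
    lognu = np.log1p(nu)
    lead = int(LEAD_IN_MAX_MM // step_mm)
    for c0 in range(0, m, chunk_size):
        c1 = min(c0 + chunk_size, m)
        R = rotations[c0:c1]  # (c,3,3)
        # world points: (c, L, n, 3)
        pts = np.einsum("cij,lnj->clni", R, pts_probe) + base_points[c0:c1, None, None, :]
        mu = field.sample(pts)
        E = _accumulate_exponent(mu.reshape(-1, n), skip_lead_in_air, lead)
        t_hat = np.log1p(nu * np.exp(-E)) / lognu
        out[c0:c1] = t_hat.reshape(c1 - c0, -1).mean(axis=1)
    return out


def mean_transmission(
    field: AttenuationField,
    geometry: ProbeGeometry,
    pose: ProbePose,
    step_mm: float,
    nu: float = DEFAULT_NU,
    skip_lead_in_air: bool = True,
) -> TransmissionResult:
    """Mean log-compressed transmission t_bar over the whole imaging fan.

    The discrete form of the per-pose quality metric: t_hat averaged over
    all scan-lines and uniformly spaced depth samples in [0, d_y].
    """
    if step_mm <= 0:
        raise ValueError("step must be positive")
    origins, dirs = scanlines(geometry)
    n = int(np.floor(geometry.depth_mm / step_mm)) + 1
    depths = step_mm * np.arange(n)
    pts_probe = origins[:, None, :] + depths[None, :, None] * dirs[:, None, :]
    pts = pts_probe @ pose.rotation.T + pose.base_point
    mu = field.sample(pts)
    E = _accumulate_exponent(mu, skip_lead_in_air, int(LEAD_IN_MAX_MM // step_mm))
    t_hat = log_compress(np.exp(-E), nu)
    return TransmissionResult(t_hat, float(t_hat.mean()), pose)


def surface_transmission_map(
    field: AttenuationField,
    geometry: ProbeGeometry,
    surface_points: np.ndarray,
    target: np.ndarray,
    roll_grid_rad: np.ndarray,
    step_mm: float,
    nu: float = DEFAULT_NU,
    reference_up: np.ndarray = (0.0, 0.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Best-over-roll t_bar for each candidate surface point.

    Returns ``(best_tbar, best_roll_rad)`` arrays aligned with
    ``surface_points``; the per-point maximum of t_bar over the roll grid,
    ties resolved to the smallest roll.
    """
    from .probe import pose_from  # local import to avoid cycle at module load

    surface_points = np.atleast_2d(np.asarray(surface_points, dtype=float))
    if len(surface_points) == 0:
        raise ValueError("empty candidate set")
    rolls = np.asarray(roll_grid_rad, dtype=float)
    rots = []
    bases = []
    for s in surface_points:
        for phi in rolls:
            p = pose_from(s, target, phi, reference_up)
            rots.append(p.rotation)
            bases.append(s)
    tbar = mean_transmission_batch(
        field, geometry, np.asarray(rots), np.asarray(bases), step_mm, nu
    ).reshape(len(surface_points), len(rolls))
    best_j = np.argmax(tbar, axis=1)  # argmax takes the first (smallest roll) tie
    return tbar[np.arange(len(surface_points)), best_j], rolls[best_j]
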