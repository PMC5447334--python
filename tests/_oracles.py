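"""Independent oracles used by the test suite.

These deliberately avoid the library's optimised code paths: brute-force
enumeration, direct voxel ray-marching and closed-form hand evaluations.
"""

from __future__ import annotations

import numpy as np

BONE_HU = 300.0


def march_segment_hits_hu(ct, p0, p1, threshold_hu=BONE_HU, step_mm=0.25) -> bool:
    """Nearest-voxel march from p0 to p1: does any voxel exceed threshold?"""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = np.linalg.norm(p1 - p0)
    n = max(int(np.ceil(length / step_mm)), 2)
    pts = p0 + np.linspace(0, 1, n)[:, None] * (p1 - p0)
    idx = np.rint(ct.world_to_index(pts)).astype(int)
    shape = np.asarray(ct.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    if not inside.any():
        return False
    vals = ct.values[tuple(idx[inside].T)]
    return bool(np.any(vals > threshold_hu))


def brute_force_candidates(points, normals, target, depth_mm, alpha_deg):
    """Admissible surface indices by direct application of both predicates."""
    out = []
    target = np.asarray(target, dtype=float)
    for i, (s, n) in enumerate(zip(points, normals)):
        d = target - s
        dist = np.linalg.norm(d)
        if dist <= 0 or dist >= depth_mm:
            continue
        d_a = d / dist
        angle = np.degrees(np.arccos(np.clip(-d_a @ n, -1, 1)))
        if angle <= alpha_deg:
            out.append(i)
    return np.asarray(out, dtype=int)


def brute_force_single_view(field, candidates, target, geometry, config):
    """Joint argmax over (candidate x roll grid) by exhaustive loop.

    Returns (candidate position, roll index, best t_bar); ties resolved to
    the lowest candidate position, then the smallest roll, exactly the
    planner's documented order.
    """
    from awplan.probe import pose_from
    from awplan.transmission import mean_transmission

    rolls = config.roll_grid()
    best = (-1.0, None, None)
    step = config.step_for(field)
    for i, s in enumerate(candidates.points):
        for j, phi in enumerate(rolls):
            pose = pose_from(s, candidates.target, float(phi), config.reference_up)
            t = mean_transmission(field, geometry, pose, step, config.nu).mean
            if t > best[0]:
                best = (t, i, j)
    return best[1], best[2], best[0]


def brute_force_multi_view(field, surface, common_indices, targets, geometry, config):
    """Joint argmax over (shared base x roll^N_t); factorised per target only
    in the sense of iterating the full product implicitly: for each base the
    best roll per target is found by explicit scan, and bases are compared on
    the product objective."""
    from awplan.probe import pose_from
    from awplan.transmission import mean_transmission

    rolls = config.roll_grid()
    step = config.step_for(field)
    best = (-np.inf, None, None)
    for pos, si in enumerate(common_indices):
        s = surface.points[si]
        logsum = 0.0
        phis = []
        for t in targets:
            vals = [
                mean_transmission(
                    field, geometry, pose_from(s, t, float(phi), config.reference_up), step, config.nu
                ).mean
                for phi in rolls
            ]
            j = int(np.argmax(vals))
            phis.append(j)
            logsum += np.log(vals[j]) if vals[j] > 0 else -np.inf
        if logsum > best[0]:
            best = (logsum, pos, phis)
    return best[1], best[2], best[0]


def numeric_mean_transmission_slab(mu1, mu2, interface_mm, depth_mm, nu, n=20001):
    """Direct numeric integration of the mean compressed transmission for a
    perpendicular single-scan-line pass through a two-layer medium."""
    l = np.linspace(0, depth_mm, n)
    t_raw = np.where(l < interface_mm, 1.0, np.exp(-(((mu2 - mu1) / (mu1 + mu2)) ** 2)))
    t_hat = np.log1p(nu * t_raw) / np.log1p(nu)
    return t_hat.mean()
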