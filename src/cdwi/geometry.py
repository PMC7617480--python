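"""Local left-ventricular coordinate frames on short-axis slices.

Cardiac fiber metrics (helix angle, sheetlet angle) are defined relative to
a local orthonormal frame at each myocardial voxel: radial r̂ (endocardium →
epicardium), circumferential ĉ (counterclockwise in-plane) and longitudinal
ẑ (slice normal, apex → base).  On a short-axis slice the frame follows from
the slice's LV center; the transmural depth d ∈ [0, 1] is the normalized
position between the endocardial and epicardial boundary along the radial
ray through the voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GeometryError(ValueError):
    """Mask/center combination does not describe an annular myocardium."""


@dataclass
class LVGeometry:
    """Per-voxel local LV frame for one short-axis slice.

    Attributes
    ----------
    mask : (nx, ny) bool
        Myocardial voxels.
    center : (2,) float
        LV center in voxel coordinates.
    radial, circumferential, longitudinal : (nx, ny, 3) float
        Orthonormal frame vectors (zero outside the mask).
    depth : (nx, ny) float
        Transmural depth, 0 at the endocardial boundary, 1 at the epicardial
        boundary; NaN outside the mask.
    """

    mask: np.ndarray
    center: np.ndarray
    radial: np.ndarray
    circumferential: np.ndarray
    longitudinal: np.ndarray
    depth: np.ndarray


def local_coordinates(mask: np.ndarray, center,
                      slice_normal=(0.0, 0.0, 1.0),
                      n_rays: int = 720) -> LVGeometry:
    """Build the local LV frame for an annular short-axis myocardial mask.

    r̂ is the in-plane unit vector from the LV center, ĉ = ẑ × r̂, and the
    transmural depth interpolates linearly between the endocardial and
    epicardial mask crossings of the radial ray through each voxel (rays are
    traced at ``n_rays`` angles and interpolated azimuthally).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise GeometryError("mask must be a 2-D short-axis slice")
    if not mask.any():
        raise GeometryError("empty myocardial mask")
    center = np.asarray(center, dtype=float)
    ci, cj = center
    if mask[int(round(ci)), int(round(cj))]:
        raise GeometryError(
            "LV center lies inside the myocardium; mask is not annular")
    zhat = np.asarray(slice_normal, dtype=float)
    zhat = zhat / np.linalg.norm(zhat)

    ii, jj = np.meshgrid(np.arange(mask.shape[0]), np.arange(mask.shape[1]),
                         indexing="ij")
    dx = ii - ci
    dy = jj - cj
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(r > 0, dx / r, 0.0)
        uy = np.where(r > 0, dy / r, 0.0)

    radial = np.zeros(mask.shape + (3,))
    radial[..., 0] = ux
    radial[..., 1] = uy
    circ = np.cross(np.broadcast_to(zhat, mask.shape + (3,)), radial)
    longit = np.zeros_like(radial)
    longit[...] = zhat

    # ray-traced endo/epi radii per azimuth
    angles = np.linspace(-np.pi, np.pi, n_rays, endpoint=False)
    r_max = float(r[mask].max()) + 2.0
    r_samples = np.arange(0.0, r_max, 0.25)
    r_endo = np.full(n_rays, np.nan)
    r_epi = np.full(n_rays, np.nan)
    for k, a in enumerate(angles):
        pi_ = ci + r_samples * np.cos(a)
        pj = cj + r_samples * np.sin(a)
        valid = (pi_ >= 0) & (pi_ <= mask.shape[0] - 1) & \
                (pj >= 0) & (pj <= mask.shape[1] - 1)
        inside = np.zeros(len(r_samples), dtype=bool)
        inside[valid] = mask[np.round(pi_[valid]).astype(int),
                             np.round(pj[valid]).astype(int)]
        if not inside.any():
            continue
        hit = np.nonzero(inside)[0]
        r_endo[k] = r_samples[hit[0]]
        r_epi[k] = r_samples[hit[-1]]
    if np.isnan(r_endo).all():
        raise GeometryError("no myocardial ray crossings found")
    # fill azimuthal gaps by nearest neighbour (circular)
    for arr in (r_endo, r_epi):
        bad = np.isnan(arr)
        if bad.any():
            good = np.nonzero(~bad)[0]
            for k in np.nonzero(bad)[0]:
                d = np.minimum(np.abs(good - k), n_rays - np.abs(good - k))
                arr[k] = arr[good[np.argmin(d)]]

    # interpolate endo/epi radii azimuthally at each voxel's angle
    idx = (theta - angles[0]) / (2 * np.pi / n_rays)
    i0 = np.floor(idx).astype(int) % n_rays
    i1 = (i0 + 1) % n_rays
    frac = idx - np.floor(idx)
    endo_at = r_endo[i0] * (1 - frac) + r_endo[i1] * frac
    epi_at = r_epi[i0] * (1 - frac) + r_epi[i1] * frac
    with np.errstate(invalid="ignore", divide="ignore"):
        depth = (r - endo_at) / np.maximum(epi_at - endo_at, 1e-9)
    depth = np.clip(depth, 0.0, 1.0)
    depth[~mask] = np.nan

    radial[~mask] = 0.0
    circ[~mask] = 0.0
    longit[~mask] = 0.0
    return LVGeometry(mask=mask, center=center, radial=radial,
                      circumferential=circ, longitudinal=longit, depth=depth)
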