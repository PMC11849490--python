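"""Maximally stable extremal regions, enclosing ellipses, orientation profiles.

For a bright animal on a dark background, sweeping a gray threshold downward
yields nested connected components; those whose area is nearly constant over
a range of thresholds (MSERs) track stable parts of the animal, from the
brightest body segment up to the whole silhouette.  Each region is summarised
by the orientation of its minimal circumscribed ellipse.  Because the number
of detected regions varies frame to frame, orientations are resampled onto a
fixed grid of N query areas, then recentered by their circular mean so the
profile is invariant to rigid rotation of the animal.

Ellipse orientations are axial quantities (defined modulo pi); interpolation
and the circular mean are carried out on doubled angles by default to avoid
the wrap artifact at +-pi/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from ._mser_core import mser_sweep, mvee_weights

__all__ = [
    "MserParams",
    "MserRegion",
    "EllipseFrame",
    "OrientationProfile",
    "detect_msers",
    "min_circumscribed_ellipse",
    "orientation_profile",
]


@dataclass
class MserParams:
    """Detector knobs (defaults suit a worm of ~60 px length).

    delta
        Stability window in quantized gray levels (0..255 scale).
    min_area, max_area_frac
        Area bounds in pixels / as a fraction of the frame.
    max_variation
        Maximum relative area change over ``delta`` levels.
    min_level
        Quantized floor below which pixels count as background.
    """

    delta: int = 5
    min_area: int = 30
    max_area_frac: float = 0.25
    max_variation: float = 0.25
    min_level: int = 8  # quantized floor; excludes background-residual haze from the sweep


@dataclass
class MserRegion:
    pixels: np.ndarray  # (k, 2) array of (row, col)
    area: int
    level: int  # quantized gray threshold of maximal stability
    stability: float  # relative area-variation score (lower = more stable)


@dataclass
class EllipseFrame:
    center: tuple[float, float]  # (row, col)
    semi_major: float
    semi_minor: float
    orientation: float  # psi, radians in (-pi/2, pi/2], from +col axis


@dataclass
class OrientationProfile:
    psi: np.ndarray  # raw interpolated orientations at the query areas
    query_areas: np.ndarray
    circ_mean: float
    recentered: np.ndarray  # psi - circ_mean, wrapped
    empty: bool = False


def _quantize(frame: np.ndarray, scale: Optional[float]) -> np.ndarray:
    f = np.asarray(frame, dtype=np.float64)
    if scale is None:
        scale = float(f.max()) if f.size else 0.0
    if scale <= 0:
        return np.zeros(f.shape, dtype=np.uint8)
    q = np.round(np.clip(f / scale, 0.0, 1.0) * 255.0)
    return q.astype(np.uint8)


def detect_msers(
    frame: np.ndarray,
    params: MserParams | None = None,
    scale: Optional[float] = None,
) -> list[MserRegion]:
    """MSER detection on a background-subtracted, bright-on-dark frame.

    ``scale`` sets the intensity mapped to gray level 255; the pipeline
    passes the video-wide maximum so thresholds are comparable across frames.
    Returns regions sorted by area ascending; a uniform frame yields [].
    """
    params = params or MserParams()
    img_full = _quantize(frame, scale)
    max_area = int(params.max_area_frac * img_full.size)
    # crop to the active region: pixels below the sweep floor are background
    rows, cols = np.nonzero(img_full >= params.min_level)
    if rows.size == 0:
        return []
    r0, r1 = int(rows.min()), int(rows.max()) + 1
    c0, c1 = int(cols.min()), int(cols.max()) + 1
    img_q = np.ascontiguousarray(img_full[r0:r1, c0:c1])
    flat = img_q.ravel()
    active = np.nonzero(flat >= params.min_level)[0]
    order = active[np.argsort(-flat[active].astype(np.int32), kind="stable")].astype(np.int64)
    anchors, levels, areas, qs = mser_sweep(
        img_q,
        order,
        np.int64(params.delta),
        np.int64(params.min_area),
        np.int64(max_area),
        float(params.max_variation),
        np.int64(params.min_level),
    )
    w = img_q.shape[1]
    regions: list[MserRegion] = []
    for anchor, level, area, q in zip(anchors, levels, areas, qs):
        mask = img_q >= level
        lab, _ = ndimage.label(mask)  # 4-connectivity default
        comp = lab[anchor // w, anchor % w]
        pix = np.argwhere(lab == comp)
        pix[:, 0] += r0
        pix[:, 1] += c0
        regions.append(MserRegion(pixels=pix, area=len(pix), level=int(level), stability=float(q)))
    regions.sort(key=lambda r: r.area)
    return regions


def _mvee(points: np.ndarray, tol: float = 1e-3, max_iter: int = 5000) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-volume enclosing ellipse of 2-D points (Khachiyan iteration).

    Returns (center, A) with the ellipse {p : (p-c)^T A (p-c) <= 1}; A is
    rescaled at the end so every input point is inside.  ``tol`` bounds the
    relative optimality gap of the ellipse volume.
    """
    p = np.asarray(points, dtype=np.float64)
    k, d = p.shape
    u = mvee_weights(np.ascontiguousarray(p), tol, max_iter)
    c = p.T @ u
    cov = (p.T * u) @ p - np.outer(c, c)
    a = np.linalg.inv(cov) / d
    # guarantee containment (iteration stops slightly short)
    dp = p - c
    scale = float(np.max(np.einsum("ij,jk,ik->i", dp, a, dp)))
    if scale > 1.0:
        a = a / scale
    return c, a


def _wrap_half_pi(psi: np.ndarray | float) -> np.ndarray | float:
    """Map angle(s) into (-pi/2, pi/2] (axial convention)."""
    out = np.mod(np.asarray(psi, dtype=np.float64) + np.pi / 2, np.pi) - np.pi / 2
    out = np.where(out == -np.pi / 2, np.pi / 2, out)
    if np.isscalar(psi):
        return float(out)
    return out


def min_circumscribed_ellipse(region: MserRegion, degenerate_eps: float = 0.5) -> EllipseFrame:
    """Minimal (minimum-area) circumscribed ellipse of a region's pixel centers.

    Degenerate (collinear) regions fall back to the fitted line's orientation
    with the minor semi-axis set to ``degenerate_eps``.
    """
    pts = np.asarray(region.pixels, dtype=np.float64)  # (row, col)
    if len(pts) == 0:
        raise ValueError("empty region")
    # work in (x, y) = (col, row)
    xy = pts[:, ::-1]
    centered = xy - xy.mean(axis=0)
    # rank check for collinearity
    svals = np.linalg.svd(centered, compute_uv=False) if len(pts) > 1 else np.array([0.0, 0.0])
    if len(pts) < 3 or (len(svals) > 1 and svals[1] < 1e-9 * max(svals[0], 1.0)):
        # degenerate: orient along the dominant direction
        if svals[0] < 1e-12:  # single point
            psi = 0.0
            a_len = degenerate_eps
        else:
            _, _, vt = np.linalg.svd(centered)
            vx, vy = vt[0]
            psi = float(np.arctan2(vy, vx))
            proj = centered @ vt[0]
            a_len = max(float(proj.max() - proj.min()) / 2.0, degenerate_eps)
        cx, cy = xy.mean(axis=0)
        return EllipseFrame(
            center=(float(cy), float(cx)),
            semi_major=a_len,
            semi_minor=degenerate_eps,
            orientation=float(_wrap_half_pi(psi)),
        )

    try:
        from scipy.spatial import ConvexHull

        hull = ConvexHull(xy)
        pts_fit = xy[hull.vertices]
    except Exception:
        pts_fit = xy
    c, a_mat = _mvee(pts_fit)
    evals, evecs = np.linalg.eigh(a_mat)
    # semi-axis lengths are 1/sqrt(eigenvalue); smallest eigenvalue = major axis
    semi = 1.0 / np.sqrt(np.maximum(evals, 1e-18))
    order = np.argsort(semi)[::-1]
    semi = semi[order]
    vmaj = evecs[:, order[0]]
    psi = float(np.arctan2(vmaj[1], vmaj[0]))
    return EllipseFrame(
        center=(float(c[1]), float(c[0])),
        semi_major=float(semi[0]),
        semi_minor=float(semi[1]),
        orientation=float(_wrap_half_pi(psi)),
    )


def _axial_mean(psi: np.ndarray, mode: str) -> float:
    """Circular mean of orientations; doubled-angle mode treats them as axial."""
    psi = np.asarray(psi, dtype=np.float64)
    if mode == "doubled":
        z = np.exp(2j * psi).sum()
        if abs(z) < 1e-9:
            return 0.0
        return float(np.angle(z) / 2.0)
    z = np.exp(1j * psi).sum()
    if abs(z) < 1e-9:
        return 0.0
    return float(np.angle(z))


def orientation_profile(
    areas: Sequence[float],
    orientations: Sequence[float],
    n_query: int,
    a_min: float,
    a_max: float,
    angle_mode: str = "doubled",
) -> OrientationProfile:
    """Fixed-length orientation profile over a grid of query areas.

    Orientations are interpolated (and linearly extrapolated) against region
    area at ``n_query`` evenly spaced areas in [a_min, a_max], then recentered
    by their circular mean.  With zero detected regions the profile is all
    zeros and flagged ``empty``.
    """
    if n_query < 1:
        raise ValueError("n_query must be >= 1")
    if not a_min < a_max:
        raise ValueError("a_min must be < a_max")
    if angle_mode not in ("doubled", "raw"):
        raise ValueError("angle_mode must be 'doubled' or 'raw'")
    query = np.linspace(a_min, a_max, n_query)

    areas = np.asarray(areas, dtype=np.float64)
    psis = np.asarray(orientations, dtype=np.float64)
    if areas.size == 0:
        z = np.zeros(n_query)
        return OrientationProfile(psi=z, query_areas=query, circ_mean=0.0, recentered=z.copy(), empty=True)

    order = np.argsort(areas, kind="stable")
    areas = areas[order]
    psis = psis[order]
    # merge duplicate areas by (axial) circular mean so interpolation is well posed
    uniq_areas: list[float] = []
    uniq_psis: list[float] = []
    i = 0
    while i < len(areas):
        j = i
        while j + 1 < len(areas) and areas[j + 1] == areas[i]:
            j += 1
        uniq_areas.append(float(areas[i]))
        uniq_psis.append(_axial_mean(psis[i : j + 1], angle_mode))
        i = j + 1
    ua = np.asarray(uniq_areas)
    up = np.asarray(uniq_psis)

    if len(ua) == 1:
        psi_q = np.full(n_query, up[0])
    else:
        factor = 2.0 if angle_mode == "doubled" else 1.0
        z = np.unwrap(factor * up)
        # piecewise-linear interpolation with linear extrapolation
        psi_q = np.interp(query, ua, z)
        left = query < ua[0]
        right = query > ua[-1]
        if left.any():
            slope = (z[1] - z[0]) / (ua[1] - ua[0])
            psi_q[left] = z[0] + slope * (query[left] - ua[0])
        if right.any():
            slope = (z[-1] - z[-2]) / (ua[-1] - ua[-2])
            psi_q[right] = z[-1] + slope * (query[right] - ua[-1])
        psi_q = psi_q / factor

    mean = _axial_mean(psi_q, angle_mode)
    if angle_mode == "doubled":
        recentered = np.asarray(_wrap_half_pi(psi_q - mean))
    else:
        recentered = np.mod(psi_q - mean + np.pi, 2 * np.pi) - np.pi
    return OrientationProfile(
        psi=psi_q, query_areas=query, circ_mean=mean, recentered=recentered, empty=False
    )


def profile_from_regions(
    regions: Sequence[MserRegion],
    n_query: int,
    a_min: float,
    a_max: float,
    angle_mode: str = "doubled",
    degenerate_eps: float = 0.5,
) -> OrientationProfile:
    """Detect ellipses for each region and build the orientation profile."""
    areas = [r.area for r in regions]
    psis = [min_circumscribed_ellipse(r, degenerate_eps).orientation for r in regions]
    return orientation_profile(areas, psis, n_query, a_min, a_max, angle_mode=angle_mode)
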