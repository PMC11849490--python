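"""Segmentation-based locomotor frequency (morphometric comparison method).

Each frame is thresholded to a binary worm mask; head and tail are the two
sharpest convex points of the boundary; the centerline is the midpoint curve
between the two boundary sides, spline-smoothed and resampled to M equidistant
points.  The anterior body curvature (mean signed curvature over body
coordinate 0.1-0.3, excluding the noisy tip) oscillates at the undulation
frequency, so f = fps / (mean spacing of its local maxima) - peaks of signed
curvature recur once per full period.

This route requires accurate segmentation of every frame and is the
noise-sensitive baseline the invariant pipeline is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import interpolate, ndimage
from scipy.signal import find_peaks
from skimage import filters, measure

from .video import FrameStack

__all__ = [
    "Centerline",
    "CurvatureProfile",
    "BaselineResult",
    "segment_worm",
    "head_tail_centerline",
    "centerline_curvature",
    "curvature_frequency",
    "analyze_baseline",
]


@dataclass
class Centerline:
    points: np.ndarray  # (M, 2) (row, col), head -> tail, equidistant in arc length
    body_coordinate: np.ndarray  # (M,) in [0, 1]


@dataclass
class CurvatureProfile:
    kappa: np.ndarray  # signed curvature per body coordinate (1/px)
    body_coordinate: np.ndarray
    anterior_mean: float  # mean kappa over s in [0.1, 0.3]


@dataclass
class BaselineResult:
    frequency_hz: float
    n_failed_frames: int
    n_frames: int
    anterior_series: np.ndarray  # per-frame anterior curvature (NaN where failed)


def segment_worm(frame: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Gaussian smoothing + Otsu threshold + largest component + hole fill."""
    f = np.asarray(frame, dtype=np.float64)
    sm = ndimage.gaussian_filter(f, sigma)
    if sm.max() <= sm.min():
        raise ValueError("empty foreground: frame is uniform")
    th = filters.threshold_otsu(sm)
    mask = sm > th
    if not mask.any():
        raise ValueError("empty foreground: nothing above threshold")
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(mask)


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n points equidistant in arc length."""
    pts = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, arc, pts[:, 0])
    out[:, 1] = np.interp(targets, arc, pts[:, 1])
    return out


def _resample_open(points: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] <= 0:
        raise ValueError("degenerate polyline")
    targets = np.linspace(0.0, arc[-1], n)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, arc, points[:, 0])
    out[:, 1] = np.interp(targets, arc, points[:, 1])
    return out


def _signed_curvature(points: np.ndarray, closed: bool) -> np.ndarray:
    """Signed curvature of a polyline via finite differences."""
    mode = "wrap" if closed else "nearest"
    d1 = np.empty_like(points)
    d2 = np.empty_like(points)
    for axis in range(2):
        d1[:, axis] = ndimage.convolve1d(points[:, axis], [0.5, 0.0, -0.5], mode=mode)
        d2[:, axis] = ndimage.convolve1d(points[:, axis], [1.0, -2.0, 1.0], mode=mode)
    num = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]  # x'y'' - y'x'' (CCW convex > 0)
    den = (d1[:, 0] ** 2 + d1[:, 1] ** 2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(den > 0, num / den, 0.0)
    return kappa


def head_tail_centerline(
    mask: np.ndarray,
    m_samples: int = 50,
    n_boundary: int = 200,
    boundary_sigma: float = 2.0,
    spline_smooth: float = 5.0,
    prev_head: Optional[np.ndarray] = None,
) -> Centerline:
    """Centerline between the two sharpest convex boundary points.

    ``prev_head`` orients the output so the head end tracks the previous
    frame's head (keeps the curvature sign consistent over time).
    """
    contours = measure.find_contours(mask.astype(np.float64), 0.5)
    if not contours:
        raise ValueError("ends not found: no boundary in mask")
    contour = max(contours, key=len)  # (row, col)
    if len(contour) < 8:
        raise ValueError("ends not found: boundary too short")
    boundary = _resample_closed(contour[:-1] if np.allclose(contour[0], contour[-1]) else contour, n_boundary)
    # ensure counterclockwise in (x, y) = (col, row) so convex curvature is positive
    x, y = boundary[:, 1], boundary[:, 0]
    area2 = float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    if area2 < 0:
        boundary = boundary[::-1].copy()
    sm = boundary.copy()
    for axis in range(2):
        sm[:, axis] = ndimage.gaussian_filter1d(boundary[:, axis], boundary_sigma, mode="wrap")
    kappa_b = _signed_curvature(sm[:, ::-1], closed=True)  # in (x, y) order

    i1 = int(np.argmax(kappa_b))
    idx = np.arange(n_boundary)
    cyc = np.minimum((idx - i1) % n_boundary, (i1 - idx) % n_boundary)
    far = cyc >= n_boundary // 4
    if not far.any():
        raise ValueError("ends not found: boundary too small")
    cand = np.where(far, kappa_b, -np.inf)
    i2 = int(np.argmax(cand))
    if kappa_b[i2] <= 0:
        raise ValueError("ends not found: second convexity maximum missing")
    # a coiled or blob-like shape has no meaningful ends: require elongation
    cov = np.cov((sm - sm.mean(axis=0)).T)
    evals = np.sort(np.linalg.eigvalsh(cov))
    if evals[0] > 0 and evals[1] / evals[0] < 2.5:
        raise ValueError("ends not found: boundary is not elongated (coiled or round shape)")

    lo, hi = sorted((i1, i2))
    side_a = sm[lo : hi + 1]
    side_b = np.vstack([sm[hi:], sm[: lo + 1]])[::-1]
    k = max(m_samples, 20)
    mid = (_resample_open(side_a, k) + _resample_open(side_b, k)) / 2.0
    if lo != i1:  # orient head first
        mid = mid[::-1].copy()

    # cubic spline smoothing, then equidistant resampling to m_samples
    try:
        tck, _ = interpolate.splprep([mid[:, 0], mid[:, 1]], s=spline_smooth * k / 50.0, k=3)
        u = np.linspace(0, 1, 8 * m_samples)
        rows, cols = interpolate.splev(u, tck)
        fine = np.column_stack([rows, cols])
    except Exception as exc:
        raise ValueError(f"ends not found: centerline spline failed ({exc})") from exc
    pts = _resample_open(fine, m_samples)

    if prev_head is not None:
        if np.linalg.norm(pts[-1] - prev_head) < np.linalg.norm(pts[0] - prev_head):
            pts = pts[::-1].copy()
    s = np.linspace(0.0, 1.0, m_samples)
    return Centerline(points=pts, body_coordinate=s)


def centerline_curvature(centerline: Centerline) -> CurvatureProfile:
    """Signed curvature along the centerline and its anterior (s in 0.1-0.3) mean.

    The curvature formula (x'y'' - y'x'') / speed^3 is parameterization
    invariant, so equidistant index spacing gives kappa directly in 1/px.
    """
    pts = centerline.points
    kappa = _signed_curvature(pts[:, ::-1], closed=False)
    s = centerline.body_coordinate
    sel = (s >= 0.1) & (s <= 0.3)
    return CurvatureProfile(kappa=kappa, body_coordinate=s, anterior_mean=float(kappa[sel].mean()))


def curvature_frequency(
    anterior_series: np.ndarray, fps: float, min_prominence_frac: float = 0.1
) -> float:
    """fps / (mean spacing of anterior-curvature maxima); 0 Hz with < 2 peaks.

    A minimal prominence of ``min_prominence_frac`` times the series SD guards
    against counting noise wiggles as bends.
    """
    series = np.asarray(anterior_series, dtype=np.float64)
    if len(series) < 3:
        raise ValueError("series must have length >= 3")
    sd = np.nanstd(series)
    if not np.isfinite(sd) or sd == 0:
        return 0.0
    filled = series.copy()
    bad = ~np.isfinite(filled)
    if bad.all():
        return 0.0
    if bad.any():
        good = np.nonzero(~bad)[0]
        filled[bad] = np.interp(np.nonzero(bad)[0], good, filled[good])
    peaks, _ = find_peaks(filled, prominence=min_prominence_frac * sd)
    if len(peaks) < 2:
        return 0.0
    mean_interval = float(np.mean(np.diff(peaks)))
    return fps / mean_interval


def analyze_baseline(stack: FrameStack, m_samples: int = 50, sigma: float = 1.0) -> BaselineResult:
    """Full segmentation pipeline over a stack.

    Frames where segmentation or centerline extraction fails contribute NaN to
    the anterior-curvature series (interpolated over when estimating the
    frequency) and are counted in ``n_failed_frames``.  If more than half the
    frames fail the estimate is reported as NaN.
    """
    t = stack.n_frames
    series = np.full(t, np.nan)
    prev_head: Optional[np.ndarray] = None
    n_failed = 0
    for i in range(t):
        try:
            mask = segment_worm(stack.frames[i], sigma=sigma)
            cl = head_tail_centerline(mask, m_samples=m_samples, prev_head=prev_head)
            prev_head = cl.points[0]
            series[i] = centerline_curvature(cl).anterior_mean
        except (ValueError, RuntimeError):
            n_failed += 1
    if n_failed > t // 2:
        freq = float("nan")
    else:
        freq = curvature_frequency(series, stack.fps)
    return BaselineResult(
        frequency_hz=freq, n_failed_frames=n_failed, n_frames=t, anterior_series=series
    )
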