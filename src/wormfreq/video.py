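"""Frame I/O and rank-1 background subtraction for dark-field worm videos.

The background of a mostly static dark-field scene is well approximated by the
first principal component (uncentered rank-1 SVD) of the pixels-by-time video
matrix.  Subtracting that rank-1 reconstruction leaves the moving, bright
animal on a near-zero background, which is the input contract for the moment
and region-feature modules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "FrameStack",
    "BackgroundModel",
    "load_frames",
    "estimate_background",
    "subtract_background",
    "write_tiff",
]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}
_VIDEO_SUFFIXES = {".avi", ".mp4", ".mov", ".mkv"}


@dataclass
class FrameStack:
    """A T x H x W stack of nonnegative grayscale intensities with a frame rate.

    Parameters
    ----------
    frames
        Array of shape (T, H, W), nonnegative intensities (float64).
    fps
        Acquisition frequency in Hz (fs > 0).
    pixel_size
        Optional metadata: micrometres per pixel.
    """

    frames: np.ndarray
    fps: float
    pixel_size: Optional[float] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        t, h, w = self.frames.shape
        if t < 1 or h < 1 or w < 1:
            raise ValueError("FrameStack requires T, H, W >= 1")
        if np.any(self.frames < 0):
            raise ValueError("FrameStack intensities must be nonnegative")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape  # type: ignore[return-value]

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class BackgroundModel:
    """Rank-1 video background: outer(temporal_coefficients, spatial_component)."""

    spatial_component: np.ndarray  # H x W, unit Euclidean norm (or all-zero)
    temporal_coefficients: np.ndarray  # length T
    shape: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.spatial_component = np.asarray(self.spatial_component, dtype=np.float64)
        self.temporal_coefficients = np.asarray(self.temporal_coefficients, dtype=np.float64)
        self.shape = self.spatial_component.shape  # type: ignore[assignment]

    def reconstruct(self) -> np.ndarray:
        """Return the rank-1 background video, shape (T, H, W)."""
        return self.temporal_coefficients[:, None, None] * self.spatial_component[None, :, :]


def _natural_key(name: str) -> tuple:
    """Sort key splitting digit runs so f2 < f10."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse a trailing color axis by an unweighted channel mean."""
    a = np.asarray(arr)
    if a.ndim == 3 and a.shape[-1] in (3, 4):
        a = a[..., :3].mean(axis=-1)
    return a.astype(np.float64)


def load_frames(path: str | Path, fps: float, pixel_size: Optional[float] = None) -> FrameStack:
    """Load a video as a :class:`FrameStack`.

    Accepts a multi-page TIFF, a directory of numbered PNG/TIFF frames
    (ordered by natural sort of filename), or a common video container
    (requires an imageio ffmpeg plugin).  Color frames are converted to
    grayscale by the unweighted channel mean.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input path does not exist: {p}")

    frames: list[np.ndarray]
    if p.is_dir():
        files = sorted(
            (f for f in p.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES),
            key=lambda f: _natural_key(f.name),
        )
        if not files:
            raise ValueError(f"zero frames found in directory {p}")
        import imageio.v3 as iio

        frames = [_to_gray(iio.imread(f)) for f in files]
    elif p.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(p)
        if data.ndim == 2:
            data = data[None]
        if data.ndim == 4:  # pages with color channels
            data = np.stack([_to_gray(page) for page in data])
        frames = [np.asarray(f, dtype=np.float64) for f in data]
    elif p.suffix.lower() in _VIDEO_SUFFIXES:
        import imageio.v3 as iio

        try:
            raw = iio.imread(p, plugin="pyav")
        except Exception:
            try:
                raw = iio.imread(p)
            except Exception as exc:  # pragma: no cover - depends on plugins
                raise RuntimeError(
                    f"cannot read video container {p.suffix}: no working imageio "
                    "video plugin available; convert to a TIFF stack instead"
                ) from exc
        frames = [_to_gray(f) for f in np.asarray(raw)]
    else:
        import imageio.v3 as iio

        frames = [_to_gray(iio.imread(p))]

    if not frames:
        raise ValueError(f"zero frames found at {p}")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")
    stack = np.stack(frames)
    stack = np.clip(stack, 0.0, None)
    return FrameStack(stack, fps=fps, pixel_size=pixel_size)


def write_tiff(stack: FrameStack, path: str | Path) -> None:
    """Write a stack as a multi-page float32 TIFF (for inspection)."""
    import tifffile

    tifffile.imwrite(Path(path), stack.frames.astype(np.float32), photometric="minisblack")


def estimate_background(stack: FrameStack) -> BackgroundModel:
    """Fit the rank-1 (first principal component) background of a video.

    Uses the uncentered SVD of the (H*W) x T video matrix, computed through
    the T x T Gram matrix for efficiency.  The rank-1 reconstruction is the
    best rank-1 approximation in the Frobenius norm.
    """
    t, h, w = stack.shape
    if t < 2:
        raise ValueError("background model requires >= 2 frames")
    m = stack.frames.reshape(t, h * w)  # rows = frames
    gram = m @ m.T  # T x T
    if not np.any(gram):
        return BackgroundModel(np.zeros((h, w)), np.zeros(t))
    evals, evecs = np.linalg.eigh(gram)
    v = evecs[:, -1]  # temporal singular vector (unit norm)
    spatial = m.T @ v
    norm = np.linalg.norm(spatial)
    if norm == 0:
        return BackgroundModel(np.zeros((h, w)), np.zeros(t))
    spatial /= norm
    # temporal coefficients = projections of each frame onto the spatial component
    coeffs = m @ spatial
    # fix sign so the spatial component is predominantly nonnegative
    if spatial.sum() < 0:
        spatial = -spatial
        coeffs = -coeffs
    return BackgroundModel(spatial.reshape(h, w), coeffs)


def subtract_background(stack: FrameStack, model: BackgroundModel) -> FrameStack:
    """Per-frame residual (frame minus rank-1 reconstruction), clamped at 0.

    Clamping encodes the dark-field assumption: the animal is brighter than
    the background, so negative residuals are background fluctuation.
    """
    t, h, w = stack.shape
    if model.shape != (h, w) or model.temporal_coefficients.shape[0] != t:
        raise ValueError(
            f"background model shape {model.shape} x {model.temporal_coefficients.shape[0]} "
            f"does not match stack {stack.shape}"
        )
    residual = stack.frames - model.reconstruct()
    np.clip(residual, 0.0, None, out=residual)
    return FrameStack(residual, fps=stack.fps, pixel_size=stack.pixel_size)
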