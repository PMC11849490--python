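"""Multi-well batch analysis: grid cropping, windowed timecourses, quiescence.

A large-field video of a multi-well plate is cropped into per-well regions of
interest from a declarative grid description; each well's recording windows
are analyzed independently with the full pipeline, giving a frequency
timecourse and the quiescent fraction (share of windows scored 0 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import PipelineConfig
from .pipeline import analyze_stack
from .video import FrameStack

__all__ = ["WellGrid", "FrequencyTimecourse", "crop_wells", "analyze_timecourse", "split_windows"]


@dataclass
class WellGrid:
    rows: int
    cols: int
    centers: np.ndarray  # (rows*cols, 2) of (row, col), row-major order
    roi_halfwidth: int

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64).reshape(self.rows * self.cols, 2)
        if self.roi_halfwidth < 1:
            raise ValueError("roi_halfwidth must be >= 1")

    @classmethod
    def from_geometry(
        cls, rows: int, cols: int, origin: tuple[float, float], pitch: float, roi_halfwidth: int
    ) -> "WellGrid":
        """Regular grid: well (i, j) centered at origin + (i, j) * pitch."""
        centers = [
            (origin[0] + i * pitch, origin[1] + j * pitch)
            for i in range(rows)
            for j in range(cols)
        ]
        return cls(rows=rows, cols=cols, centers=np.array(centers), roi_halfwidth=roi_halfwidth)

    def validate(self, frame_hw: tuple[int, int]) -> None:
        h, w = frame_hw
        hw = self.roi_halfwidth
        for k, (cy, cx) in enumerate(self.centers):
            r0, r1 = int(round(cy)) - hw, int(round(cy)) + hw
            c0, c1 = int(round(cx)) - hw, int(round(cx)) + hw
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                raise ValueError(f"well {k} ROI [{r0}:{r1}, {c0}:{c1}] falls outside the {h}x{w} frame")
        for a in range(len(self.centers)):
            for b in range(a + 1, len(self.centers)):
                dy, dx = np.abs(self.centers[a] - self.centers[b])
                if dy < 2 * hw and dx < 2 * hw:
                    raise ValueError(f"wells {a} and {b} have overlapping ROIs")


@dataclass
class FrequencyTimecourse:
    times: np.ndarray  # window start times (s)
    frequencies: np.ndarray  # Hz per window; NaN where analysis failed
    quiescent_fraction: float
    n_failed_windows: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        if len(self.times) != len(self.frequencies):
            raise ValueError("times and frequencies must have equal length")


def crop_wells(stack: FrameStack, grid: WellGrid) -> list[FrameStack]:
    """Per-well square stacks (2*roi_halfwidth wide), row-major well order."""
    grid.validate(stack.shape[1:])
    hw = grid.roi_halfwidth
    out = []
    for cy, cx in grid.centers:
        r0, c0 = int(round(cy)) - hw, int(round(cx)) - hw
        out.append(
            FrameStack(
                stack.frames[:, r0 : r0 + 2 * hw, c0 : c0 + 2 * hw].copy(),
                fps=stack.fps,
                pixel_size=stack.pixel_size,
            )
        )
    return out


def split_windows(stack: FrameStack, window_s: float) -> list[FrameStack]:
    """Split a stack into consecutive non-overlapping analysis windows."""
    n = max(1, int(round(window_s * stack.fps)))
    out = []
    for start in range(0, stack.n_frames, n):
        chunk = stack.frames[start : start + n]
        if len(chunk) >= max(4, n // 2):  # drop a trailing stub too short to analyze
            out.append(FrameStack(chunk, fps=stack.fps, pixel_size=stack.pixel_size))
    return out


def analyze_timecourse(
    well_windows: Sequence[FrameStack],
    config: Optional[PipelineConfig] = None,
    window_period_s: Optional[float] = None,
) -> FrequencyTimecourse:
    """One frequency per recording window; quiescent fraction over valid windows.

    Windows whose analysis raises are recorded as NaN, excluded from the
    quiescent-fraction denominator, and counted in ``n_failed_windows``.
    ``window_period_s`` sets the spacing of the reported start times (e.g.
    120 s for a 20 s window taken every 2 min); defaults to each window's own
    duration.
    """
    config = config or PipelineConfig()
    freqs = np.full(len(well_windows), np.nan)
    times = np.zeros(len(well_windows))
    t_acc = 0.0
    n_failed = 0
    for i, win in enumerate(well_windows):
        times[i] = t_acc
        period = window_period_s if window_period_s is not None else win.n_frames / win.fps
        t_acc += period
        try:
            freqs[i] = analyze_stack(win, config).result.frequency_hz
        except Exception:
            n_failed += 1
    valid = np.isfinite(freqs)
    if valid.any():
        qf = float(np.mean(freqs[valid] == 0.0))
    else:
        qf = float("nan")
    return FrequencyTimecourse(
        times=times, frequencies=freqs, quiescent_fraction=qf, n_failed_windows=n_failed
    )
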