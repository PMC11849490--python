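"""End-to-end orchestration: background -> invariants -> autocorrelation -> Hz.

``analyze_stack`` is the single entry point used by the CLI, the multi-well
driver, and the benchmark sweeps.  It is deterministic for a fixed input and
config (all randomness in the package lives in the simulator's seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import baseline as seg
from .config import PipelineConfig
from .hu import HuVector, hu_from_frame
from .mser import OrientationProfile, detect_msers, min_circumscribed_ellipse, orientation_profile
from .rhythm import (
    AutocorrSeries,
    EnsembleMatrix,
    ExtremaRunFamily,
    FrequencyResult,
    build_ensemble,
    ensemble_autocorrelation,
    frequency_from_autocorr,
    standardize,
)
from .video import FrameStack, estimate_background, subtract_background

__all__ = ["PipelineResult", "extract_features", "analyze_stack"]


@dataclass
class PipelineResult:
    result: FrequencyResult
    autocorr: Optional[AutocorrSeries] = None
    family: Optional[ExtremaRunFamily] = None
    ensemble: Optional[EnsembleMatrix] = None
    n_failed_frames: int = 0


class ModuleError(RuntimeError):
    """Error annotated with the failing module and frame index."""


def _per_frame_features(
    stack: FrameStack, config: PipelineConfig
) -> tuple[list[Optional[HuVector]], list[Optional[OrientationProfile]]]:
    t = stack.n_frames
    hu_series: list[Optional[HuVector]] = [None] * t
    psi_series: list[Optional[OrientationProfile]] = [None] * t

    if not config.disable_hu:
        for i in range(t):
            try:
                hu_series[i] = hu_from_frame(stack.frames[i], h8_prefactor=config.h8_prefactor)
            except ValueError:
                hu_series[i] = None  # zero-mass frame; imputed downstream

    if not config.disable_mser:
        gmax = float(stack.frames.max())
        per_frame: list[tuple[list[float], list[float]]] = []
        largest = 0.0
        for i in range(t):
            try:
                regions = detect_msers(stack.frames[i], config.mser, scale=gmax)
            except Exception as exc:
                raise ModuleError(f"mser failed at frame {i}: {exc}") from exc
            areas = [float(r.area) for r in regions]
            psis = [min_circumscribed_ellipse(r).orientation for r in regions]
            per_frame.append((areas, psis))
            if areas:
                largest = max(largest, max(areas))
        if largest <= 0:
            # no region in any frame: every profile is empty (imputed downstream)
            n = config.n_orientations
            empty = OrientationProfile(
                psi=np.zeros(n), query_areas=np.linspace(1, 2, n),
                circ_mean=0.0, recentered=np.zeros(n), empty=True,
            )
            psi_series = [empty] * t
        else:
            if config.area_range_mode == "detected":
                qq = config.area_range_quantile
                mins = [min(a) for a, _ in per_frame if a]
                maxs = [max(a) for a, _ in per_frame if a]
                a_min = float(np.quantile(mins, qq))
                a_max = float(np.quantile(maxs, qq))
            elif config.area_range_mode == "largest_frac":
                a_max = config.a_max_frac * largest
                a_min = max(config.a_min_frac * largest, 1.0)
            else:
                raise ModuleError(f"unknown area_range_mode {config.area_range_mode!r}")
            if not a_min < a_max:
                a_min, a_max = 0.5 * a_max, max(a_max, a_min)
            if not a_min < a_max:  # still degenerate (single region scale)
                a_min, a_max = 0.5 * a_max, a_max + 1.0
            for i, (areas, psis) in enumerate(per_frame):
                psi_series[i] = orientation_profile(
                    areas, psis, config.n_orientations, a_min, a_max, angle_mode=config.angle_mode
                )
    return hu_series, psi_series


def extract_features(stack: FrameStack, config: PipelineConfig) -> EnsembleMatrix:
    """Background subtraction (unless disabled) and ensemble assembly."""
    work = stack
    if not config.disable_background and stack.n_frames >= 2:
        try:
            model = estimate_background(stack)
            work = subtract_background(stack, model)
        except ValueError as exc:
            raise ModuleError(f"background estimation failed: {exc}") from exc
    hu_series, psi_series = _per_frame_features(work, config)
    return build_ensemble(
        hu_series,
        psi_series,
        fps=stack.fps,
        include_hu=not config.disable_hu,
        include_mser=not config.disable_mser,
    )


def analyze_stack(stack: FrameStack, config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Estimate locomotor frequency of a single-animal video.

    With ``config.method == "segmentation"`` the morphometric baseline is run
    instead of the invariant pipeline.
    """
    config = config or PipelineConfig()
    config.validate()

    if config.method == "segmentation":
        work = stack
        if not config.disable_background and stack.n_frames >= 2:
            work = subtract_background(stack, estimate_background(stack))
        br = seg.analyze_baseline(work, m_samples=config.seg_m_samples, sigma=config.seg_sigma)
        freq = br.frequency_hz
        quiescent = freq == 0.0
        return PipelineResult(
            result=FrequencyResult(
                frequency_hz=freq, mean_interval_lags=None, quiescent=bool(quiescent)
            ),
            n_failed_frames=br.n_failed_frames,
        )

    ensemble = extract_features(stack, config)
    std = standardize(ensemble)
    tau_max = config.tau_max
    t = std.n_frames
    if tau_max is None:
        tau_max = min(t // 2, t - 2)
    autocorr = ensemble_autocorrelation(std, tau_max=tau_max)
    result, family = frequency_from_autocorr(
        autocorr,
        threshold=config.prominence_threshold,
        conversion=config.conversion,
        refine=config.refine_extrema,
        adjacency=config.adjacency,
    )
    return PipelineResult(result=result, autocorr=autocorr, family=family, ensemble=std)


def write_artifacts(res: PipelineResult, out_dir: str | Path) -> None:
    """Dump intermediate tables (ensemble, autocorrelation, extrema) as CSV/JSON."""
    import json

    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if res.ensemble is not None:
        pd.DataFrame(res.ensemble.values).to_csv(out / "ensemble_standardized.csv", index=False)
    if res.autocorr is not None:
        pd.DataFrame({"lag": res.autocorr.lags, "r": res.autocorr.r}).to_csv(
            out / "autocorrelation.csv", index=False
        )
    if res.family is not None:
        run_id = {}
        for rid, run in enumerate(res.family.runs):
            for idx in run:
                run_id[idx] = rid
        discarded = set(res.family.discarded)
        rows = [
            {
                "lag": e.lag,
                "refined_lag": e.refined_lag,
                "value": e.value,
                "kind": e.kind,
                "prominence": e.prominence,
                "kept": i not in discarded,
                "run": run_id.get(i, -1),
            }
            for i, e in enumerate(res.family.extrema)
        ]
        pd.DataFrame(rows).to_csv(out / "extrema.csv", index=False)
    with open(out / "result.json", "w") as fh:
        json.dump(
            {
                "frequency_hz": res.result.frequency_hz,
                "mean_interval_lags": res.result.mean_interval_lags,
                "quiescent": res.result.quiescent,
                "n_failed_frames": res.n_failed_frames,
            },
            fh,
            indent=2,
        )
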