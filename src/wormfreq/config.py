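"""Declarative configuration for the analysis pipeline.

Defaults reproduce the reference pipeline: background subtraction on, both
feature blocks on, N = 4 orientation invariants, prominence threshold 0.14,
autocorrelation out to half the video length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

from .mser import MserParams

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    method: str = "invariant"  # "invariant" | "segmentation"

    # module ablation switches (mirror the module-ablation experiment)
    disable_background: bool = False
    disable_hu: bool = False
    disable_mser: bool = False

    # feature extraction
    n_orientations: int = 4  # N: MSER orientation invariants per frame
    mser: MserParams = field(default_factory=MserParams)
    # query-area bounds for the orientation profile: "detected" anchors them at
    # the scales the detector actually returns (quantiles of the per-frame
    # smallest/largest region areas, so queries interpolate rather than
    # extrapolate); "largest_frac" uses fixed fractions of the video-wide
    # largest region area
    area_range_mode: str = "detected"
    area_range_quantile: float = 0.2
    a_min_frac: float = 0.01  # used by area_range_mode="largest_frac"
    a_max_frac: float = 1.0
    angle_mode: str = "doubled"  # axial-angle handling ("doubled" | "raw")
    h8_prefactor: str = "eta11"

    # rhythm analysis
    tau_max: Optional[int] = None  # default floor(T/2)
    prominence_threshold: float = 0.14
    conversion: str = "half_period"  # lag -> Hz conversion ("half_period" | "full_period")
    refine_extrema: bool = True  # parabolic sub-frame extremum refinement
    adjacency: str = "survivors"  # run adjacency ("survivors" | "original")

    # segmentation baseline
    seg_sigma: float = 1.0
    seg_m_samples: int = 50

    def validate(self) -> None:
        if self.method not in ("invariant", "segmentation"):
            raise ValueError("method must be 'invariant' or 'segmentation'")
        if self.disable_hu and self.disable_mser:
            raise ValueError("cannot disable both feature blocks")
        if self.n_orientations < 1:
            raise ValueError("n_orientations must be >= 1")
        if not 0 <= self.a_min_frac < self.a_max_frac:
            raise ValueError("require 0 <= a_min_frac < a_max_frac")


def _update_dataclass(obj: Any, data: dict) -> None:
    for key, value in data.items():
        if not hasattr(obj, key):
            raise KeyError(f"unknown config key: {key}")
        current = getattr(obj, key)
        if isinstance(value, dict) and hasattr(current, "__dataclass_fields__"):
            _update_dataclass(current, value)
        else:
            setattr(obj, key, value)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides."""
    cfg = PipelineConfig()
    if path is not None:
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        _update_dataclass(cfg, data)
    if overrides:
        _update_dataclass(cfg, overrides)
    cfg.validate()
    return cfg
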