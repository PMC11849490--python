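"""Ensemble autocorrelation and extrema-run frequency estimation.

Per-frame invariants (8 Hu moments + N recentered MSER orientations) form a
P x T ensemble matrix.  Each row is z-scored (population variance), then the
lag-tau autocorrelation averages the cosine similarity between ensemble
columns tau frames apart.  Locomotor frequency follows from the mean spacing
of prominent alternating peaks/troughs of that autocorrelation: adjacent
peak-trough spacing of a periodic signal's autocorrelation is half a period,
so f = fps / (2 * mean spacing).  If no extremum run survives the prominence
threshold, the animal is scored quiescent (f = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks, peak_prominences

from .hu import HuVector
from .mser import OrientationProfile

__all__ = [
    "EnsembleMatrix",
    "AutocorrSeries",
    "Extremum",
    "ExtremaRunFamily",
    "FrequencyResult",
    "build_ensemble",
    "standardize",
    "ensemble_autocorrelation",
    "find_extrema_with_prominence",
    "select_runs",
    "estimate_frequency",
    "frequency_from_autocorr",
]

DEFAULT_PROMINENCE_THRESHOLD = 0.14


@dataclass
class EnsembleMatrix:
    values: np.ndarray  # P x T
    fps: float
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("ensemble must be a P x T matrix")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class AutocorrSeries:
    r: np.ndarray  # values at lags 0..tau_max
    fps: float

    @property
    def lags(self) -> np.ndarray:
        return np.arange(len(self.r))


@dataclass
class Extremum:
    lag: int
    value: float
    kind: str  # "peak" | "trough"
    prominence: float
    refined_lag: float = 0.0  # sub-frame lag from parabolic refinement

    def __post_init__(self) -> None:
        if not self.refined_lag:
            self.refined_lag = float(self.lag)


@dataclass
class ExtremaRunFamily:
    extrema: list[Extremum]  # ordered by lag, alternating kinds
    threshold: float = DEFAULT_PROMINENCE_THRESHOLD
    discarded: list[int] = field(default_factory=list)  # indices into extrema
    runs: list[list[int]] = field(default_factory=list)  # index runs into extrema

    @property
    def empty(self) -> bool:
        return len(self.runs) == 0


@dataclass
class FrequencyResult:
    frequency_hz: float
    mean_interval_lags: Optional[float]
    quiescent: bool


def build_ensemble(
    hu_series: Sequence[Optional[HuVector]],
    psi_series: Sequence[Optional[OrientationProfile]],
    fps: float,
    include_hu: bool = True,
    include_mser: bool = True,
) -> EnsembleMatrix:
    """Stack per-frame invariants into a P x T matrix (rows h1..h8, psi~1..psi~N).

    Frames whose Hu vector is missing (zero-mass frame) or whose orientation
    profile is flagged empty are imputed with the row's mean over valid
    frames, so standardization stays finite.  The ablation flags drop the Hu
    or MSER block entirely.
    """
    t = len(hu_series)
    if len(psi_series) != t:
        raise ValueError("hu_series and psi_series must have equal length")
    if t == 0:
        raise ValueError("empty series")
    if not (include_hu or include_mser):
        raise ValueError("at least one feature block must be enabled")

    blocks: list[np.ndarray] = []
    if include_hu:
        hu_block = np.full((8, t), np.nan)
        for i, hv in enumerate(hu_series):
            if hv is not None:
                hu_block[:, i] = hv.h
        blocks.append(hu_block)
    if include_mser:
        n = None
        for prof in psi_series:
            if prof is not None:
                n = len(prof.recentered)
                break
        if n is None:
            raise ValueError("no orientation profile available in any frame")
        psi_block = np.full((n, t), np.nan)
        for i, prof in enumerate(psi_series):
            if prof is not None and not prof.empty:
                if len(prof.recentered) != n:
                    raise ValueError("orientation profile length varies across frames")
                psi_block[:, i] = prof.recentered
        blocks.append(psi_block)

    values = np.vstack(blocks)
    # impute missing frames with the row mean over valid frames
    for row in values:
        bad = np.isnan(row)
        if bad.all():
            row[:] = 0.0
        elif bad.any():
            row[bad] = row[~bad].mean()
    return EnsembleMatrix(values, fps=fps, standardized=False)


def standardize(ensemble: EnsembleMatrix) -> EnsembleMatrix:
    """Per-row z-score with the population standard deviation.

    Constant rows (zero variance) map to all-zeros rather than NaN.
    """
    if ensemble.n_frames < 2:
        raise ValueError("standardization requires T >= 2")
    v = ensemble.values
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)  # population (ddof=0), as in the z-score definition
    out = np.zeros_like(v)
    nz = sd[:, 0] > 0
    out[nz] = (v[nz] - mean[nz]) / sd[nz]
    return EnsembleMatrix(out, fps=ensemble.fps, standardized=True)


def ensemble_autocorrelation(ensemble: EnsembleMatrix, tau_max: Optional[int] = None) -> AutocorrSeries:
    """Mean cosine similarity between ensemble columns tau frames apart.

    R(tau) = 1/(T-tau) * sum_t cos(F(t), F(t+tau)) for tau = 0..tau_max
    (default floor(T/2)).  Columns with zero norm contribute 0 to the sum but
    still count in the T-tau normalizer.
    """
    if not ensemble.standardized:
        raise ValueError("autocorrelation expects a standardized ensemble")
    t = ensemble.n_frames
    if tau_max is None:
        tau_max = t // 2
    if not 1 <= tau_max <= t - 2:
        raise ValueError(f"tau_max must be in [1, T-2], got {tau_max} for T={t}")
    v = ensemble.values
    norms = np.linalg.norm(v, axis=0)
    u = np.where(norms > 0, v / np.where(norms > 0, norms, 1.0), 0.0)
    gram = u.T @ u  # cos similarity of every column pair
    r = np.empty(tau_max + 1)
    for tau in range(tau_max + 1):
        diag = np.diagonal(gram, offset=tau)
        r[tau] = diag.sum() / (t - tau)
    return AutocorrSeries(r=r, fps=ensemble.fps)


def _endpoint_peak_prominence(r: np.ndarray) -> float:
    """Prominence of the lag-0 peak with the contour truncated at the border."""
    higher = np.nonzero(r[1:] > r[0])[0]
    stop = higher[0] + 1 if len(higher) else len(r)
    return float(r[0] - r[1:stop].min()) if stop > 1 else 0.0


def _refine_lag(r: np.ndarray, i: int) -> float:
    """Sub-frame extremum location by a 3-point parabolic fit."""
    if i <= 0 or i >= len(r) - 1:
        return float(i)
    denom = r[i - 1] - 2 * r[i] + r[i + 1]
    if abs(denom) < 1e-15:
        return float(i)
    shift = 0.5 * (r[i - 1] - r[i + 1]) / denom
    if abs(shift) > 1.0:  # numerically degenerate; keep the grid lag
        return float(i)
    return float(i + shift)


def find_extrema_with_prominence(series: AutocorrSeries, refine: bool = True) -> ExtremaRunFamily:
    """Ordered alternating peaks/troughs of R(tau) with topographic prominences.

    Includes the lag-0 peak (prominence computed with the contour truncated at
    the series boundary).  Plateau extrema are reduced to their midpoint
    sample.  Trough prominences are peak prominences of the negated series.
    """
    r = np.asarray(series.r, dtype=np.float64)
    if len(r) < 3:
        raise ValueError("series must have length >= 3")

    peaks, _ = find_peaks(r)
    troughs, _ = find_peaks(-r)
    peak_prom = peak_prominences(r, peaks)[0] if len(peaks) else np.array([])
    trough_prom = peak_prominences(-r, troughs)[0] if len(troughs) else np.array([])

    ext: list[Extremum] = []
    if 0 not in peaks:  # lag-0 peak always included
        ext.append(
            Extremum(lag=0, value=float(r[0]), kind="peak", prominence=_endpoint_peak_prominence(r))
        )
    # the far endpoint is an extremum when the series arrives rising/falling
    last = len(r) - 1
    if r[last] > r[last - 1]:
        ext.append(
            Extremum(lag=last, value=float(r[last]), kind="peak",
                     prominence=_endpoint_peak_prominence(r[::-1]))
        )
    elif r[last] < r[last - 1]:
        ext.append(
            Extremum(lag=last, value=float(r[last]), kind="trough",
                     prominence=_endpoint_peak_prominence(-r[::-1]))
        )
    for i, p in zip(peaks, peak_prom):
        ext.append(Extremum(lag=int(i), value=float(r[i]), kind="peak", prominence=float(p)))
    for i, p in zip(troughs, trough_prom):
        ext.append(Extremum(lag=int(i), value=float(r[i]), kind="trough", prominence=float(p)))
    ext.sort(key=lambda e: e.lag)

    # enforce alternation: among adjacent same-kind extrema keep the more extreme
    cleaned: list[Extremum] = []
    for e in ext:
        if cleaned and cleaned[-1].kind == e.kind:
            prev = cleaned[-1]
            better = e.value > prev.value if e.kind == "peak" else e.value < prev.value
            if better:
                cleaned[-1] = e
            continue
        cleaned.append(e)

    if refine:
        for e in cleaned:
            if e.lag > 0:
                e.refined_lag = _refine_lag(r, e.lag)
    return ExtremaRunFamily(extrema=cleaned)


def select_runs(
    family: ExtremaRunFamily,
    threshold: float = DEFAULT_PROMINENCE_THRESHOLD,
    adjacency: str = "survivors",
) -> ExtremaRunFamily:
    """Partition prominent extrema into maximal runs; drop runs shorter than 2.

    Extrema with prominence below ``threshold`` are discarded.  Low-prominence
    noise wiggles come in adjacent peak+trough pairs (equal prominences), so
    the surviving major extrema still alternate; with the default
    ``adjacency="survivors"`` the survivors are re-indexed and runs are
    maximal alternating stretches of that list.  Runs split wherever two
    consecutive survivors have the same kind (their spacing is a full period,
    not the half-period the estimator averages).

    ``adjacency="original"`` instead requires surviving extrema to be adjacent
    in the full extrema list (any discarded wiggle in between breaks a run) —
    a stricter, fragile-under-noise reading kept for comparison.

    The resulting family may be empty, which is scored as quiescence.
    """
    ext = family.extrema
    discarded = [i for i, e in enumerate(ext) if e.prominence < threshold]
    dropped = set(discarded)
    survivors = [i for i in range(len(ext)) if i not in dropped]
    runs: list[list[int]] = []
    cur: list[int] = []
    for i in survivors:
        if cur:
            if adjacency == "original":
                ok = i == cur[-1] + 1
            elif adjacency == "survivors":
                ok = ext[i].kind != ext[cur[-1]].kind
            else:
                raise ValueError("adjacency must be 'survivors' or 'original'")
            if ok:
                cur.append(i)
                continue
            if len(cur) >= 2:
                runs.append(cur)
        cur = [i]
    if len(cur) >= 2:
        runs.append(cur)
    return ExtremaRunFamily(extrema=ext, threshold=threshold, discarded=discarded, runs=runs)


def estimate_frequency(
    family: ExtremaRunFamily,
    fps: float,
    conversion: str = "half_period",
    use_refined_lags: bool = True,
) -> FrequencyResult:
    """Frequency from the mean adjacent-extremum lag of the surviving runs.

    delta = sum_i (lag(last_i) - lag(first_i)) / sum_i (len_i - 1) averages
    every adjacent peak-trough spacing.  Under the default ``half_period``
    conversion f = fps / (2 * delta), because neighbouring extrema of an
    autocorrelation are half an oscillation period apart.  ``full_period``
    (f = fps / delta) is provided for comparison.
    """
    if family.empty:
        return FrequencyResult(frequency_hz=0.0, mean_interval_lags=None, quiescent=True)
    lag_of = (lambda e: e.refined_lag) if use_refined_lags else (lambda e: float(e.lag))
    span = 0.0
    count = 0
    for run in family.runs:
        first, last = family.extrema[run[0]], family.extrema[run[-1]]
        span += lag_of(last) - lag_of(first)
        count += len(run) - 1
    delta = span / count
    if delta <= 0:
        return FrequencyResult(frequency_hz=0.0, mean_interval_lags=None, quiescent=True)
    if conversion == "half_period":
        f = fps / (2.0 * delta)
    elif conversion == "full_period":
        f = fps / delta
    else:
        raise ValueError("conversion must be 'half_period' or 'full_period'")
    return FrequencyResult(frequency_hz=float(f), mean_interval_lags=float(delta), quiescent=False)


def frequency_from_autocorr(
    series: AutocorrSeries,
    threshold: float = DEFAULT_PROMINENCE_THRESHOLD,
    conversion: str = "half_period",
    refine: bool = True,
    adjacency: str = "survivors",
) -> tuple[FrequencyResult, ExtremaRunFamily]:
    """Extrema detection, run selection and frequency estimation in one step."""
    family = find_extrema_with_prominence(series, refine=refine)
    family = select_runs(family, threshold=threshold, adjacency=adjacency)
    result = estimate_frequency(family, series.fps, conversion=conversion, use_refined_lags=refine)
    return result, family
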