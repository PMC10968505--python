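"""From per-frame pupil detections to normalised PLR curves and PIPR-6s.

The chain mirrors standard chromatic-pupillometry processing:

1. build a time-indexed pupil-area trace from the detections table;
2. invalidate blinks and step outliers (blinks appear as missing/aberrant
   detections, not as genuine area changes);
3. smooth with an exponentially weighted moving average (EWMA) over the
   valid samples;
4. invalidate residual outliers (raw far from smoothed);
5. compute the baseline — the mean pupil area over the pre-stimulus window —
   from the raw valid samples;
6. normalise each sample to percent-of-baseline:

       normalized = 100 - (baseline - absolute) / baseline * 100

   which is algebraically ``100 * absolute / baseline``;
7. read off the post-illumination pupil response at a fixed delay after
   stimulus offset (PIPR-6s: 6 s), as the mean over a short window.

The headline statistic is the red-minus-blue PIPR-6s difference: melanopsin
keeps the pupil constricted after a blue stimulus, so blue PIPR sits well
below red and the difference is positive in healthy eyes (about 10% in the
literature for full-field and ring stimuli alike).

Aggregation is per-trial-first: PIPR is computed per trial, then averaged
(mean and n-1 sd) across the repeats, matching how repeated measurements per
stimulus condition are reported.  Curve aggregation resamples each trial's
valid samples onto a common grid by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError, InputError
from .simulate import ProtocolTiming

__all__ = [
    "PLRTrace",
    "NormalizedTrace",
    "PIPRMetrics",
    "AnalysisConfig",
    "ProcessedTrial",
    "build_trace",
    "flag_blinks",
    "ewma_filter",
    "compute_baseline",
    "normalize",
    "pipr_at",
    "pipr_difference",
    "aggregate",
    "aggregate_pipr",
    "process_trace",
]


@dataclass(frozen=True)
class PLRTrace:
    """Raw pupil-area time series with validity flags and protocol timing."""

    times_s: np.ndarray
    areas_px2: np.ndarray
    valid: np.ndarray
    timing: ProtocolTiming

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        if not (len(t) == len(self.areas_px2) == len(self.valid)):
            raise InputError("times, areas and valid must have equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise InputError("times must be strictly increasing")
        if len(t) and self.timing.offset_s > t[-1] + 1e-9:
            raise InputError("record ends before the stimulus offset")


@dataclass(frozen=True)
class NormalizedTrace:
    """Baseline-normalised trace (% of baseline) with the baseline it used."""

    times_s: np.ndarray
    normalized_pct: np.ndarray
    baseline_px2: float
    valid: np.ndarray
    timing: ProtocolTiming


@dataclass(frozen=True)
class PIPRMetrics:
    """PIPR per colour plus the red-minus-blue difference, with dispersion."""

    pipr_blue: float
    pipr_red: float
    difference: float
    delay_s: float = 6.0
    window_halfwidth_s: float = 0.25
    n_trials: int = 1
    dispersion_blue: float = float("nan")
    dispersion_red: float = float("nan")

    def __post_init__(self) -> None:
        if self.delay_s < 0:
            raise ConfigurationError("delay_s must be non-negative")
        if abs(self.difference - (self.pipr_red - self.pipr_blue)) > 1e-9:
            raise ConfigurationError("difference must equal pipr_red - pipr_blue")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the analysis chain (defaults documented in docs)."""

    alpha: float = 0.3
    max_rel_step: float = 0.5
    min_gap_frames: int = 3
    residual_k: float = 4.0
    pipr_delay_s: float = 6.0
    window_halfwidth_s: float = 0.25
    pipr_on_smoothed: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigurationError("alpha must lie in (0, 1]")
        if self.max_rel_step <= 0:
            raise ConfigurationError("max_rel_step must be positive")


def build_trace(detections: pd.DataFrame, timing: ProtocolTiming) -> PLRTrace:
    """Detections table -> :class:`PLRTrace`.

    Times come from ``frame_index / frame_rate``; rows with invalid
    detections become invalid samples (their areas are carried as NaN).
    Duplicate frame indices are an input error.
    """
    df = detections.sort_values("frame_index")
    idx = df["frame_index"].to_numpy()
    if len(np.unique(idx)) != len(idx):
        raise InputError("duplicate frame indices in detections")
    times = idx / timing.frame_rate
    valid = df["valid"].to_numpy(dtype=bool)
    areas = df["area_px2"].to_numpy(dtype=float)
    valid = valid & np.isfinite(areas)
    return PLRTrace(times_s=times, areas_px2=areas, valid=valid, timing=timing)


def flag_blinks(
    trace: PLRTrace, max_rel_step: float = 0.5, min_gap_frames: int = 3
) -> np.ndarray:
    """Blink/outlier validity pass; returns an updated validity array.

    A sample is invalidated when its detection already failed or when its
    area jumps by more than ``max_rel_step`` (relative) from the last valid
    sample — blinks and partial occlusions produce such steps, genuine PLR
    dynamics do not at video frame rates.  Valid runs shorter than
    ``min_gap_frames`` squeezed between invalid runs are invalidated too,
    merging the flanking blink intervals.
    """
    if len(trace.times_s) == 0:
        raise AnalysisError("empty trace")
    areas = trace.areas_px2
    valid = trace.valid.copy()
    last_area = None
    for i in range(len(areas)):
        if not valid[i]:
            continue
        if last_area is not None:
            if abs(areas[i] - last_area) / last_area > max_rel_step:
                valid[i] = False
                continue
        last_area = areas[i]

    if min_gap_frames > 1:
        # merge invalid runs separated by very short valid runs
        i = 0
        n = len(valid)
        while i < n:
            if valid[i]:
                j = i
                while j < n and valid[j]:
                    j += 1
                interior = i > 0 and j < n  # flanked by invalid on both sides
                if interior and (j - i) < min_gap_frames:
                    valid[i:j] = False
                i = j
            else:
                i += 1
    return valid


def ewma_filter(
    values: np.ndarray, alpha: float, valid: np.ndarray | None = None
) -> np.ndarray:
    """Exponentially weighted moving average over the valid samples.

    ``y_0 = x_0``; ``y_i = alpha * x_i + (1 - alpha) * y_{i-1}`` with the
    recursion running over valid samples only, so the filter propagates
    across blink gaps.  Invalid positions are NaN in the output.
    """
    if not 0.0 < alpha <= 1.0:
        raise ConfigurationError("alpha must lie in (0, 1]")
    x = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(x.shape, dtype=bool)
    out = np.full(x.shape, np.nan)
    prev = None
    for i in np.flatnonzero(valid):
        xi = x[i]
        prev = xi if prev is None else alpha * xi + (1.0 - alpha) * prev
        out[i] = prev
    return out


def compute_baseline(trace: PLRTrace, valid: np.ndarray | None = None) -> float:
    """Mean raw pupil area over the pre-stimulus baseline window."""
    valid = trace.valid if valid is None else valid
    in_window = trace.times_s < trace.timing.onset_s
    sel = in_window & valid
    if not sel.any():
        raise AnalysisError("no valid samples in the baseline window; trial unusable")
    return float(np.mean(trace.areas_px2[sel]))


def normalize(
    trace: PLRTrace,
    baseline_px2: float,
    valid: np.ndarray | None = None,
    areas: np.ndarray | None = None,
) -> NormalizedTrace:
    """Percent-of-baseline normalisation of each valid sample.

    Implements ``100 - (baseline - absolute)/baseline * 100``, the standard
    pupil-area normalisation, identically equal to ``100*absolute/baseline``.
    """
    if baseline_px2 <= 0:
        raise AnalysisError("baseline must be positive")
    valid = trace.valid if valid is None else valid
    areas = trace.areas_px2 if areas is None else areas
    with np.errstate(invalid="ignore"):
        norm = 100.0 - (baseline_px2 - areas) / baseline_px2 * 100.0
    norm = np.where(valid, norm, np.nan)
    return NormalizedTrace(
        times_s=trace.times_s,
        normalized_pct=norm,
        baseline_px2=baseline_px2,
        valid=valid,
        timing=trace.timing,
    )


def pipr_at(
    nt: NormalizedTrace,
    delay_s: float = 6.0,
    window_halfwidth_s: float = 0.25,
    values: np.ndarray | None = None,
) -> float:
    """Mean normalised pupil area in a window centred ``delay_s`` after offset.

    ``values`` overrides the trace's own normalised samples (e.g. to evaluate
    on the EWMA-smoothed curve); validity flags always come from the trace.
    """
    center = nt.timing.offset_s + delay_s
    if center > nt.times_s[-1] + 1e-9:
        raise AnalysisError("PIPR evaluation time falls outside the record")
    vals = nt.normalized_pct if values is None else values
    sel = (
        (nt.times_s >= center - window_halfwidth_s)
        & (nt.times_s <= center + window_halfwidth_s)
        & nt.valid
        & np.isfinite(vals)
    )
    if not sel.any():
        raise AnalysisError("no valid samples in the PIPR window")
    return float(np.mean(vals[sel]))


def pipr_difference(pipr_red: float, pipr_blue: float) -> float:
    """Red-minus-blue PIPR difference (%); positive when melanopsin responds."""
    if not (np.isfinite(pipr_red) and np.isfinite(pipr_blue)):
        raise AnalysisError("PIPR values must be finite")
    return pipr_red - pipr_blue


def aggregate(
    traces: Sequence[NormalizedTrace], grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and sample sd of traces resampled onto a common grid.

    Each trace is linearly interpolated over its valid samples.  With a
    single trace the sd is zero by convention.
    """
    if len(traces) == 0:
        raise AnalysisError("no traces to aggregate")
    grid = np.asarray(grid, dtype=float)
    resampled = []
    for nt in traces:
        sel = nt.valid & np.isfinite(nt.normalized_pct)
        if not sel.any():
            raise AnalysisError("trace has no valid samples to interpolate")
        resampled.append(np.interp(grid, nt.times_s[sel], nt.normalized_pct[sel]))
    stack = np.vstack(resampled)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros_like(mean)
    return mean, sd


def aggregate_pipr(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample sd of per-trial PIPR values."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise AnalysisError("no PIPR values to aggregate")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return mean, sd


@dataclass(frozen=True)
class ProcessedTrial:
    """Everything the chain derives from one trial."""

    trace: PLRTrace
    normalized: NormalizedTrace
    smoothed_pct: np.ndarray
    baseline_px2: float
    pipr: float
    valid_fraction: float
    config: AnalysisConfig = field(default_factory=AnalysisConfig)


def process_trace(
    trace: PLRTrace, config: AnalysisConfig | None = None
) -> ProcessedTrial:
    """Run the full chain on one trial's trace.

    Order: blink flagging -> EWMA over valid samples -> residual-outlier pass
    (|raw - smoothed| > k * robust sd, sd = 1.4826*MAD) -> baseline from raw
    valid samples -> normalisation -> PIPR on the smoothed (default) or raw
    normalised curve.
    """
    cfg = config or AnalysisConfig()
    valid = flag_blinks(trace, cfg.max_rel_step, cfg.min_gap_frames)

    smoothed_area = ewma_filter(trace.areas_px2, cfg.alpha, valid)
    residuals = trace.areas_px2[valid] - smoothed_area[valid]
    mad = np.median(np.abs(residuals - np.median(residuals)))
    robust_sd = 1.4826 * mad
    if robust_sd > 0:
        bad = np.zeros_like(valid)
        bad[valid] = np.abs(residuals) > cfg.residual_k * robust_sd
        valid = valid & ~bad
        smoothed_area = ewma_filter(trace.areas_px2, cfg.alpha, valid)

    baseline = compute_baseline(trace, valid)
    normalized = normalize(trace, baseline, valid)
    smoothed_pct = 100.0 * smoothed_area / baseline
    pipr_values = smoothed_pct if cfg.pipr_on_smoothed else None
    pipr = pipr_at(
        normalized,
        delay_s=cfg.pipr_delay_s,
        window_halfwidth_s=cfg.window_halfwidth_s,
        values=pipr_values,
    )
    return ProcessedTrial(
        trace=trace,
        normalized=normalized,
        smoothed_pct=smoothed_pct,
        baseline_px2=baseline,
        pipr=pipr,
        valid_fraction=float(np.mean(valid)),
        config=cfg,
    )
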