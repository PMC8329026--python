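"""Pupillometry preprocessing and per-segment task-evoked response metrics.

The pipeline follows the standard psychophysiology recipe for video-based
eye-trackers: merge the binocular signal into one diameter per frame, bridge
short dropouts (blinks) by linear interpolation, smooth with a low-pass
Butterworth filter, exclude residual outliers by a feasible-range rule plus a
z-score rule, reference against a pre-stimulus baseline, and summarise each
utterance segment by mean dilation, peak dilation, and the slope of a linear
fit.

Dilation is signed: positive values are dilation relative to baseline,
negative values contraction.  Slope is in mm per frame at the nominal 50 Hz
rate (multiply by 50 for mm/s).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum
from typing import Optional

import numpy as np
from scipy import signal

from .core import FRAME_RATE, PupilStream, UtteranceSegment, ValidationError


class Provenance(IntEnum):
    """Per-frame origin of the merged diameter value."""

    MISSING = 0
    MERGED_BOTH = 1
    LEFT_ONLY = 2
    RIGHT_ONLY = 3
    INTERPOLATED = 4


@dataclass
class FilterSpec:
    """Low-pass Butterworth smoothing parameters."""

    order: int = 5
    cutoff_hz: float = 4.0
    sampling_hz: float = FRAME_RATE
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValidationError("filter order must be >= 1")
        if not (0 < self.cutoff_hz < self.sampling_hz / 2):
            raise ValidationError("cutoff must lie below the Nyquist frequency")

    def coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        return signal.butter(self.order, self.cutoff_hz, btype="low", fs=self.sampling_hz)


@dataclass
class OutlierSpec:
    """Feasible-range and z-score exclusion parameters.

    The feasible range brackets physiologically possible human pupil
    diameters; the z rule removes residual artefacts relative to the mean of
    the surviving signal.  ``z_scope`` controls whether z statistics come
    from this participant's series or are supplied globally.
    """

    feasible_min_mm: float = 1.5
    feasible_max_mm: float = 9.0
    z_threshold: float = 2.0
    z_scope: str = "per-participant"      # or "global"
    global_mean: Optional[float] = None
    global_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.feasible_min_mm >= self.feasible_max_mm:
            raise ValidationError("feasible_min must be < feasible_max")
        if self.z_threshold <= 0:
            raise ValidationError("z_threshold must be positive")
        if self.z_scope not in ("per-participant", "global"):
            raise ValidationError(f"unknown z_scope {self.z_scope!r}")


@dataclass
class PupilSeries:
    """A merged monocular-equivalent pupil series with bookkeeping masks.

    ``valid`` marks frames that carry a diameter value (measured or
    interpolated); ``excluded`` marks frames rejected by outlier rules.
    Only ``usable`` frames (valid and not excluded) enter metric
    computation.
    """

    t: np.ndarray
    diameter_mm: np.ndarray
    valid: np.ndarray
    flags: np.ndarray                      # Provenance codes, int8
    excluded: np.ndarray | None = None
    outlier_stats: tuple[float, float] | None = None   # (mean, sd) used by z rule

    def __post_init__(self) -> None:
        if self.excluded is None:
            self.excluded = np.zeros(self.t.size, dtype=bool)

    @property
    def usable(self) -> np.ndarray:
        return self.valid & ~self.excluded

    def __len__(self) -> int:
        return self.t.size


@dataclass
class PupilBaseline:
    """Pre-stimulus reference diameter for one participant."""

    role: str
    value_mm: float
    window: tuple[float, float]


def merge_binocular(stream: PupilStream) -> PupilSeries:
    """Combine left and right diameters into one value per frame.

    Both eyes present: their mean.  One eye present: that eye.  Neither:
    the frame is invalid.  Missingness is data, not an error.
    """
    left, right = stream.left_mm, stream.right_mm
    has_l, has_r = ~np.isnan(left), ~np.isnan(right)
    diameter = np.full(stream.t.size, np.nan)
    flags = np.full(stream.t.size, Provenance.MISSING, dtype=np.int8)
    both = has_l & has_r
    diameter[both] = 0.5 * (left[both] + right[both])
    flags[both] = Provenance.MERGED_BOTH
    only_l = has_l & ~has_r
    diameter[only_l] = left[only_l]
    flags[only_l] = Provenance.LEFT_ONLY
    only_r = has_r & ~has_l
    diameter[only_r] = right[only_r]
    flags[only_r] = Provenance.RIGHT_ONLY
    return PupilSeries(t=stream.t.copy(), diameter_mm=diameter,
                       valid=has_l | has_r, flags=flags)


def interpolate_gaps(series: PupilSeries, max_gap_frames: int = 25) -> PupilSeries:
    """Bridge short invalid runs by linear interpolation between the
    flanking valid frames.

    Runs longer than ``max_gap_frames`` (default 0.5 s — a generous blink)
    stay invalid, as do leading/trailing runs with only one flank:
    extrapolation is refused.
    """
    d = series.diameter_mm.copy()
    valid = series.valid.copy()
    flags = series.flags.copy()
    n = d.size
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        gap = j - i
        if i > 0 and j < n and gap <= max_gap_frames:
            x0, x1 = series.t[i - 1], series.t[j]
            y0, y1 = d[i - 1], d[j]
            for k in range(i, j):
                frac = (series.t[k] - x0) / (x1 - x0)
                d[k] = y0 + frac * (y1 - y0)
            valid[i:j] = True
            flags[i:j] = Provenance.INTERPOLATED
        i = j
    return replace(series, diameter_mm=d, valid=valid, flags=flags,
                   excluded=series.excluded.copy())


def lowpass_filter(series: PupilSeries, spec: FilterSpec = FilterSpec()) -> PupilSeries:
    """Smooth the merged series with the configured low-pass Butterworth.

    Zero-phase mode runs the filter forward and backward so metric windows
    are not shifted by group delay; causal mode applies the plain recursion.
    Residual invalid frames (long gaps) are bridged by edge-hold for the
    filter arithmetic only — their validity mask is unchanged and they never
    enter metrics.
    """
    n_valid = int(series.valid.sum())
    if n_valid < 3 * spec.order:
        raise ValidationError(
            f"series too short to filter: {n_valid} valid frames, "
            f"need at least {3 * spec.order}"
        )
    b, a = spec.coefficients()
    x = series.diameter_mm.copy()
    invalid = ~series.valid
    if invalid.any():
        idx = np.arange(x.size)
        x[invalid] = np.interp(idx[invalid], idx[~invalid], x[~invalid])
    if spec.zero_phase:
        y = signal.filtfilt(b, a, x)
    else:
        y = signal.lfilter(b, a, x)
    return replace(series, diameter_mm=y, valid=series.valid.copy(),
                   flags=series.flags.copy(), excluded=series.excluded.copy())


def remove_outliers(
    series: PupilSeries,
    spec: OutlierSpec = OutlierSpec(),
    recompute_stats: bool = False,
) -> PupilSeries:
    """Flag frames outside the feasible range or beyond the z threshold.

    The range rule runs first; z statistics (mean, SD) are computed on the
    range-surviving valid frames.  The statistics are stored on the series,
    so a second application with ``recompute_stats=False`` reuses them and
    excludes nothing new (idempotence).  Raises if no usable frame survives.
    """
    d = series.diameter_mm
    excluded = series.excluded.copy()
    in_range = series.valid & (d >= spec.feasible_min_mm) & (d <= spec.feasible_max_mm)
    out_of_range = series.valid & ~in_range

    if spec.z_scope == "global":
        if spec.global_mean is None or spec.global_sd is None:
            raise ValidationError("global z scope requires global_mean and global_sd")
        mean, sd = spec.global_mean, spec.global_sd
    elif series.outlier_stats is not None and not recompute_stats:
        mean, sd = series.outlier_stats
    else:
        pool = d[in_range & ~excluded]
        if pool.size == 0:
            raise ValidationError("no frames inside the feasible range; unusable signal")
        mean, sd = float(np.mean(pool)), float(np.std(pool))

    excluded |= out_of_range
    if sd > 0:
        excluded |= series.valid & (np.abs(d - mean) > spec.z_threshold * sd)
    out = replace(series, diameter_mm=d.copy(), valid=series.valid.copy(),
                  flags=series.flags.copy(), excluded=excluded)
    out.outlier_stats = (mean, sd)
    if not out.usable.any():
        raise ValidationError("all frames excluded; unusable signal")
    return out


def extract_baseline(series: PupilSeries, window: tuple[float, float],
                     role: str = "") -> PupilBaseline:
    """Mean usable diameter over the pre-stimulus window.

    Requires at least 50% usable coverage of the window, so a blink-ridden
    baseline fails loudly rather than biasing every dilation downstream.
    """
    start, end = window
    in_win = (series.t >= start) & (series.t < end)
    n_win = int(in_win.sum())
    if n_win == 0:
        raise ValidationError(f"baseline window [{start}, {end}] covers no frames")
    use = in_win & series.usable
    if use.sum() < 0.5 * n_win:
        raise ValidationError(
            f"baseline window [{start}, {end}]: only {int(use.sum())}/{n_win} "
            f"usable frames (< 50%)"
        )
    return PupilBaseline(role=role, value_mm=float(series.diameter_mm[use].mean()),
                         window=(start, end))


def segment_pupil_metrics(
    series: PupilSeries,
    baseline: PupilBaseline,
    segment: UtteranceSegment,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Per-segment (mean_dilation, peak_dilation, slope).

    mean/peak are the mean and max of (diameter - baseline) over usable
    frames in [start, end); slope is the least-squares slope of diameter
    against frame index, in mm/frame.  With fewer than two usable frames all
    three are undefined (None).
    """
    in_seg = (series.t >= segment.start) & (series.t < segment.end)
    use = in_seg & series.usable
    if use.sum() < 2:
        return None, None, None
    d = series.diameter_mm[use]
    dil = d - baseline.value_mm
    frames = np.round(series.t[use] * FRAME_RATE)
    slope = float(np.polyfit(frames, d, 1)[0])
    return float(dil.mean()), float(dil.max()), slope


def preprocess(
    stream: PupilStream,
    filter_spec: FilterSpec = FilterSpec(),
    outlier_spec: OutlierSpec = OutlierSpec(),
    max_gap_frames: int = 25,
) -> PupilSeries:
    """The full cleaning chain: merge, interpolate, filter, exclude outliers."""
    series = merge_binocular(stream)
    series = interpolate_gaps(series, max_gap_frames)
    series = lowpass_filter(series, filter_spec)
    return remove_outliers(series, outlier_spec)
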