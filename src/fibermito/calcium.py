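"""Ratiometric Ca²⁺ trace analysis: baseline, ROI means, 490/420 ratio and
ATP-evoked transient metrics.

The mitochondrial indicator is excited at 490 and 420 nm and reported as the
490/420 ratio; records are time-lapse (2 s frame interval in the reference
protocol). Cytosolic single-indicator records reuse the same machinery with
F/F₀ in place of the two-channel ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RatiometricTrace",
    "TransientMetrics",
    "baseline_subtract",
    "roi_means",
    "compute_ratio",
    "dff_trace",
    "transient_metrics",
]

DETECTION_K = 3.0
PEAK_SMOOTH_WINDOW = 3


@dataclass
class RatiometricTrace:
    """Time-indexed two-channel record (ROI means) and its stimulus time."""

    time: np.ndarray
    f490: np.ndarray
    f420: np.ndarray
    stimulus_time: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.f490 = np.asarray(self.f490, dtype=float)
        self.f420 = np.asarray(self.f420, dtype=float)
        if not (len(self.time) == len(self.f490) == len(self.f420)):
            raise ValueError("time, f490 and f420 must have equal lengths")

    @property
    def ratio(self) -> np.ndarray:
        return compute_ratio(self.f490, self.f420)


@dataclass
class TransientMetrics:
    """Resting level and stimulus-evoked transient quantification."""

    resting_level: float
    peak_amplitude: float
    time_to_peak: float
    detected: bool
    prestim_sd: float
    k: float = DETECTION_K


def _window_indices(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return np.flatnonzero((time >= lo) & (time <= hi))


def baseline_subtract(
    data: np.ndarray,
    time: np.ndarray,
    prestim_window: tuple[float, float],
    stimulus_time: float | None = None,
) -> np.ndarray:
    """Subtract the pre-stimulus mean along the time axis.

    ``data`` is a 1D series or an image time-lapse (t, y, x); in image mode
    the per-pixel mean pre-stimulus frame is subtracted (the numeric analogue
    of subtracting a pre-stimulus fluorescence image). The window must be
    nonempty and precede the stimulus.
    """
    data = np.asarray(data, dtype=float)
    time = np.asarray(time, dtype=float)
    idx = _window_indices(time, prestim_window)
    if idx.size == 0:
        raise ValueError("pre-stimulus window contains no frames")
    if stimulus_time is not None and prestim_window[1] >= stimulus_time:
        raise ValueError("pre-stimulus window must end before the stimulus")
    baseline = data[idx].mean(axis=0)
    return data - baseline


def roi_means(stack: np.ndarray, roi_masks: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-ROI traces and the per-cell trace of a (t, y, x) time-lapse.

    Returns ``(per_roi, cell)`` where ``per_roi`` has shape (n_roi, t) and
    ``cell`` is the mean across ROIs, the standard 3–6-regions-per-cell
    readout.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a (t, y, x) time-lapse")
    traces = []
    for m in roi_masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != stack.shape[1:]:
            raise ValueError("ROI mask shape does not match the frame shape")
        if not m.any():
            raise ValueError("empty ROI")
        traces.append(stack[:, m].mean(axis=1))
    per_roi = np.array(traces)
    return per_roi, per_roi.mean(axis=0)


def compute_ratio(
    f490: np.ndarray, f420: np.ndarray, floor: float = 1e-12
) -> np.ndarray:
    """490/420 excitation ratio; samples with f420 below ``floor`` are masked
    (NaN) with a warning rather than producing unbounded values."""
    f490 = np.asarray(f490, dtype=float)
    f420 = np.asarray(f420, dtype=float)
    bad = f420 < floor
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} samples have f420 below the floor and were masked",
            stacklevel=2,
        )
    out = np.divide(f490, f420, out=np.full_like(f490, np.nan), where=~bad)
    return out


def dff_trace(
    f: np.ndarray, time: np.ndarray, prestim_window: tuple[float, float]
) -> np.ndarray:
    """Single-channel F/F₀ trace (F₀ = pre-stimulus mean), for cytosolic dyes."""
    f = np.asarray(f, dtype=float)
    idx = _window_indices(np.asarray(time, dtype=float), prestim_window)
    if idx.size == 0:
        raise ValueError("pre-stimulus window contains no frames")
    f0 = f[idx].mean()
    if f0 <= 0:
        raise ValueError("pre-stimulus mean must be positive for F/F0")
    return f / f0


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    # reflect-pad so the peak region is not attenuated at the record edges
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: len(x)]


def transient_metrics(
    ratio: np.ndarray,
    time: np.ndarray,
    stimulus_time: float,
    prestim_window: tuple[float, float] | None = None,
    k: float = DETECTION_K,
    smooth_window: int = PEAK_SMOOTH_WINDOW,
    peak_window_s: float | None = None,
) -> TransientMetrics:
    """Resting level, peak amplitude and detection flag of a ratio record.

    Resting level is the mean ratio over the pre-stimulus window (all frames
    before the stimulus when ``prestim_window`` is None). The peak is read
    from a lightly smoothed copy of the post-stimulus trace (centered moving
    average, ``smooth_window`` frames; 1 disables): the raw maximum of a few
    hundred noisy frames is biased upward by selection, which would break
    amplitude recovery and detection calibration. A transient is detected iff
    the amplitude exceeds ``k`` times the raw pre-stimulus SD.
    """
    ratio = np.asarray(ratio, dtype=float)
    time = np.asarray(time, dtype=float)
    if time[-1] < stimulus_time:
        raise ValueError("record ends before the stimulus")
    if prestim_window is None:
        prestim_window = (time[0], stimulus_time - 1e-9)
    pre = _window_indices(time, prestim_window)
    if pre.size == 0:
        raise ValueError("pre-stimulus window contains no frames")
    if prestim_window[1] >= stimulus_time:
        raise ValueError("pre-stimulus window must end before the stimulus")
    resting = float(np.nanmean(ratio[pre]))
    prestim_sd = float(np.nanstd(ratio[pre], ddof=1)) if pre.size > 1 else 0.0

    post = time > stimulus_time
    if peak_window_s is not None:
        post &= time <= stimulus_time + peak_window_s
    if not post.any():
        raise ValueError("no post-stimulus frames to search for a peak")
    smoothed = _moving_average(np.nan_to_num(ratio, nan=resting), smooth_window)
    ipost = np.flatnonzero(post)
    ipeak = ipost[int(np.argmax(smoothed[ipost]))]
    amplitude = float(smoothed[ipeak] - resting)
    return TransientMetrics(
        resting_level=resting,
        peak_amplitude=amplitude,
        time_to_peak=float(time[ipeak] - stimulus_time),
        detected=bool(amplitude > k * prestim_sd),
        prestim_sd=prestim_sd,
        k=k,
    )
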