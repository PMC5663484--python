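"""Breath extraction: preprocessing, peak detection, IBI/RV series construction.

The detector is deliberately simple and robust to uncalibrated units: the
signal is zero-phase high-passed (so peak times are not shifted by filter
delay) and lightly smoothed, local maxima are accepted if their prominence
exceeds a fraction of the window's robust amplitude, and a refractory period
suppresses secondary maxima within one breath (the higher peak wins; on an
exact tie the earlier one is kept).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .exceptions import InsufficientDataError, ParameterError
from .signals import BreathSeries, RespiratorySignal

__all__ = [
    "DetectionParams",
    "preprocess",
    "detect_breath_peaks",
    "build_breath_series",
    "series_summary",
    "extract_breaths",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the breath detector.

    ``min_prominence`` is relative to the robust window amplitude
    (4 x 1.4826 x MAD); ``refractory`` is the minimal peak spacing in seconds
    (default 0.15 s, i.e. a ceiling of ~6.7 breaths/s, well above guinea-pig
    rates); ``smoothing_width`` is the moving-average width in seconds.
    """

    highpass_cutoff: float = 0.1
    min_prominence: float = 0.3
    refractory: float = 0.15
    smoothing_width: float = 0.02

    def __post_init__(self):
        if self.refractory <= 0:
            raise ParameterError("refractory must be positive")
        if not (0.0 < self.min_prominence < 1.0):
            raise ParameterError("min_prominence must lie in (0, 1)")
        if self.highpass_cutoff < 0:
            raise ParameterError("highpass_cutoff must be >= 0")
        if self.smoothing_width < 0:
            raise ParameterError("smoothing_width must be >= 0")


def preprocess(signal: RespiratorySignal, params: DetectionParams = DetectionParams()) -> RespiratorySignal:
    """Remove baseline drift and high-frequency noise, preserving peak times.

    High-pass: 2nd-order Butterworth applied forward-backward (zero phase).
    Smoothing: centred moving average of ``smoothing_width`` seconds.
    Length is preserved.
    """
    fs = signal.fs
    if params.highpass_cutoff >= fs / 2:
        raise ParameterError(
            f"highpass cutoff {params.highpass_cutoff} Hz >= Nyquist ({fs / 2} Hz)"
        )
    x = signal.samples
    if params.highpass_cutoff > 0:
        sos = sps.butter(2, params.highpass_cutoff, btype="highpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    width = int(round(params.smoothing_width * fs))
    if width > 1:
        x = ndimage.uniform_filter1d(x, size=width, mode="nearest")
    return RespiratorySignal(
        samples=x, fs=fs, start_offset=signal.start_offset, metadata=dict(signal.metadata)
    )


def robust_amplitude(x: np.ndarray) -> float:
    """Robust amplitude scale of a window: 4 x 1.4826 x MAD."""
    return 4.0 * 1.4826 * float(np.median(np.abs(x - np.median(x))))


def detect_breath_peaks(
    signal: RespiratorySignal, params: DetectionParams = DetectionParams()
) -> np.ndarray:
    """Detect breath peaks in a preprocessed signal; returns sample indices.

    Local maxima with prominence >= ``min_prominence x robust amplitude`` are
    candidates; candidates closer than the refractory period are resolved
    greedily by height (ties by earlier index). A flat signal yields an empty
    array, not an error.
    """
    x = signal.samples
    scale = robust_amplitude(x)
    if scale == 0.0:
        return np.array([], dtype=int)
    candidates, props = sps.find_peaks(x, prominence=params.min_prominence * scale)
    if candidates.size == 0:
        return candidates
    # greedy refractory resolution: higher peak wins, exact tie -> earlier
    min_gap = params.refractory * signal.fs
    order = np.lexsort((candidates, -x[candidates]))
    accepted: list = []
    for idx in candidates[order]:
        pos = bisect.bisect_left(accepted, idx)
        left_ok = pos == 0 or idx - accepted[pos - 1] >= min_gap
        right_ok = pos == len(accepted) or accepted[pos] - idx >= min_gap
        if left_ok and right_ok:
            accepted.insert(pos, int(idx))
    return np.array(accepted, dtype=int)


def build_breath_series(signal: RespiratorySignal, peaks: np.ndarray) -> BreathSeries:
    """Turn detected peaks into the IBI/RV series.

    ``ibi_k = (t_{k+1} - t_k)``; ``rv_k`` is the signal value at peak k minus
    the minimum of the signal between its neighbouring peaks (leading and
    trailing peaks use their single adjacent trough). Requires >= 3 peaks.
    """
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size < 3:
        raise InsufficientDataError(f"need >= 3 breath peaks, found {peaks.size}")
    x = signal.samples
    fs = signal.fs
    troughs = np.array(
        [np.min(x[peaks[k] : peaks[k + 1] + 1]) for k in range(peaks.size - 1)]
    )
    baseline = np.empty(peaks.size)
    baseline[0] = troughs[0]
    baseline[-1] = troughs[-1]
    baseline[1:-1] = np.minimum(troughs[:-1], troughs[1:])
    rv = x[peaks] - baseline
    peak_times = signal.start_offset + peaks / fs
    return BreathSeries(
        ibi=np.diff(peak_times),
        rv=rv,
        peak_times=peak_times,
        metadata=dict(signal.metadata),
    )


def series_summary(series: BreathSeries):
    """(mean_ibi, cv_ibi, mean_rv, cv_rv); CV = sample SD (ddof=1) / mean."""
    mean_ibi = float(np.mean(series.ibi))
    mean_rv = float(np.mean(series.rv))
    if mean_ibi == 0 or mean_rv == 0:
        raise ParameterError("CV undefined for zero mean")
    cv_ibi = float(np.std(series.ibi, ddof=1) / mean_ibi)
    cv_rv = float(np.std(series.rv, ddof=1) / mean_rv)
    return mean_ibi, cv_ibi, mean_rv, cv_rv


def detection_f1(truth_times, detected_times, tolerance: float = 0.1):
    """F1 score of detected peak times against ground truth.

    Greedy one-to-one matching in time order; a detection matches a true
    peak if within ``tolerance`` seconds. Returns ``(f1, precision, recall)``.
    """
    truth = np.sort(np.asarray(truth_times, dtype=float))
    det = np.sort(np.asarray(detected_times, dtype=float))
    i = j = tp = 0
    while i < truth.size and j < det.size:
        dt = det[j] - truth[i]
        if abs(dt) <= tolerance:
            tp += 1
            i += 1
            j += 1
        elif dt < 0:
            j += 1
        else:
            i += 1
    precision = tp / det.size if det.size else 0.0
    recall = tp / truth.size if truth.size else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return f1, precision, recall


def extract_breaths(
    signal: RespiratorySignal, params: DetectionParams = DetectionParams()
) -> BreathSeries:
    """Convenience chain: preprocess -> detect -> build series."""
    cleaned = preprocess(signal, params)
    peaks = detect_breath_peaks(cleaned, params)
    return build_breath_series(cleaned, peaks)
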