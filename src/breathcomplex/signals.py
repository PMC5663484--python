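"""Core data containers: respiratory signals, breath series, analysis windows.

Conventions used throughout the package: 0-based sample indexing, half-open
windows ``[start, start + duration * fs)``, times in seconds, pressure and
breath amplitudes in arbitrary (uncalibrated plethysmograph) units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError, DataError


@dataclass
class RespiratorySignal:
    """A uniformly sampled respiratory pressure trace.

    Parameters
    ----------
    samples : ndarray
        Pressure samples, arbitrary units.
    fs : float
        Sampling rate in Hz.
    start_offset : float
        Time of the first sample relative to the recording start, seconds.
    metadata : dict
        Free-form key/value pairs (subject id, group label, ...).
    """

    samples: np.ndarray
    fs: float
    start_offset: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ParameterError("signal samples must be one-dimensional")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        bad = np.flatnonzero(~np.isfinite(self.samples))
        if bad.size:
            raise DataError(
                f"non-finite sample at index {bad[0]} (0-based); signals must be finite"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (start_offset + k / fs)."""
        return self.start_offset + np.arange(self.samples.size) / self.fs

    def slice(self, start_index: int, n_samples: int) -> "RespiratorySignal":
        """Half-open slice [start_index, start_index + n_samples)."""
        if start_index < 0 or start_index + n_samples > self.samples.size:
            raise ParameterError("slice extends outside the signal")
        return RespiratorySignal(
            samples=self.samples[start_index : start_index + n_samples].copy(),
            fs=self.fs,
            start_offset=self.start_offset + start_index / self.fs,
            metadata=dict(self.metadata),
        )


@dataclass
class BreathSeries:
    """Paired inter-breath-interval (IBI) and respiratory-volume (RV) series.

    For ``n`` breath peaks: ``peak_times`` and ``rv`` have length ``n`` while
    ``ibi`` (successive peak-to-peak intervals, seconds) has length ``n - 1``.
    RV is the peak amplitude measured from the local baseline, arbitrary units.
    """

    ibi: np.ndarray
    rv: np.ndarray
    peak_times: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ibi = np.asarray(self.ibi, dtype=float)
        self.rv = np.asarray(self.rv, dtype=float)
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if len(self.ibi) != len(self.peak_times) - 1:
            raise ParameterError(
                f"ibi length {len(self.ibi)} != n_peaks - 1 = {len(self.peak_times) - 1}"
            )
        if len(self.rv) != len(self.peak_times):
            raise ParameterError("rv must have one value per peak")
        if np.any(self.ibi <= 0):
            raise ParameterError("all inter-breath intervals must be positive")
        if np.any(self.rv <= 0):
            raise ParameterError("all breath amplitudes must be positive")
        if np.any(np.diff(self.peak_times) <= 0):
            raise ParameterError("peak times must be strictly increasing")

    @property
    def n_breaths(self) -> int:
        return len(self.peak_times)


@dataclass
class AnalysisWindow:
    """The selected analysis window of a recording.

    ``start_index`` is a 0-based sample index; the window covers the half-open
    sample range ``[start_index, start_index + duration * fs)``.
    ``artifact_score`` is the (non-negative) score under which this window was
    chosen; lower is cleaner.
    """

    start_index: int
    duration: float
    artifact_score: float

    def __post_init__(self):
        if self.start_index < 0:
            raise ParameterError("window start index must be >= 0")
        if self.duration <= 0:
            raise ParameterError("window duration must be positive")
        if self.artifact_score < 0:
            raise ParameterError("artifact score must be >= 0")
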