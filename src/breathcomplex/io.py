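"""Reading/writing respiratory signals and breath series; analysis-window selection.

On-disk formats (all UTF-8 plain text):

* **Signal CSV** — one header line ``# fs=<Hz>`` followed by one sample value
  per line (or two comma-separated columns ``time,value``; the time column is
  ignored apart from establishing ``start_offset``). Written at 17 significant
  digits so a write/read round trip is lossless.
* **Breath-series TSV** — header ``ibi_s\trv_au\tpeak_time_s``; the first row
  has an empty ``ibi_s`` field (n peaks yield n-1 intervals).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .exceptions import (
    DataError,
    FormatError,
    InsufficientDataError,
    ParameterError,
)
from .signals import AnalysisWindow, BreathSeries, RespiratorySignal

__all__ = [
    "read_signal",
    "write_signal",
    "read_breath_series",
    "write_breath_series",
    "select_analysis_window",
    "artifact_score",
]


def read_signal(path, format: str = "csv") -> RespiratorySignal:
    """Read a respiratory signal from disk.

    Raises :class:`FormatError` if the ``# fs=<Hz>`` header is missing and
    :class:`DataError` (naming the first offending 0-based sample index) if
    any sample is non-finite.
    """
    if format != "csv":
        raise ParameterError(f"unsupported signal format {format!r}")
    fs = None
    values = []
    start_offset = 0.0
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("#") or "fs=" not in first:
            raise FormatError(f"{path}: missing '# fs=<Hz>' header line")
        try:
            fs = float(first.split("fs=")[1].split()[0])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: cannot parse sampling rate from {first!r}") from exc
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(",")
            try:
                if len(fields) == 1:
                    values.append(float(fields[0]))
                elif len(fields) == 2:
                    if not values:
                        start_offset = float(fields[0])
                    values.append(float(fields[1]))
                else:
                    raise FormatError(f"{path}: expected 1 or 2 columns, got {len(fields)}")
            except ValueError:
                values.append(np.nan)  # caught below with the right index
    samples = np.asarray(values, dtype=float)
    if samples.size == 0:
        raise FormatError(f"{path}: no samples")
    bad = np.flatnonzero(~np.isfinite(samples))
    if bad.size:
        raise DataError(f"{path}: non-finite sample at index {bad[0]} (0-based)")
    return RespiratorySignal(samples=samples, fs=fs, start_offset=start_offset)


def write_signal(signal: RespiratorySignal, path, format: str = "csv") -> None:
    """Write a signal; inverse of :func:`read_signal`, lossless for csv."""
    if format != "csv":
        raise ParameterError(f"unsupported signal format {format!r}")
    if signal.samples.size == 0:
        raise FormatError("refusing to write an empty signal")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs={signal.fs:.17g}\n")
        for v in signal.samples:
            fh.write(f"{v:.17g}\n")


def write_breath_series(series: BreathSeries, path) -> None:
    """Write a breath series as a 3-column TSV (ibi_s, rv_au, peak_time_s)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ibi_s\trv_au\tpeak_time_s\n")
        for k in range(series.n_breaths):
            ibi = "" if k == 0 else f"{series.ibi[k - 1]:.17g}"
            fh.write(f"{ibi}\t{series.rv[k]:.17g}\t{series.peak_times[k]:.17g}\n")


def read_breath_series(path) -> BreathSeries:
    """Read a breath series written by :func:`write_breath_series`."""
    ibi, rv, times = [], [], []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip().split("\t")
        if header[:2] != ["ibi_s", "rv_au"]:
            raise FormatError(f"{path}: unexpected breath-series header {header}")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}: expected 3 tab-separated columns")
            if fields[0] != "":
                ibi.append(float(fields[0]))
            rv.append(float(fields[1]))
            times.append(float(fields[2]))
    return BreathSeries(ibi=np.array(ibi), rv=np.array(rv), peak_times=np.array(times))


# ---------------------------------------------------------------------------
# Analysis-window selection

def artifact_score(
    window: np.ndarray,
    fs: float,
    band=(0.5, 5.0),
    amplitude_weight: float = 0.5,
    spectral_weight: float = 0.5,
) -> float:
    """Two-term artifact score of a signal window (lower = cleaner).

    ``amplitude_weight x`` (fraction of samples farther than 5 robust SD from
    the window median) ``+ spectral_weight x`` (fraction of non-DC power
    outside the breathing band). The robust SD is 1.4826 x MAD. The default
    band 0.5-5 Hz brackets guinea-pig respiratory rates (~1-3 Hz).
    """
    med = np.median(window)
    robust_sd = 1.4826 * np.median(np.abs(window - med))
    if robust_sd > 0:
        amp_frac = np.mean(np.abs(window - med) > 5.0 * robust_sd)
    else:
        amp_frac = 0.0

    nperseg = min(window.size, 8192)
    freqs, psd = sps.welch(window, fs=fs, nperseg=nperseg, detrend="constant")
    nz = freqs > 0
    total = np.sum(psd[nz])
    if total > 0:
        out_of_band = nz & ((freqs < band[0]) | (freqs > band[1]))
        spec_frac = np.sum(psd[out_of_band]) / total
    else:
        spec_frac = 0.0
    return float(amplitude_weight * amp_frac + spectral_weight * spec_frac)


def select_analysis_window(
    signal: RespiratorySignal,
    duration: float = 1200.0,
    hop: float = 30.0,
    band=(0.5, 5.0),
    amplitude_weight: float = 0.5,
    spectral_weight: float = 0.5,
) -> AnalysisWindow:
    """Select the lowest-artifact window of the given duration.

    A window of ``duration`` seconds slides over the recording in steps of
    ``hop`` seconds; the window with the minimal :func:`artifact_score` is
    returned, ties broken by the earliest start.
    """
    n_win = int(round(duration * signal.fs))
    if n_win > signal.n_samples:
        raise InsufficientDataError(
            f"signal of {signal.duration:.0f}s shorter than the {duration:.0f}s window"
        )
    step = max(1, int(round(hop * signal.fs)))
    starts = list(range(0, signal.n_samples - n_win + 1, step))
    scores = np.array(
        [
            artifact_score(
                signal.samples[s : s + n_win],
                signal.fs,
                band=band,
                amplitude_weight=amplitude_weight,
                spectral_weight=spectral_weight,
            )
            for s in starts
        ]
    )
    best = int(np.argmin(scores))  # argmin returns the earliest minimum
    return AnalysisWindow(
        start_index=starts[best], duration=duration, artifact_score=float(scores[best])
    )
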