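"""Complexity measures for breath series: SampEn, cross-SampEn, and DFA.

Sample entropy (SampEn) is the negative natural logarithm of the conditional
probability that two subsequences of length ``m`` that match within a
tolerance ``r`` still match when extended to length ``m + 1``, with
self-matches excluded. Lower SampEn means a more regular (more predictable)
series. Matching uses the Chebyshev (max-coordinate) distance and the
tolerance is expressed as a fraction of the series' sample SD, the
established convention for physiological series, so the measure is invariant
under affine rescaling of the data.

Cross-sample entropy applies the same match-counting across two series to
quantify their *asynchrony*: both series are z-normalized independently
(their units are incommensurate — seconds vs. arbitrary amplitude), every
(i, j) template pair between the two series is compared, and larger values
indicate fewer shared sub-patterns (more asynchrony); smaller values indicate
stronger synchronization. The definition is symmetric in its arguments.

Detrended fluctuation analysis (DFA) integrates the mean-centred series,
splits the profile into non-overlapping windows of varying size (taken from
both the start and the end so no tail is discarded), removes a least-squares
polynomial trend per window, and regresses log RMS fluctuation on log window
size. The slope is the scaling exponent alpha: 0.5 for uncorrelated noise,
>0.5 for persistent long-range correlation, ~1.5 for integrated noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist, pdist

from .exceptions import DegenerateSeriesError, InsufficientDataError, ParameterError
from .signals import BreathSeries

__all__ = [
    "EntropyParams",
    "DfaParams",
    "ComplexityProfile",
    "sample_entropy",
    "cross_sample_entropy",
    "dfa",
    "complexity_profile",
]


@dataclass(frozen=True)
class EntropyParams:
    """SampEn parameters: embedding dimension ``m`` and tolerance ``r``
    (as a fraction of the series' sample SD)."""

    m: int = 2
    r: float = 0.2

    def __post_init__(self):
        if self.m < 1:
            raise ParameterError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ParameterError("tolerance r must be positive")


@dataclass(frozen=True)
class DfaParams:
    """DFA parameters.

    ``max_scale=None`` means n // 4 at call time. ``n_scales`` log-spaced
    window sizes are used (duplicate integers removed); ``detrend_order`` is
    the per-window polynomial order (1 = classic DFA-1).
    """

    min_scale: int = 4
    max_scale: Optional[int] = None
    n_scales: int = 16
    detrend_order: int = 1

    def __post_init__(self):
        if self.min_scale < 4:
            raise ParameterError("min_scale must be >= 4")
        if self.max_scale is not None and self.max_scale <= self.min_scale:
            raise ParameterError("max_scale must exceed min_scale")
        if self.n_scales < 6:
            raise ParameterError("n_scales must be >= 6")
        if self.detrend_order < 0:
            raise ParameterError("detrend_order must be >= 0")


@dataclass
class ComplexityProfile:
    """Per-recording complexity metric bundle.

    Entropies in nats; ``alpha_*`` are DFA scaling exponents. A non-finite
    entropy marks the 'no template matches' condition, treated as missing by
    the group statistics.
    """

    mean_ibi: float
    cv_ibi: float
    mean_rv: float
    cv_rv: float
    sampen_ibi: float
    sampen_rv: float
    alpha_ibi: float
    alpha_rv: float
    cross_sampen: float
    n_breaths: int

    METRICS = (
        "mean_ibi", "cv_ibi", "mean_rv", "cv_rv",
        "sampen_ibi", "sampen_rv", "alpha_ibi", "alpha_rv", "cross_sampen",
    )

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.METRICS} | {
            "n_breaths": self.n_breaths
        }


# ---------------------------------------------------------------------------
# Sample entropy

def _match_counts(x: np.ndarray, m: int, r_abs: float):
    """Pair counts (B, A) of m- and (m+1)-template Chebyshev matches, i < j.

    Both counts use the first ``N - m`` template start positions, so every
    counted m-template has a defined (m+1)-extension (the standard
    Richman–Moorman convention); self-matches are excluded by i < j.
    """
    n = x.size
    nt = n - m
    tm = sliding_window_view(x, m)[:nt]
    tm1 = sliding_window_view(x, m + 1)
    b = int(np.sum(pdist(tm, "chebyshev") <= r_abs))
    a = int(np.sum(pdist(tm1, "chebyshev") <= r_abs))
    return b, a


def sample_entropy(x, params: EntropyParams = EntropyParams()) -> float:
    """SampEn(m, r) of a series, in nats.

    Returns 0.0 for a zero-variance series (every template matches) and
    ``math.inf`` when no (m+1)-template pair matches (the conditional
    probability is unestimable; downstream statistics treat it as missing).
    """
    x = np.asarray(x, dtype=float)
    m = params.m
    if x.size < m + 2:
        raise InsufficientDataError(f"need at least m + 2 = {m + 2} samples, got {x.size}")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return 0.0
    b, a = _match_counts(x, m, params.r * sd)
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


def cross_sample_entropy(x, y, params: EntropyParams = EntropyParams()) -> float:
    """Cross-SampEn(m, r) between two equal-length series, in nats.

    Each series is z-normalized independently (tolerance ``r`` is then in SD
    units); all (i, j) template pairs across the two series are counted, so
    the statistic is exactly symmetric in (x, y). Larger values = more
    asynchrony; 0.0 is returned if either series has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError(f"series lengths differ: {x.size} vs {y.size}")
    m = params.m
    if x.size < m + 2:
        raise InsufficientDataError(f"need at least m + 2 = {m + 2} samples, got {x.size}")
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0.0 or sy == 0.0:
        return 0.0
    zx = (x - np.mean(x)) / sx
    zy = (y - np.mean(y)) / sy
    nt = x.size - m
    xm = sliding_window_view(zx, m)[:nt]
    ym = sliding_window_view(zy, m)[:nt]
    b = int(np.sum(cdist(xm, ym, "chebyshev") <= params.r))
    xm1 = sliding_window_view(zx, m + 1)
    ym1 = sliding_window_view(zy, m + 1)
    a = int(np.sum(cdist(xm1, ym1, "chebyshev") <= params.r))
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


# ---------------------------------------------------------------------------
# Detrended fluctuation analysis

def _dfa_fluctuation(profile: np.ndarray, scale: int, order: int) -> float:
    """RMS detrended fluctuation at one window size (windows from both ends)."""
    n = profile.size
    nseg = n // scale
    design = np.vander(np.arange(scale, dtype=float), order + 1)
    proj = design @ np.linalg.pinv(design)
    sq = []
    for segs in (
        profile[: nseg * scale].reshape(nseg, scale),
        profile[n - nseg * scale :].reshape(nseg, scale),
    ):
        resid = segs.T - proj @ segs.T
        sq.append(np.mean(resid**2, axis=0))
    return float(np.sqrt(np.mean(np.concatenate(sq))))


def dfa(x, params: DfaParams = DfaParams()):
    """DFA scaling exponent of a series.

    Returns ``(alpha, scales, fluctuations)``: the exponent, the integer
    window sizes used, and F(s) at each. The series is mean-centred and
    integrated before windowing.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 * params.min_scale:
        raise InsufficientDataError(
            f"need at least 4 x min_scale = {4 * params.min_scale} samples, got {n}"
        )
    if np.std(x) == 0.0:
        raise DegenerateSeriesError("DFA undefined for a zero-variance series")
    max_scale = params.max_scale if params.max_scale is not None else n // 4
    max_scale = min(max_scale, n // 4)
    if max_scale <= params.min_scale:
        raise InsufficientDataError("max_scale does not exceed min_scale for this length")
    scales = np.unique(
        np.round(
            np.logspace(np.log10(params.min_scale), np.log10(max_scale), params.n_scales)
        ).astype(int)
    )
    scales = scales[(scales >= params.min_scale) & (scales >= params.detrend_order + 2)]
    if scales.size < 6:
        raise InsufficientDataError(f"only {scales.size} usable scales (< 6)")

    profile = np.cumsum(x - np.mean(x))
    fluct = np.array([_dfa_fluctuation(profile, int(s), params.detrend_order) for s in scales])
    good = fluct > 0
    if np.sum(good) < 6:
        raise DegenerateSeriesError("fewer than 6 scales with non-zero fluctuation")
    alpha = float(np.polyfit(np.log(scales[good]), np.log(fluct[good]), 1)[0])
    return alpha, scales[good], fluct[good]


# ---------------------------------------------------------------------------
# Per-recording profile

def complexity_profile(
    series: BreathSeries,
    eparams: EntropyParams = EntropyParams(),
    dparams: DfaParams = DfaParams(),
) -> ComplexityProfile:
    """All complexity metrics of one recording's breath series.

    Cross-SampEn aligns IBI and RV by dropping the last RV value (n peaks
    give n-1 intervals). Emits a validity warning — not an error — below 100
    breaths, where the entropy and DFA estimates become unstable.
    """
    from .extraction import series_summary  # local import to avoid a cycle

    if series.n_breaths < 100:
        warnings.warn(
            f"only {series.n_breaths} breaths; complexity metrics are unstable below 100",
            UserWarning,
            stacklevel=2,
        )
    mean_ibi, cv_ibi, mean_rv, cv_rv = series_summary(series)
    alpha_ibi, _, _ = dfa(series.ibi, dparams)
    alpha_rv, _, _ = dfa(series.rv, dparams)
    return ComplexityProfile(
        mean_ibi=mean_ibi,
        cv_ibi=cv_ibi,
        mean_rv=mean_rv,
        cv_rv=cv_rv,
        sampen_ibi=sample_entropy(series.ibi, eparams),
        sampen_rv=sample_entropy(series.rv, eparams),
        alpha_ibi=alpha_ibi,
        alpha_rv=alpha_rv,
        cross_sampen=cross_sample_entropy(series.ibi, series.rv[:-1], eparams),
        n_breaths=series.n_breaths,
    )
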