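"""Synthetic plethysmography with known ground-truth complexity.

This module generates respiratory recordings whose inter-breath intervals
(IBI) and breath amplitudes (RV) follow stochastic processes with
*controllable* irregularity, long-range correlation and coupling, so that
every downstream stage (window selection, breath detection, entropy and DFA
estimation, group statistics) can be validated against a known truth.

The generative model, per recording:

1. Fractional Gaussian noise (fGn) innovations with a chosen Hurst exponent
   are synthesised exactly by circulant embedding (Davies–Harte), so the
   target autocovariance holds by construction rather than by AR
   approximation — DFA of the output scales with alpha ~ H.
2. IBI and RV innovation streams share a common fGn component whose weight is
   ``coupling_rho`` (the shared-innovation fraction); at ``coupling_rho = 1``
   the two z-streams are identical, at 0 they are independent.
3. A ``regularity`` control blends both innovation streams with a strictly
   periodic (period-3, zero-mean, unit-variance) cycle using sqrt weights, so
   the blend lowers sample entropy while leaving each series' mean and CV
   unchanged. Because the cycle is shared in phase by the two channels,
   raising regularity also entrains amplitude to rhythm: cross-sample entropy
   falls (more synchronization). Plain Gaussian correlation between the
   channels barely moves cross-SampEn — off-diagonal template pairs dominate
   the match counts — so the shared deterministic rhythm is the generator's
   main synchronization mechanism.
4. Occasional deep inspirations (sighs) multiply the breath amplitude (and,
   optionally, the following interval) by a fixed factor.
5. Rendering turns each breath into a smooth unimodal pressure pulse at the
   cumulative IBI peak time, then adds Gaussian sensor noise, sinusoidal
   baseline drift and gain-multiplied artifact epochs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .exceptions import ConfigurationError, ParameterError
from .signals import BreathSeries, RespiratorySignal

__all__ = [
    "FgnSpec",
    "BreathProcessSpec",
    "RenderSpec",
    "SynthCohortConfig",
    "CohortRecording",
    "fgn_autocovariance",
    "generate_fgn",
    "generate_breath_series",
    "render_signal",
    "generate_cohort",
    "control_like_template",
    "asthma_like_template",
    "derive_seed",
]


# ---------------------------------------------------------------------------
# Specifications

@dataclass(frozen=True)
class FgnSpec:
    """Parameters of a fractional-Gaussian-noise draw.

    ``hurst`` in (0, 1); H = 0.5 is white noise, H > 0.5 persistent
    long-range correlation. ``mean``/``sd`` are the population moments of the
    returned samples.
    """

    n: int
    hurst: float
    mean: float = 0.0
    sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.hurst < 1.0):
            raise ParameterError(f"hurst must lie in (0, 1), got {self.hurst}")
        if self.sd <= 0:
            raise ParameterError(f"sd must be positive, got {self.sd}")
        if self.n < 16:
            raise ParameterError(f"n must be >= 16, got {self.n}")


@dataclass(frozen=True)
class BreathProcessSpec:
    """Generative parameters of one recording's breath point process.

    ``coupling_rho`` is the shared-innovation fraction between the IBI and RV
    streams (sign gives the direction); ``regularity`` in [0, 1] blends the
    IBI innovations toward a strictly periodic cycle (0 = fully stochastic,
    1 = strictly periodic), leaving mean and CV untouched.
    """

    n_breaths: int = 1000
    ibi_mean: float = 0.6
    ibi_cv: float = 0.1
    ibi_hurst: float = 0.6
    rv_mean: float = 1.0
    rv_cv: float = 0.1
    rv_hurst: float = 0.6
    coupling_rho: float = 0.2
    regularity: float = 0.1
    sigh_rate: float = 0.01
    sigh_amplitude_factor: float = 2.5
    sigh_prolongs_ibi: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_breaths < 4:
            raise ParameterError("n_breaths must be >= 4")
        if self.ibi_mean <= 0:
            raise ParameterError("ibi_mean must be positive")
        if self.rv_mean <= 0:
            raise ParameterError("rv_mean must be positive")
        if self.ibi_cv < 0 or self.rv_cv < 0:
            raise ParameterError("coefficients of variation must be >= 0")
        for name, h in (("ibi_hurst", self.ibi_hurst), ("rv_hurst", self.rv_hurst)):
            if not (0.0 < h < 1.0):
                raise ParameterError(f"{name} must lie in (0, 1), got {h}")
        if not (-1.0 <= self.coupling_rho <= 1.0):
            raise ParameterError("coupling_rho must lie in [-1, 1]")
        if not (0.0 <= self.regularity <= 1.0):
            raise ParameterError("regularity must lie in [0, 1]")
        if not (0.0 <= self.sigh_rate < 0.2):
            raise ParameterError("sigh_rate must lie in [0, 0.2)")
        if self.sigh_amplitude_factor <= 1.0:
            raise ParameterError("sigh_amplitude_factor must exceed 1")


@dataclass(frozen=True)
class RenderSpec:
    """How a breath series is rendered to a pressure trace.

    ``artifact_epochs`` is a list of ``(start_s, duration_s, gain)`` tuples;
    each epoch's samples are multiplied by ``gain`` (gain > 1 emulates
    movement artifact, gain < 1 a still/occluded period).
    """

    fs: float = 1000.0
    waveform: str = "raised_cosine"
    noise_sd: float = 0.0
    drift_amplitude: float = 0.0
    drift_period: float = 120.0
    artifact_epochs: tuple = ()

    def __post_init__(self):
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.waveform not in ("raised_cosine", "gaussian_pulse"):
            raise ParameterError(f"unknown waveform {self.waveform!r}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.drift_amplitude < 0:
            raise ParameterError("drift_amplitude must be >= 0")
        if self.drift_amplitude > 0 and self.drift_period <= 0:
            raise ParameterError("drift_period must be positive")
        epochs = sorted(self.artifact_epochs, key=lambda e: e[0])
        for start, dur, _gain in epochs:
            if start < 0 or dur <= 0:
                raise ConfigurationError("artifact epochs need start >= 0 and duration > 0")
        for (s0, d0, _), (s1, _, _) in zip(epochs, epochs[1:]):
            if s0 + d0 > s1:
                raise ConfigurationError("artifact epochs must not overlap")
        object.__setattr__(self, "artifact_epochs", tuple(epochs))


@dataclass(frozen=True)
class SynthCohortConfig:
    """Group-wise generative design of a synthetic cohort.

    ``groups`` maps a group label to the BreathProcessSpec template used for
    every animal in that group; per-recording seeds are derived
    deterministically from ``master_seed`` (see :func:`derive_seed`).
    """

    groups: dict
    n_per_group: int = 10
    record_duration: float = 3600.0
    render: RenderSpec = field(default_factory=RenderSpec)
    master_seed: int = 0

    def __post_init__(self):
        labels = list(self.groups)
        if len(labels) != len(set(labels)):
            raise ConfigurationError("duplicate group labels in cohort config")
        if len(labels) == 0:
            raise ConfigurationError("cohort needs at least one group")
        if self.n_per_group < 1:
            raise ParameterError("n_per_group must be >= 1")
        if self.record_duration <= 0:
            raise ParameterError("record_duration must be positive")


@dataclass
class CohortRecording:
    """One rendered recording plus its generative ground truth."""

    subject_id: str
    group: str
    signal: RespiratorySignal
    truth: BreathSeries


# ---------------------------------------------------------------------------
# Fractional Gaussian noise

def fgn_autocovariance(hurst: float, lags, sd: float = 1.0) -> np.ndarray:
    """Closed-form fGn autocovariance gamma(k) = sd^2/2 (|k+1|^2H - 2|k|^2H + |k-1|^2H)."""
    k = np.abs(np.asarray(lags, dtype=float))
    two_h = 2.0 * hurst
    return 0.5 * sd**2 * ((k + 1) ** two_h - 2 * k**two_h + np.abs(k - 1) ** two_h)


def generate_fgn(spec: FgnSpec) -> np.ndarray:
    """Exact synthesis of fractional Gaussian noise by circulant embedding.

    The covariance of the output matches :func:`fgn_autocovariance` exactly
    (Davies–Harte construction), so DFA on the result scales with
    alpha ~ hurst without AR-fit bias. Deterministic given ``spec.seed``.
    """
    n = spec.n
    gamma = fgn_autocovariance(spec.hurst, np.arange(n + 1))
    # first row of the 2n x 2n circulant embedding
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    m = row.size  # 2n
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        raise ParameterError(
            f"circulant embedding not nonnegative definite for hurst={spec.hurst}"
        )
    lam = np.clip(lam, 0.0, None)

    rng = np.random.default_rng(spec.seed)
    w = np.zeros(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * rng.standard_normal()
    w[n] = np.sqrt(lam[n] / m) * rng.standard_normal()
    u = rng.standard_normal(n - 1)
    v = rng.standard_normal(n - 1)
    w[1:n] = np.sqrt(lam[1:n] / (2 * m)) * (u + 1j * v)
    w[n + 1 :] = np.conj(w[n - 1 : 0 : -1])
    x = np.fft.fft(w).real[:n]
    return spec.mean + spec.sd * x


# ---------------------------------------------------------------------------
# Breath point process

#: zero-mean, unit-variance period-3 cycle used by the regularity blend
_CYCLE = np.array([-1.0, 0.0, 1.0]) * np.sqrt(1.5)


def _sub_seeds(seed: int, count: int) -> list:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(count)]


def generate_breath_series(spec: BreathProcessSpec) -> BreathSeries:
    """Draw one recording's IBI/RV breath series from the generative model.

    ``IBI_k = ibi_mean * (1 + ibi_cv * zx_k)`` and analogously for RV, where
    the z-innovations are built as described in the module docstring. IBI is
    floored at ``0.2 * ibi_mean`` (and RV at ``0.05 * rv_mean``) to keep both
    positive; the number of floored values is recorded in the metadata.
    """
    n = spec.n_breaths
    seed_x, seed_y, seed_c, seed_sigh = _sub_seeds(spec.seed, 4)
    shared_hurst = 0.5 * (spec.ibi_hurst + spec.rv_hurst)
    e_x = generate_fgn(FgnSpec(n=max(n, 16), hurst=spec.ibi_hurst, seed=seed_x))[:n]
    e_y = generate_fgn(FgnSpec(n=max(n, 16), hurst=spec.rv_hurst, seed=seed_y))[:n]
    e_c = generate_fgn(FgnSpec(n=max(n, 16), hurst=shared_hurst, seed=seed_c))[:n]

    a = abs(spec.coupling_rho)
    sign = 1.0 if spec.coupling_rho >= 0 else -1.0
    zx = np.sqrt(1.0 - a) * e_x + np.sqrt(a) * e_c
    zy = np.sqrt(1.0 - a) * e_y + sign * np.sqrt(a) * e_c

    # variance-preserving blend toward a strictly periodic rhythm; the cycle
    # is shared (same phase) by both channels, so raising regularity also
    # entrains amplitude to rhythm (stronger synchronization)
    reg = spec.regularity
    cycle = np.resize(_CYCLE, n)
    zx = np.sqrt(1.0 - reg) * zx + np.sqrt(reg) * cycle
    zy = np.sqrt(1.0 - reg) * zy + np.sqrt(reg) * cycle

    ibi = spec.ibi_mean * (1.0 + spec.ibi_cv * zx[: n - 1])
    rv = spec.rv_mean * (1.0 + spec.rv_cv * zy)

    ibi_floor = 0.2 * spec.ibi_mean
    rv_floor = 0.05 * spec.rv_mean
    n_ibi_floored = int(np.sum(ibi < ibi_floor))
    n_rv_floored = int(np.sum(rv < rv_floor))
    ibi = np.maximum(ibi, ibi_floor)
    rv = np.maximum(rv, rv_floor)

    rng_sigh = np.random.default_rng(seed_sigh)
    sigh_mask = rng_sigh.random(n) < spec.sigh_rate
    rv = np.where(sigh_mask, rv * spec.sigh_amplitude_factor, rv)
    if spec.sigh_prolongs_ibi:
        prolong = sigh_mask[: n - 1]
        ibi = np.where(prolong, ibi * spec.sigh_amplitude_factor, ibi)

    peak_times = spec.ibi_mean + np.concatenate([[0.0], np.cumsum(ibi)])
    return BreathSeries(
        ibi=ibi,
        rv=rv,
        peak_times=peak_times,
        metadata={
            "n_ibi_floored": n_ibi_floored,
            "n_rv_floored": n_rv_floored,
            "n_sighs": int(sigh_mask.sum()),
            "seed": spec.seed,
        },
    )


# ---------------------------------------------------------------------------
# Rendering

def _pulse_half_widths(peak_times: np.ndarray, ibi_scale: float) -> np.ndarray:
    """Per-breath pulse half-width: 45% of the smaller adjacent gap (capped).

    Adjacent pulses then occupy at most 90% of their gap, so supports never
    overlap and each rendered maximum equals its ground-truth amplitude.
    """
    gaps = np.diff(peak_times)
    left = np.concatenate([[np.inf], gaps])
    right = np.concatenate([gaps, [np.inf]])
    h = 0.45 * np.minimum(left, right)
    return np.minimum(h, 0.45 * ibi_scale)


def render_signal(
    series: BreathSeries,
    render: RenderSpec,
    seed: Optional[int] = None,
    duration: Optional[float] = None,
):
    """Render a breath series to a pressure trace.

    Each breath becomes one smooth unimodal pulse (raised cosine or truncated
    Gaussian) of peak amplitude ``rv_k`` centred at ``peak_times[k]``; sensor
    noise, baseline drift and artifact epochs are applied afterwards.

    Returns ``(signal, truth)`` where ``truth`` is the breath series actually
    rendered (trailing breaths that do not fit inside ``duration`` are
    dropped, and the returned ground truth reflects that).

    Raises
    ------
    ConfigurationError
        If the series needs more than twice the requested ``duration``, or an
        artifact epoch lies outside the record.
    """
    fs = render.fs
    ibi_scale = float(np.median(series.ibi))
    half = _pulse_half_widths(series.peak_times, ibi_scale)
    natural = series.peak_times[-1] + half[-1] + 2.0 / fs

    if duration is None:
        duration = natural
    elif natural > 2.0 * duration:
        raise ConfigurationError(
            f"series spans {natural:.1f}s, more than twice the requested {duration:.1f}s"
        )

    fits = series.peak_times + half <= duration
    n_keep = series.n_breaths if fits.all() else int(np.argmax(~fits))
    if n_keep < 3:
        raise ConfigurationError("fewer than 3 breaths fit in the requested duration")
    truth = BreathSeries(
        ibi=series.ibi[: n_keep - 1],
        rv=series.rv[:n_keep],
        peak_times=series.peak_times[:n_keep],
        metadata=dict(series.metadata),
    )

    n_samples = int(round(duration * fs))
    x = np.zeros(n_samples)
    for t_k, a_k, h_k in zip(truth.peak_times, truth.rv, half[:n_keep]):
        if render.waveform == "raised_cosine":
            lo = max(0, int(np.ceil((t_k - h_k) * fs)))
            hi = min(n_samples, int(np.floor((t_k + h_k) * fs)) + 1)
            t = np.arange(lo, hi) / fs
            x[lo:hi] += a_k * 0.5 * (1.0 + np.cos(np.pi * (t - t_k) / h_k))
        else:  # gaussian_pulse, truncated at 4 sigma
            sigma = h_k / 4.0
            lo = max(0, int(np.ceil((t_k - 4 * sigma) * fs)))
            hi = min(n_samples, int(np.floor((t_k + 4 * sigma) * fs)) + 1)
            t = np.arange(lo, hi) / fs
            x[lo:hi] += a_k * np.exp(-0.5 * ((t - t_k) / sigma) ** 2)

    t_all = np.arange(n_samples) / fs
    if render.drift_amplitude > 0:
        x = x + render.drift_amplitude * np.sin(2 * np.pi * t_all / render.drift_period)
    if render.noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + render.noise_sd * rng.standard_normal(n_samples)
    for start, dur, gain in render.artifact_epochs:
        if start + dur > duration + 1e-9:
            raise ConfigurationError("artifact epoch extends past the record end")
        i0, i1 = int(round(start * fs)), int(round((start + dur) * fs))
        x[i0:i1] *= gain

    signal = RespiratorySignal(samples=x, fs=fs, metadata=dict(series.metadata))
    return signal, truth


# ---------------------------------------------------------------------------
# Cohorts

def derive_seed(master_seed: int, group: str, index: int) -> int:
    """Deterministic per-recording seed: SHA-256 of (master_seed, group, index)."""
    digest = hashlib.sha256(f"{master_seed}/{group}/{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def control_like_template(**overrides) -> BreathProcessSpec:
    """Breath-process template emulating healthy (saline-exposed) dynamics.

    Irregular rhythm (low regularity), mildly persistent intervals
    (H = 0.6), serially uncorrelated amplitudes (H = 0.5), weak IBI–RV
    coupling, a deep inspiration roughly every two minutes.
    """
    params = dict(
        ibi_mean=0.6, ibi_cv=0.10, ibi_hurst=0.6,
        rv_mean=1.0, rv_cv=0.15, rv_hurst=0.5,
        coupling_rho=0.2, regularity=0.1,
        sigh_rate=0.005, sigh_amplitude_factor=2.0,
    )
    params.update(overrides)
    return BreathProcessSpec(**params)


def asthma_like_template(**overrides) -> BreathProcessSpec:
    """Breath-process template emulating allergen-exposed (asthmatic) dynamics.

    Relative to :func:`control_like_template`: more regular rhythm (lower
    SampEn_IBI), raised IBI variability (CV x 1.5), stronger long-range
    correlation in amplitude (rv_hurst = 0.9, higher DFA alpha_RV) and
    stronger IBI-RV coupling (lower cross-SampEn). Means are unchanged.
    """
    params = dict(
        ibi_mean=0.6, ibi_cv=0.15, ibi_hurst=0.6,
        rv_mean=1.0, rv_cv=0.15, rv_hurst=0.9,
        coupling_rho=0.8, regularity=0.6,
        sigh_rate=0.005, sigh_amplitude_factor=2.0,
    )
    params.update(overrides)
    return BreathProcessSpec(**params)


def generate_cohort(cfg: SynthCohortConfig) -> list:
    """Generate all recordings of a synthetic cohort.

    Returns a list of :class:`CohortRecording`; fully reproducible from
    ``cfg.master_seed`` (per-recording seeds are content-derived, so streams
    are independent across recordings and stable under re-ordering).
    """
    recordings = []
    for group, template in cfg.groups.items():
        for index in range(cfg.n_per_group):
            seed = derive_seed(cfg.master_seed, group, index)
            n_breaths = int(np.ceil(1.02 * cfg.record_duration / template.ibi_mean)) + 8
            spec = replace(template, n_breaths=n_breaths, seed=seed)
            series = generate_breath_series(spec)
            noise_seed = derive_seed(cfg.master_seed, group + "/noise", index)
            signal, truth = render_signal(
                series, cfg.render, seed=noise_seed, duration=cfg.record_duration
            )
            subject_id = f"{group}-{index:02d}"
            signal.metadata.update({"subject_id": subject_id, "group": group})
            truth.metadata.update({"subject_id": subject_id, "group": group})
            recordings.append(
                CohortRecording(subject_id=subject_id, group=group, signal=signal, truth=truth)
            )
    return recordings
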