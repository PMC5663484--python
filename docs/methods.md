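# Methods

## Scope and model

The package quantifies the complexity of respiratory dynamics from a single
pressure channel (whole-body plethysmography, uncalibrated units) on a
breath-by-breath basis. One recording yields two point-process series — the
inter-breath intervals IBI_k (seconds) and the breath amplitudes RV_k
(arbitrary units) — and from them a per-recording profile:
mean and coefficient of variation of each series, sample entropy
SampEn(m, r), the DFA scaling exponent α of each series, and the
cross-sample entropy between them. Profiles are compared across experimental
groups with classical omnibus + post-hoc tests.

## Breath extraction

A fixed-length analysis window (default 1200 s) slides over the recording in
30-s hops; the window minimizing a two-term artifact score is analysed. The
score is `0.5 × (fraction of samples beyond 5 robust SD of the window
median) + 0.5 × (fraction of non-DC Welch power outside 0.5–5 Hz)`, with the
robust SD taken as 1.4826 × MAD. The band brackets guinea-pig respiratory
rates (~1–3 Hz); both weights and the band are configurable. The score is
deliberately scale-invariant (plethysmograph gain is arbitrary), so a
constant gain change is itself invisible — gain *steps* inside a window are
what it detects, which is how artifact epochs are avoided. Ties go to the
earliest window.

The window is high-passed with a 2nd-order Butterworth filter applied
forward–backward (zero phase, so peak times are not shifted; default cutoff
0.1 Hz) and smoothed with a 20 ms centred moving average. Breath peaks are
local maxima with prominence ≥ 0.3 × (4 × 1.4826 × MAD of the window);
candidates closer than a 0.15 s refractory period are resolved greedily by
height, exact ties to the earlier peak. The prominence floor trades
sensitivity to unusually small breaths (below ~0.3 of the robust amplitude)
for immunity to noise ripples; fidelity benchmarks on noiseless renders use
a 0.15 floor with the high-pass off, since there is neither noise nor drift
to guard against. RV is measured peak-minus-adjacent-trough (minimum of the
signal between neighbouring peaks) rather than as the absolute peak value,
which immunizes amplitudes against residual drift. Deep inspirations are
retained, not censored.

## Complexity metrics

**Sample entropy.** SampEn(m, r) = −ln(A/B), with B the number of pairs
(i < j) of m-length templates whose Chebyshev distance is ≤ r × sample SD,
and A the analogous count at length m+1; both counts use the first N−m
template positions so every m-template has a defined extension, and
self-matches are excluded by i < j. Defaults m = 2, r = 0.2 (SD-relative,
the established convention for physiological series, which makes the measure
affine-invariant). A zero-variance series returns 0 (every template
matches); A = 0 or B = 0 returns +inf, a distinguished "no matches" value
that the group statistics drop pairwise with a logged count rather than cap
arbitrarily. Note a subtlety found during property testing: on a *fixed*
finite series SampEn is not guaranteed monotone in r (the conditional ratio
A/B can dip as r grows); only the counts A and B are monotone, and SampEn
decreases with r in expectation.

**Cross-sample entropy.** Both series are z-normalized independently (their
units are incommensurate), every ordered template pair (i from x, j from y)
is compared — making the statistic exactly symmetric and, for x = y,
equivalent to SampEn with self-matches allowed — and Cross-SampEn =
−ln(A/B) with r in SD units. Larger values mean fewer shared sub-patterns
(more asynchrony). IBI and RV are aligned by dropping the last RV value
(n peaks give n−1 intervals).

**DFA.** The mean-centred series is integrated; for each of 16 log-spaced
window sizes s in [4, n/4] (duplicate integers removed) the profile is split
into ⌊n/s⌋ non-overlapping windows from the start *and* from the end (so no
tail is discarded), each window is detrended by an order-1 least-squares
polynomial, and F(s) is the RMS residual over all 2⌊n/s⌋ windows. α is the
OLS slope of log F vs log s. The detrending order and scale grid are
configurable; DFA is applied to the raw IBI/RV values with the integration
done internally (the standard profile construction).

## Group statistics

One-way ANOVA (scipy's F) with pairwise two-sample pooled-variance t tests
of each group against the reference, Bonferroni-adjusted (raw p × number of
comparisons, capped at 1); or Kruskal–Wallis (mid-rank ties correction) with
Dunn's z on mean ranks, `z = (R̄_a − R̄_b) / sqrt((N(N+1)/12 − T)(1/n_a +
1/n_b))`, tie term `T = Σ(t³−t)/(12(N−1))`, same Bonferroni adjustment. By
default each metric is screened for normality (Shapiro–Wilk per group,
α = 0.05) to choose between the two; the choice can be forced. Non-finite
metric values are excluded pairwise with a logged count. The effect-pattern
report evaluates, per case group vs control: SampEn_IBI lower, CV_IBI
higher, α_RV higher, cross-SampEn lower (each requiring adjusted
significance), and no significant shift in the means and remaining panels;
groups with fewer than 5 usable values are flagged low-power.

## Synthetic generator

The generator produces the study conditions for all verification: fGn
innovations are synthesized *exactly* by circulant embedding (Davies–Harte),
so the target autocovariance γ(k) = sd²/2(|k+1|^2H − 2|k|^2H + |k−1|^2H)
holds by construction and DFA recovers α ≈ H without AR-fit bias. Per
recording, IBI and RV innovation streams share a common fGn component with
weight `coupling_rho` (the shared stream's Hurst is the mean of the two
channel Hursts — a shared stream cannot carry two exponents at once); a
`regularity` control then blends both streams with a period-3, zero-mean,
unit-variance cycle using sqrt weights (sqrt(1−reg), sqrt(reg)), which
lowers entropy while preserving each series' mean and CV exactly. The cycle
is shared in phase between the channels, so regularity also entrains
amplitude to rhythm. This is deliberate: Gaussian correlation between the
channels barely moves cross-SampEn at m = 2, r = 0.2 — off-diagonal template
pairs dominate the match counts — so a shared deterministic rhythm is the
mechanism that produces measurable synchronization. IBI_k =
ibi_mean(1 + ibi_cv·z_k), floored at 0.2·ibi_mean (RV at 0.05·rv_mean;
floor events are counted in the metadata). Sighs multiply RV by
`sigh_amplitude_factor` with per-breath probability `sigh_rate`
(optionally prolonging the following interval, off by default).

Rendering turns each breath into a raised-cosine (or truncated-Gaussian)
pulse of amplitude RV_k at the cumulative peak time, with per-breath
half-width 45% of the smaller adjacent gap so pulses never overlap and
rendered maxima equal the ground-truth amplitudes; Gaussian sensor noise,
sinusoidal baseline drift and gain-multiplied artifact epochs are applied
afterwards. Ground truth is returned (and serialized) alongside every
rendered signal. Per-recording seeds are SHA-256 digests of (master seed,
group, index), so cohorts are bit-reproducible and streams independent.

**Cohort templates.** Control-like: ibi_mean 0.6 s (~100 breaths/min),
ibi_cv 0.10, ibi_hurst 0.6, rv_cv 0.15, rv_hurst 0.5, coupling 0.2,
regularity 0.1, sigh rate 0.005 (one deep inspiration every ~2 min) with
amplitude factor 2.0. Asthma-like: regularity 0.6, ibi_cv 0.15 (1.5×),
rv_hurst 0.9, coupling 0.8; means and sigh parameters unchanged. Amplitude
fluctuations in control are modelled as serially uncorrelated (H = 0.5) so
the case group's persistent amplitudes (H = 0.9) produce a clear α_RV
contrast; sigh parameters are kept modest because large rare spikes act as
white noise that masks both the amplitude scaling and the synchronization
structure.

**What the generator does not emulate.** Real plethysmography has
inspiratory/expiratory asymmetry, amplitude-dependent breath widths,
apneas, movement artifacts with spectral colour, and slow physiological
state changes; none of these are modelled, so passing tests demonstrate the
*estimators'* correctness and the pipeline's fidelity under controlled
conditions, not robustness to every field artifact. Two calibration
properties are worth knowing: (1) because the shared cycle enters both
channels, the case group's SampEn_RV also falls — in real asthmatic animals
amplitude entropy is reported unchanged, so the generator's synchronization
mechanism is a stylization; (2) the SampEn-vs-regularity curve is slightly
non-monotone at weak regularity (a faint periodic admixture spreads
templates into phase clusters and can *raise* SampEn by a few percent before
determinism dominates), so monotonicity holds from regularity ≈ 0.3 on.

## Problem sizes and numerical choices

Analysis defaults match a 1 kHz, 60-min recording with a 20-min window.
The verification suite and the acceptance script use scaled designs chosen
to exercise every code path at stable statistics: 250 Hz / 900-s recordings
with 600-s windows for the cohort pattern (≈1000 breaths per window, n = 10
per group), 1 kHz / 120-breath renders for extraction fidelity, n = 8192
and 20 seeds for DFA calibration, and 1000 series-level null cohorts
(3 × 8 recordings, 200 breaths each) for type-I calibration. Entropy
estimators are validated against exhaustive triple-loop counting to
floating-point equality. All tolerances asserted in tests (α within 0.05 of
H; IBI within 2 ms and RV within 1% on noiseless renders; detection F1 ≥
0.95 at 10% amplitude noise; type-I 5% ± 2%) are measured properties of
these designs, not fitted constants.

Degenerate inputs are handled explicitly: constant series give SampEn = 0
and CV = 0 and are rejected by DFA; identical groups give F = 0 and H = 0;
all-tied data raise a degenerate-series error rather than returning NaN.
0-based sample indexing and half-open windows [start, start + duration·fs)
are used throughout.
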