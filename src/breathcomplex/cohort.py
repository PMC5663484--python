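"""Cohort-level analysis: pipeline orchestration, group statistics, and the
model/results objects.

The entry point is :class:`CohortComplexity`, a model built either from a
table of per-recording complexity profiles or directly from recordings
(``from_recordings`` runs the full window-selection → breath-extraction →
complexity pipeline). ``fit()`` compares every metric across groups — one-way
ANOVA with Bonferroni-adjusted pairwise t tests against the reference group,
or Kruskal–Wallis with Dunn's post test, chosen per metric by a normality
screen when ``method="auto"`` — and returns a :class:`CohortComplexityResults`
with the comparisons, a ``summary()`` table, and the qualitative
effect-pattern report (regular-rhythm / raised-variability / amplitude-
persistence / synchronization shifts in case groups relative to control).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .exceptions import (
    BreathComplexError,
    DegenerateSeriesError,
    InsufficientDataError,
    ParameterError,
    PipelineError,
)
from .extraction import DetectionParams, detect_breath_peaks, preprocess, build_breath_series
from .io import select_analysis_window
from .metrics import ComplexityProfile, DfaParams, EntropyParams, complexity_profile

logger = logging.getLogger("breathcomplex")

__all__ = [
    "PipelineConfig",
    "GroupComparison",
    "run_pipeline",
    "one_way_anova_bonferroni",
    "kruskal_dunn",
    "reproduce_effect_pattern",
    "CohortComplexity",
    "CohortComplexityResults",
    "EFFECT_PATTERN",
]


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end per-recording analysis settings."""

    window_duration: float = 1200.0
    window_hop: float = 30.0
    detection: DetectionParams = field(default_factory=DetectionParams)
    entropy: EntropyParams = field(default_factory=EntropyParams)
    dfa: DfaParams = field(default_factory=DfaParams)


@dataclass
class GroupComparison:
    """Omnibus + pairwise comparison of one metric across groups.

    ``pairwise`` holds ``(group_a, group_b, raw_p, adjusted_p)`` tuples with
    ``group_a`` the reference; the adjustment is Bonferroni (raw p times the
    number of pairwise tests, capped at 1).
    """

    metric: str
    method: str
    omnibus_stat: float
    omnibus_p: float
    pairwise: list

    def __post_init__(self):
        for _, _, raw, adj in self.pairwise:
            if adj < raw - 1e-12:
                raise ParameterError("adjusted p must be >= raw p")


# ---------------------------------------------------------------------------
# Pipeline

def run_pipeline(recordings, config: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Analyse every recording of a cohort; returns the cohort table.

    ``recordings`` is an iterable of objects with ``subject_id``, ``group``
    and ``signal`` attributes (e.g. :class:`~breathcomplex.synthetic.CohortRecording`).
    Per-recording failures are logged and recorded in the table's
    ``attrs['failures']`` — they do not abort the cohort. Raises
    :class:`PipelineError` only if *every* recording fails.
    """
    rows = []
    failures = []
    for rec in recordings:
        try:
            window = select_analysis_window(
                rec.signal, duration=config.window_duration, hop=config.window_hop
            )
            segment = rec.signal.slice(
                window.start_index, int(round(config.window_duration * rec.signal.fs))
            )
            cleaned = preprocess(segment, config.detection)
            peaks = detect_breath_peaks(cleaned, config.detection)
            series = build_breath_series(cleaned, peaks)
            profile = complexity_profile(series, config.entropy, config.dfa)
        except BreathComplexError as exc:
            logger.warning("recording %s failed: %s", rec.subject_id, exc)
            failures.append((rec.subject_id, str(exc)))
            continue
        rows.append(
            {"subject_id": rec.subject_id, "group": rec.group, **profile.as_dict()}
        )
    if not rows:
        raise PipelineError("all recordings failed", failures=failures)
    table = pd.DataFrame(rows)
    table.attrs["failures"] = failures
    return table


def _group_values(table: pd.DataFrame, metric: str, group_col: str):
    """Finite metric values per group, preserving group order of appearance."""
    if metric not in table.columns:
        raise ParameterError(f"metric {metric!r} not in table")
    out = {}
    n_dropped = 0
    for label in table[group_col].unique():
        vals = table.loc[table[group_col] == label, metric].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        n_dropped += vals.size - finite.size
        out[str(label)] = finite
    if n_dropped:
        logger.warning("%s: dropped %d undefined value(s) before comparison", metric, n_dropped)
    return out


def _check_groups(groups: dict) -> None:
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    for label, vals in groups.items():
        if vals.size < 2:
            raise InsufficientDataError(f"group {label!r} has fewer than 2 usable values")


def _ordered_pairs(groups: dict, reference: str):
    if reference not in groups:
        raise ParameterError(f"reference group {reference!r} not present")
    return [(reference, other) for other in groups if other != reference]


def one_way_anova_bonferroni(
    table: pd.DataFrame, metric: str, reference_group: str, group_col: str = "group"
) -> GroupComparison:
    """One-way ANOVA omnibus F plus Bonferroni-adjusted pairwise t tests
    of every group against the reference."""
    groups = _group_values(table, metric, group_col)
    _check_groups(groups)
    if all(np.var(v) == 0.0 for v in groups.values()):
        raise DegenerateSeriesError(f"{metric}: zero within-group variance everywhere")
    f_stat, p_omni = sstats.f_oneway(*groups.values())
    pairs = _ordered_pairs(groups, reference_group)
    k = len(pairs)
    pairwise = []
    for ref, other in pairs:
        t, raw_p = sstats.ttest_ind(groups[ref], groups[other], equal_var=True)
        if not np.isfinite(raw_p):  # both groups constant and equal
            raw_p = 1.0
        pairwise.append((ref, other, float(raw_p), min(1.0, float(raw_p) * k)))
    return GroupComparison(
        metric=metric,
        method="anova_bonferroni",
        omnibus_stat=float(f_stat),
        omnibus_p=float(p_omni),
        pairwise=pairwise,
    )


def kruskal_dunn(
    table: pd.DataFrame, metric: str, reference_group: str, group_col: str = "group"
) -> GroupComparison:
    """Kruskal–Wallis omnibus H (mid-rank ties correction) plus Dunn's
    pairwise z tests against the reference, Bonferroni-adjusted.

    Dunn's statistic for groups a, b compares mean ranks over the pooled
    mid-ranked sample: z = (Rbar_a - Rbar_b) / sqrt((N(N+1)/12 - T)(1/n_a + 1/n_b))
    with the tie correction T = sum(t^3 - t) / (12 (N - 1)).
    """
    groups = _group_values(table, metric, group_col)
    _check_groups(groups)
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        raise DegenerateSeriesError(f"{metric}: all values tied")
    h_stat, p_omni = sstats.kruskal(*groups.values())

    ranks = sstats.rankdata(pooled)
    n_total = pooled.size
    offsets = np.cumsum([0] + [v.size for v in groups.values()])
    mean_rank = {
        label: float(np.mean(ranks[offsets[i] : offsets[i + 1]]))
        for i, label in enumerate(groups)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = _ordered_pairs(groups, reference_group)
    k = len(pairs)
    pairwise = []
    for ref, other in pairs:
        se = np.sqrt(base_var * (1.0 / groups[ref].size + 1.0 / groups[other].size))
        z = (mean_rank[ref] - mean_rank[other]) / se if se > 0 else 0.0
        raw_p = float(2.0 * sstats.norm.sf(abs(z)))
        pairwise.append((ref, other, raw_p, min(1.0, raw_p * k)))
    return GroupComparison(
        metric=metric,
        method="kruskal_dunn",
        omnibus_stat=float(h_stat),
        omnibus_p=float(p_omni),
        pairwise=pairwise,
    )


def _choose_method(groups: dict, alpha: float = 0.05) -> str:
    """Normality screen: parametric unless any group fails Shapiro–Wilk."""
    for vals in groups.values():
        if vals.size < 3 or np.var(vals) == 0.0:
            return "kruskal_dunn"
        if sstats.shapiro(vals).pvalue < alpha:
            return "kruskal_dunn"
    return "anova_bonferroni"


def compare_metric(
    table: pd.DataFrame,
    metric: str,
    reference_group: str,
    method: str = "auto",
    group_col: str = "group",
) -> GroupComparison:
    """Dispatch a single-metric group comparison by name or normality screen."""
    if method == "auto":
        method = _choose_method(_group_values(table, metric, group_col))
    if method == "anova_bonferroni":
        return one_way_anova_bonferroni(table, metric, reference_group, group_col)
    if method == "kruskal_dunn":
        return kruskal_dunn(table, metric, reference_group, group_col)
    raise ParameterError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Effect-pattern report

#: Direction expected in case groups relative to control for each metric:
#: the asthmatic phenotype is a more regular rhythm (lower SampEn_IBI) with
#: higher interval variability (CV_IBI), more persistent amplitude dynamics
#: (alpha_RV) and stronger IBI–RV synchronization (lower cross-SampEn), with
#: no shift in the means or the remaining panels.
EFFECT_PATTERN = {
    "sampen_ibi": "lower",
    "cv_ibi": "higher",
    "alpha_rv": "higher",
    "cross_sampen": "lower",
    "mean_ibi": "none",
    "mean_rv": "none",
    "sampen_rv": "none",
    "alpha_ibi": "none",
    "cv_rv": "none",
}

#: the four panels that must shift for the pattern to count as reproduced
PRIMARY_EFFECTS = ("sampen_ibi", "cv_ibi", "alpha_rv", "cross_sampen")


def reproduce_effect_pattern(
    table: pd.DataFrame,
    control_label: str,
    case_labels=None,
    method: str = "auto",
    alpha: float = 0.05,
    group_col: str = "group",
) -> pd.DataFrame:
    """Evaluate the direction-and-significance pattern of case vs control.

    Returns one row per (case group, metric): the expected and observed
    direction, the Bonferroni-adjusted p-value of the pairwise test against
    control, and whether the expectation holds (a 'none' expectation holds
    when the shift is *not* significant). Rows are flagged ``low_power`` when
    either group has fewer than 5 usable values; missing metrics are reported
    as untestable rather than raising.
    """
    if case_labels is None:
        case_labels = [g for g in table[group_col].unique() if g != control_label]
    rows = []
    for metric, expected in EFFECT_PATTERN.items():
        try:
            comp = compare_metric(table, metric, control_label, method=method, group_col=group_col)
            groups = _group_values(table, metric, group_col)
        except (BreathComplexError, KeyError) as exc:
            for case in case_labels:
                rows.append(
                    {
                        "case_group": case, "metric": metric, "expected": expected,
                        "observed": "untestable", "adjusted_p": np.nan,
                        "significant": False, "holds": np.nan, "low_power": np.nan,
                        "note": str(exc),
                    }
                )
            continue
        adj = {(a, b): p_adj for a, b, _, p_adj in comp.pairwise}
        for case in case_labels:
            p_adj = adj.get((control_label, case), np.nan)
            delta = float(np.mean(groups[case]) - np.mean(groups[control_label]))
            observed = "higher" if delta > 0 else "lower" if delta < 0 else "equal"
            significant = bool(np.isfinite(p_adj) and p_adj < alpha)
            if expected == "none":
                holds = not significant
            else:
                holds = significant and observed == expected
            low_power = min(groups[case].size, groups[control_label].size) < 5
            rows.append(
                {
                    "case_group": case, "metric": metric, "expected": expected,
                    "observed": observed, "adjusted_p": p_adj,
                    "significant": significant, "holds": holds,
                    "low_power": low_power, "note": comp.method,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results

class CohortComplexity:
    """Group-comparison model over a cohort of complexity profiles.

    Parameters
    ----------
    table : DataFrame
        One row per recording with a group column and the complexity metric
        columns (the output of :func:`run_pipeline` or a profiles CSV).
    reference : str, optional
        Reference (control) group label; defaults to the first group in the
        table.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        group_col: str = "group",
        subject_col: str = "subject_id",
        reference: Optional[str] = None,
    ):
        if group_col not in table.columns:
            raise ParameterError(f"table lacks group column {group_col!r}")
        if subject_col in table.columns and table[subject_col].duplicated().any():
            raise ParameterError("duplicated subject ids in cohort table")
        counts = table[group_col].value_counts()
        if len(counts) < 2:
            raise InsufficientDataError("cohort table needs >= 2 groups")
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise InsufficientDataError(f"groups with fewer than 2 recordings: {small}")
        self.table = table.reset_index(drop=True)
        self.group_col = group_col
        self.subject_col = subject_col
        self.reference = str(reference) if reference is not None else str(table[group_col].iloc[0])
        if self.reference not in set(table[group_col].astype(str)):
            raise ParameterError(f"reference group {self.reference!r} not in table")
        self.metrics = [m for m in ComplexityProfile.METRICS if m in table.columns]
        self.failures = list(table.attrs.get("failures", []))

    @classmethod
    def from_recordings(
        cls,
        recordings,
        config: PipelineConfig = PipelineConfig(),
        reference: Optional[str] = None,
    ) -> "CohortComplexity":
        """Run the full per-recording pipeline, then build the model."""
        table = run_pipeline(recordings, config)
        return cls(table, reference=reference)

    @classmethod
    def from_csv(cls, path, reference: Optional[str] = None, **kwargs) -> "CohortComplexity":
        return cls(pd.read_csv(path), reference=reference, **kwargs)

    def fit(self, method: str = "auto", alpha: float = 0.05) -> "CohortComplexityResults":
        """Compare every metric across groups; returns the results object."""
        comparisons = {}
        for metric in self.metrics:
            try:
                comparisons[metric] = compare_metric(
                    self.table, metric, self.reference, method=method, group_col=self.group_col
                )
            except BreathComplexError as exc:
                logger.warning("metric %s untestable: %s", metric, exc)
        if not comparisons:
            raise InsufficientDataError("no metric could be compared")
        return CohortComplexityResults(self, comparisons, alpha=alpha)


class CohortComplexityResults:
    """Fitted group comparisons; produced by :meth:`CohortComplexity.fit`."""

    def __init__(self, model: CohortComplexity, comparisons: dict, alpha: float = 0.05):
        self.model = model
        self.comparisons = comparisons
        self.alpha = alpha

    def group_means(self) -> pd.DataFrame:
        """Mean (SEM) of every metric per group."""
        grouped = self.model.table.groupby(self.model.group_col)[self.model.metrics]
        return grouped.agg(["mean", "sem"])

    def pairwise_table(self) -> pd.DataFrame:
        rows = []
        for metric, comp in self.comparisons.items():
            for a, b, raw, adj in comp.pairwise:
                rows.append(
                    {
                        "metric": metric, "method": comp.method,
                        "reference": a, "group": b,
                        "raw_p": raw, "adjusted_p": adj,
                        "significant": adj < self.alpha,
                    }
                )
        return pd.DataFrame(rows)

    def effect_pattern(self, case_labels=None, method: str = "auto") -> pd.DataFrame:
        """Direction-and-significance report vs the reference group."""
        return reproduce_effect_pattern(
            self.model.table,
            self.model.reference,
            case_labels=case_labels,
            method=method,
            alpha=self.alpha,
            group_col=self.model.group_col,
        )

    def pattern_reproduced(self, case_labels=None) -> bool:
        """True if all four primary effect directions hold with adjusted
        significance in every case group."""
        report = self.effect_pattern(case_labels=case_labels)
        primary = report[report["metric"].isin(PRIMARY_EFFECTS)]
        return bool(primary["holds"].astype(bool).all())

    def summary(self) -> str:
        """Human-readable summary of the fitted comparisons."""
        lines = [
            "Breathing-pattern complexity: group comparison",
            f"  groups: {', '.join(map(str, self.model.table[self.model.group_col].unique()))}"
            f"  (reference: {self.model.reference})",
            f"  recordings: {len(self.model.table)}   alpha: {self.alpha}",
            "",
            f"{'metric':<14}{'method':<18}{'omnibus':>10}{'p':>10}  pairwise (vs reference, adj. p)",
        ]
        for metric, comp in self.comparisons.items():
            pw = "  ".join(
                f"{b}:{adj:.3g}{'*' if adj < self.alpha else ''}"
                for _, b, _, adj in comp.pairwise
            )
            lines.append(
                f"{metric:<14}{comp.method:<18}{comp.omnibus_stat:>10.4g}"
                f"{comp.omnibus_p:>10.3g}  {pw}"
            )
        if self.model.failures:
            lines.append("")
            lines.append(f"  pipeline failures: {len(self.model.failures)}")
        return "\n".join(lines)

    def plot_metric(self, metric: str, ax=None):
        """Strip plot of one metric per group (diagnostic, not publication)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        labels = list(self.model.table[self.model.group_col].unique())
        rng = np.random.default_rng(0)
        for i, label in enumerate(labels):
            vals = self.model.table.loc[
                self.model.table[self.model.group_col] == label, metric
            ].to_numpy(dtype=float)
            jitter = rng.uniform(-0.08, 0.08, vals.size)
            ax.plot(np.full(vals.size, i) + jitter, vals, "o", alpha=0.7)
            finite = vals[np.isfinite(vals)]
            if finite.size:
                ax.hlines(np.mean(finite), i - 0.2, i + 0.2, color="k")
        ax.set_xticks(range(len(labels)), labels)
        ax.set_ylabel(metric)
        return ax
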