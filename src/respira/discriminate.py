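"""Statistical discrimination of respirator fit state and filter clogging.

Fit evaluation: per channel, per-subject aggregate peak-to-peak amplitudes
for the three fit conditions are compared with two-sided *paired* t-tests
(initial↔loose, loose↔final, initial↔final) at α = 0.05, after a
Shapiro–Wilk normality check on the paired differences.  With a 10-subject
panel each test has 9 degrees of freedom.  A well-behaved channel separates
both transitions involving the loose condition while the two fitted
conditions remain statistically indistinguishable (the seal is recovered).

Clogging evaluation: per channel, one-way ANOVA across the occlusion levels
followed by Tukey's HSD post-hoc pairwise comparisons (studentized-range
distribution, pooled within-group variance).  The fully clogged level's
pressure distribution is an order of magnitude above the rest and would
swamp the pooled variance, hiding the differences among the other levels,
so it is excluded from the pressure channel's ANOVA and Tukey comparisons
by default.

No multiple-testing correction is applied across channels or comparisons;
every report carries a note saying so.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import DegenerateDataError, MissingDataError, ValidationError
from .features import aggregate_features

__all__ = [
    "TTestResult",
    "AnovaResult",
    "TukeyMatrix",
    "ChannelFitResult",
    "ChannelClogResult",
    "EvaluationReport",
    "shapiro_wilk",
    "paired_t_two_sided",
    "one_way_anova",
    "tukey_hsd",
    "evaluate_fitting",
    "evaluate_clogging",
]

FIT_COMPARISONS = (
    ("fit_initial", "fit_loose"),
    ("fit_loose", "fit_final"),
    ("fit_initial", "fit_final"),
)

MULTIPLICITY_NOTE = (
    "p-values are not corrected for multiple comparisons across channels or "
    "condition pairs"
)


# ---------------------------------------------------------------------------
# elementary statistics (scipy-backed)
# ---------------------------------------------------------------------------

def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro–Wilk normality test; returns ``(W, p)``."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValidationError(f"Shapiro–Wilk needs 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("Shapiro–Wilk undefined on a zero-variance sample")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    p_value: float
    df: int
    comparison: str = ""

    def to_dict(self) -> dict:
        return {"t": self.t_stat, "p": self.p_value, "df": self.df,
                "comparison": self.comparison}


def paired_t_two_sided(a, b, comparison: str = "") -> TTestResult:
    """Two-sided paired t-test on subject-aligned samples.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``d = a - b`` and the n−1 SD;
    ``df = n - 1``.  A zero-variance difference vector makes the statistic
    undefined and raises :class:`DegenerateDataError` rather than reporting
    an infinite t.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValidationError("paired t-test needs two equal-length 1-D samples, n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        raise DegenerateDataError("paired differences have zero variance")
    res = stats.ttest_rel(a, b)
    return TTestResult(float(res.statistic), float(res.pvalue), len(a) - 1, comparison)


@dataclass(frozen=True)
class AnovaResult:
    df_between: int
    df_within: int
    f_stat: float
    p_value: float

    def to_dict(self) -> dict:
        return {"df_between": self.df_between, "df_within": self.df_within,
                "F": self.f_stat, "p": self.p_value}


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA over ≥ 2 groups of ≥ 2 values each."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in gs):
        raise ValidationError("every ANOVA group needs at least 2 values")
    pooled = np.concatenate(gs)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs)
    if ss_within == 0.0:
        raise DegenerateDataError("zero within-group variance; F undefined")
    res = stats.f_oneway(*gs)
    return AnovaResult(
        df_between=len(gs) - 1,
        df_within=len(pooled) - len(gs),
        f_stat=float(res.statistic),
        p_value=float(res.pvalue),
    )


@dataclass(frozen=True)
class TukeyMatrix:
    """Symmetric matrix of Tukey-HSD adjusted pairwise p-values.

    ``clipped`` marks the display convention of some legacy statistics
    packages, which saturate adjusted p-values into [0.001, 0.900]; raw
    values are reported by default.
    """

    labels: tuple
    p_values: np.ndarray
    clipped: bool = False

    def p(self, a, b) -> float:
        return float(self.p_values[self.labels.index(a), self.labels.index(b)])

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "p_values": [[float(v) for v in row] for row in self.p_values],
            "clipped": self.clipped,
        }


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence] = None,
    clip_legacy: bool = False,
) -> TukeyMatrix:
    """Tukey's HSD pairwise comparisons after a one-way layout.

    Adjusted p-values come from the studentized-range distribution with the
    pooled within-group variance.  ``clip_legacy`` reproduces the
    saturated [0.001, 0.900] display convention of legacy software; raw
    values are the default.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValidationError("Tukey HSD needs at least 2 groups")
    if any(len(g) < 2 for g in gs):
        raise ValidationError("every group needs at least 2 values")
    if sum(float(np.sum((g - g.mean()) ** 2)) for g in gs) == 0.0:
        raise DegenerateDataError("zero within-group variance")
    res = stats.tukey_hsd(*gs)
    p = np.array(res.pvalue, dtype=float)
    np.fill_diagonal(p, 1.0)
    # enforce exact symmetry against floating-point asymmetries
    p = 0.5 * (p + p.T)
    if clip_legacy:
        off = ~np.eye(len(gs), dtype=bool)
        p[off] = np.clip(p[off], 0.001, 0.900)
    if labels is None:
        labels = tuple(range(len(gs)))
    return TukeyMatrix(labels=tuple(labels), p_values=p, clipped=clip_legacy)


# ---------------------------------------------------------------------------
# evaluation reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelFitResult:
    channel: str
    tests: tuple[TTestResult, ...]
    normality: dict  # comparison -> (W, p) on the paired differences
    significant: dict  # comparison -> bool at alpha

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "tests": [t.to_dict() for t in self.tests],
            "normality": {k: {"W": w, "p": p} for k, (w, p) in self.normality.items()},
            "significant": dict(self.significant),
        }


@dataclass(frozen=True)
class ChannelClogResult:
    channel: str
    anova: AnovaResult
    tukey: TukeyMatrix
    normality: dict  # level -> (W, p)
    excluded_levels: tuple[int, ...]
    significant: bool

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "anova": self.anova.to_dict(),
            "tukey": self.tukey.to_dict(),
            "normality": {str(k): {"W": w, "p": p} for k, (w, p) in self.normality.items()},
            "excluded_levels": list(self.excluded_levels),
            "significant": self.significant,
        }


@dataclass(frozen=True)
class EvaluationReport:
    mode: str  # "fitting" or "clogging"
    alpha: float
    channels: dict
    notes: tuple[str, ...] = field(default=(MULTIPLICITY_NOTE,))

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "alpha": self.alpha,
            "channels": {k: v.to_dict() for k, v in self.channels.items()},
            "notes": list(self.notes),
        }


def _subject_matrix(agg: pd.DataFrame, channel: str, key_col: str, keys) -> pd.DataFrame:
    """Pivot per-subject aggregates to subjects × conditions for one channel."""
    sub = agg[agg["channel"] == channel]
    pivot = sub.pivot_table(index="subject_id", columns=key_col, values="p2p")
    missing = [k for k in keys if k not in pivot.columns]
    if missing:
        raise MissingDataError(f"channel {channel!r}: missing condition(s) {missing}")
    if pivot[list(keys)].isna().any().any():
        bad = pivot[list(keys)].isna().any(axis=1)
        raise MissingDataError(
            f"channel {channel!r}: incomplete subjects {list(pivot.index[bad])}"
        )
    return pivot[list(keys)]


def _maybe_aggregate(features: pd.DataFrame, statistic: str) -> pd.DataFrame:
    if "cycle_index" in features.columns:
        return aggregate_features(features, statistic=statistic)
    return features


def evaluate_fitting(
    features: pd.DataFrame, alpha: float = 0.05, statistic: str = "mean"
) -> EvaluationReport:
    """Paired t-test evaluation of the fitted → loose → fitted protocol.

    Accepts a per-cycle feature table (aggregated internally, mean per
    subject per condition by default) or a pre-aggregated one.  Per channel,
    the three comparisons are tested two-sided at ``alpha`` after a
    Shapiro–Wilk check on the paired differences; non-normal differences are
    recorded as warnings, not failures.
    """
    agg = _maybe_aggregate(features, statistic)
    kinds = [k for k, _ in FIT_COMPARISONS] + [FIT_COMPARISONS[-1][1]]
    channels = {}
    for ch in sorted(agg["channel"].unique()):
        pivot = _subject_matrix(agg, ch, "kind", tuple(dict.fromkeys(kinds)))
        tests, normality, significant = [], {}, {}
        for a, b in FIT_COMPARISONS:
            label = f"{a}~{b}"
            d = pivot[a].to_numpy() - pivot[b].to_numpy()
            try:
                normality[label] = shapiro_wilk(d)
            except (DegenerateDataError, ValidationError):
                normality[label] = (float("nan"), float("nan"))
            res = paired_t_two_sided(pivot[a].to_numpy(), pivot[b].to_numpy(), label)
            tests.append(res)
            significant[label] = bool(res.p_value < alpha)
        channels[ch] = ChannelFitResult(ch, tuple(tests), normality, significant)
    return EvaluationReport(mode="fitting", alpha=alpha, channels=channels)


def evaluate_clogging(
    features: pd.DataFrame,
    alpha: float = 0.05,
    exclude_levels_for: Optional[Mapping[str, Sequence[int]]] = None,
    statistic: str = "mean",
    clip_legacy: bool = False,
) -> EvaluationReport:
    """ANOVA + Tukey evaluation of the filter-clogging protocol.

    ``exclude_levels_for`` maps channel → occlusion levels dropped from that
    channel's ANOVA and Tukey comparisons.  The default drops the 100 % level
    from the pressure channel: its peak-to-peak distribution is more than an
    order of magnitude above the rest and would dominate the pooled variance,
    masking the separability of the remaining levels.
    """
    if exclude_levels_for is None:
        exclude_levels_for = {"p": (100,)}
    agg = _maybe_aggregate(features, statistic)
    agg = agg[agg["kind"] == "clog_level"]
    if agg.empty:
        raise ValidationError("feature table holds no clogging-level rows")
    agg = agg.assign(clog_pct=agg["clog_pct"].astype(int))
    channels = {}
    for ch in sorted(agg["channel"].unique()):
        levels = sorted(int(v) for v in agg.loc[agg["channel"] == ch, "clog_pct"].unique())
        excluded = tuple(int(v) for v in exclude_levels_for.get(ch, ()))
        included = [lv for lv in levels if lv not in excluded]
        if len(included) < 2:
            raise ValidationError(
                f"channel {ch!r}: exclusion leaves {len(included)} level(s), need >= 2"
            )
        pivot = _subject_matrix(agg[agg["channel"] == ch], ch, "clog_pct", included)
        groups = [pivot[lv].to_numpy() for lv in included]
        normality = {}
        for lv, g in zip(included, groups):
            try:
                normality[lv] = shapiro_wilk(g)
            except (DegenerateDataError, ValidationError):
                normality[lv] = (float("nan"), float("nan"))
        anova = one_way_anova(groups)
        tukey = tukey_hsd(groups, labels=included, clip_legacy=clip_legacy)
        channels[ch] = ChannelClogResult(
            ch, anova, tukey, normality, excluded, bool(anova.p_value < alpha)
        )
    return EvaluationReport(mode="clogging", alpha=alpha, channels=channels)
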