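"""Cohort-level statistics: classification, group comparison, thresholds.

Lesions are labelled *non-neoplastic* when a histogram feature exceeds its
threshold — positively skewed uptake is the signature of necrosis and
inflammation, whereas proliferating tumor uptake is symmetric.  The default
rule uses the published cut-offs (skewness 0.624, tendency 0.084) with
skewness alone deciding the label: the two features can disagree (a
necrotic tumor core can sit above the skewness cut but below the tendency
cut) and the clinical narrative follows skewness.

Group differences are reported with both the Wilcoxon rank-sum test (exact
for small samples) and Welch's t test: small imbalanced cohorts make the
nonparametric test the safer default, but the parametric companion is kept
for comparability with mean +- SD reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateThresholdWarning, ValidationError
from .features import FEATURE_COLUMNS, LesionFeatures

__all__ = [
    "ClassificationRule",
    "ClassificationResult",
    "GroupComparison",
    "classify",
    "compare_groups",
    "derive_threshold",
    "rank_sum_test",
    "threshold_transparency",
    "NEOPLASTIC",
    "NON_NEOPLASTIC",
    "ABSTAINED",
]

NEOPLASTIC = "neoplastic"
NON_NEOPLASTIC = "non-neoplastic"
ABSTAINED = "abstained"

_COMBINE_MODES = ("skewness_only", "tendency_only", "either", "both")

#: Published classification cut-offs.
DEFAULT_SKEWNESS_THRESHOLD = 0.624
DEFAULT_TENDENCY_THRESHOLD = 0.084


@dataclass(frozen=True)
class ClassificationRule:
    """Threshold rule for labelling a lesion from its histogram features.

    A feature votes non-neoplastic iff its value is strictly greater than
    its threshold (a value exactly at the cut votes neoplastic); ``combine``
    selects how the two votes form the label.
    """

    skewness_threshold: float = DEFAULT_SKEWNESS_THRESHOLD
    tendency_threshold: float = DEFAULT_TENDENCY_THRESHOLD
    combine: str = "skewness_only"

    def __post_init__(self) -> None:
        if not np.isfinite(self.skewness_threshold) or not np.isfinite(self.tendency_threshold):
            raise ValidationError("thresholds must be finite")
        if self.combine not in _COMBINE_MODES:
            raise ValidationError(
                f"combine must be one of {_COMBINE_MODES}, got {self.combine!r}"
            )


@dataclass(frozen=True)
class ClassificationResult:
    label: str
    votes: dict[str, str] = field(default_factory=dict)
    abstained: bool = False


def _vote(value: float, threshold: float) -> str:
    return NON_NEOPLASTIC if value > threshold else NEOPLASTIC


def classify(
    features: LesionFeatures | dict[str, float],
    rule: ClassificationRule | None = None,
) -> ClassificationResult:
    """Apply a threshold rule to one lesion's histogram features.

    Both per-feature votes are always reported; an undefined skewness
    (zero-variance ROI) yields an abstained result rather than a guess.
    """
    if rule is None:
        rule = ClassificationRule()
    if isinstance(features, LesionFeatures):
        skew, tend = features.skewness, features.tendency
    else:
        skew, tend = float(features["skewness"]), float(features["tendency"])
    if not np.isfinite(skew):
        return ClassificationResult(
            label=ABSTAINED,
            votes={"skewness": ABSTAINED, "tendency": _vote(tend, rule.tendency_threshold)
                   if np.isfinite(tend) else ABSTAINED},
            abstained=True,
        )
    if not np.isfinite(tend):
        raise ValidationError("tendency is not finite")
    votes = {
        "skewness": _vote(skew, rule.skewness_threshold),
        "tendency": _vote(tend, rule.tendency_threshold),
    }
    if rule.combine == "skewness_only":
        label = votes["skewness"]
    elif rule.combine == "tendency_only":
        label = votes["tendency"]
    elif rule.combine == "either":
        label = NON_NEOPLASTIC if NON_NEOPLASTIC in votes.values() else NEOPLASTIC
    else:  # both
        label = (
            NON_NEOPLASTIC
            if all(v == NON_NEOPLASTIC for v in votes.values())
            else NEOPLASTIC
        )
    return ClassificationResult(label=label, votes=votes)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution (via the equivalent Mann-Whitney U statistic)
    when the pooled sample is small (n <= 25) and tie-free; otherwise the
    normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


@dataclass(frozen=True)
class GroupComparison:
    """Per-feature two-group summary: means, SDs, and test p-values."""

    table: pd.DataFrame
    groups: tuple[str, str]

    def to_text(self) -> str:
        """Human-readable report: feature x group mean +- SD, p-values."""
        a, b = self.groups
        lines = [
            f"{'Feature':<12}{a + ' (mean ± SD)':>24}{b + ' (mean ± SD)':>28}"
            f"{'rank-sum p':>14}{'t-test p':>12}"
        ]
        for feat, row in self.table.iterrows():
            lines.append(
                f"{feat:<12}"
                f"{row[f'mean_{a}']:>14.3f} ± {row[f'sd_{a}']:<8.3f}"
                f"{row[f'mean_{b}']:>14.3f} ± {row[f'sd_{b}']:<8.3f}"
                f"{row['rank_sum_p']:>13.4g}{row['t_test_p']:>12.4g}"
            )
        return "\n".join(lines)


def compare_groups(
    table: pd.DataFrame,
    group_col: str = "group",
    features: list[str] | None = None,
) -> GroupComparison:
    """Compare every feature between two groups.

    Means and SDs use the sample (divide-by-n-1) convention matching
    "mean +- standard deviation" reporting.  The t test is Welch's
    (unequal variances); it is NaN when either group has fewer than two
    observations.
    """
    groups = sorted(table[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValidationError(f"exactly two groups required, got {groups}")
    a, b = groups
    if features is None:
        features = [c for c in FEATURE_COLUMNS if c in table.columns]
    if not features:
        raise ValidationError("no feature columns found in the table")
    rows = {}
    for feat in features:
        va = table.loc[table[group_col] == a, feat].dropna().to_numpy(float)
        vb = table.loc[table[group_col] == b, feat].dropna().to_numpy(float)
        if va.size < 1 or vb.size < 1:
            raise ValidationError(f"feature {feat!r}: each group needs >= 1 value")
        if va.size >= 2 and vb.size >= 2:
            t_p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
        else:
            t_p = float("nan")
        rows[feat] = {
            f"mean_{a}": va.mean(),
            f"sd_{a}": va.std(ddof=1) if va.size > 1 else float("nan"),
            f"n_{a}": va.size,
            f"mean_{b}": vb.mean(),
            f"sd_{b}": vb.std(ddof=1) if vb.size > 1 else float("nan"),
            f"n_{b}": vb.size,
            "rank_sum_p": rank_sum_test(va, vb),
            "t_test_p": t_p,
        }
    return GroupComparison(table=pd.DataFrame(rows).T, groups=(a, b))


def derive_threshold(
    values_a: np.ndarray,
    values_b: np.ndarray,
    method: str = "midpoint_of_means",
) -> float:
    """Derive a candidate cut separating two groups of feature values.

    ``midpoint_of_means`` returns (mean_a + mean_b) / 2.  ``youden`` scans
    every observed value as a candidate cut, treating the higher-mean group
    as positive with decision rule *value >= cut*, and returns the cut
    maximizing Youden's J = sensitivity + specificity - 1 (ties broken
    toward the smallest such cut).
    """
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    if va.size == 0 or vb.size == 0:
        raise ValidationError("both groups must be non-empty")
    if method == "midpoint_of_means":
        if np.isclose(va.mean(), vb.mean()):
            warnings.warn(
                "group means coincide; midpoint threshold is degenerate",
                DegenerateThresholdWarning,
                stacklevel=2,
            )
        return float((va.mean() + vb.mean()) / 2.0)
    if method == "youden":
        pos, neg = (vb, va) if vb.mean() >= va.mean() else (va, vb)
        cuts = np.unique(np.concatenate([pos, neg]))
        best_cut, best_j = float(cuts[0]), -np.inf
        for c in cuts:
            sens = np.mean(pos >= c)
            spec = np.mean(neg < c)
            j = sens + spec - 1.0
            if j > best_j + 1e-12:
                best_j, best_cut = j, float(c)
        if best_j <= 1e-12:
            warnings.warn(
                "groups are indistinguishable; Youden threshold is degenerate",
                DegenerateThresholdWarning,
                stacklevel=2,
            )
        return best_cut
    raise ValidationError(f"unknown threshold method {method!r}")


def threshold_transparency(
    mean_a: float,
    mean_b: float,
    published: float,
    atol: float = 1e-3,
) -> dict[str, float | bool]:
    """Check whether a published cut-off is the midpoint of the group means.

    The derivation of the published cut-offs is not documented and cannot
    be reproduced from group summary statistics alone; this helper makes
    that explicit in reports instead of silently adopting the cut.
    """
    derived = (mean_a + mean_b) / 2.0
    return {
        "midpoint_of_means": float(derived),
        "published": float(published),
        "reproduces_published": bool(abs(derived - published) <= atol),
    }
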