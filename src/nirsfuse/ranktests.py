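"""Rank-based separability tests for feature distributions across classes.

Validates that a feature separates activity classes without assuming
normality: the Mann-Whitney U test for two groups (motor vs. no-motor) and
the Kruskal-Wallis H test across the three classes (rest, MD, SN), both with
midrank tie handling and a 0.05 decision level.

Statistic conventions: U reported is U1 (first sample); exact p-values come
from full enumeration of rank assignments when the pooled sample is small
(n1 + n2 <= 12) and tie-free, otherwise the normal approximation with tie
and continuity corrections is used.  H uses the chi-square approximation
with (groups - 1) degrees of freedom and the tie-correction divisor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
_EXACT_MAX_N = 12


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact-enumeration" | "normal-approx" | "chi2-approx"
    tie_correction_applied: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def reject_at_05(self) -> bool:
        return self.p_value < ALPHA


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U (U1 of the first sample) with automatic method choice."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    ties = _has_ties(np.concatenate([x, y]))
    exact = (x.size + y.size) <= _EXACT_MAX_N and not ties
    res = stats.mannwhitneyu(
        x,
        y,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        method="exact-enumeration" if exact else "normal-approx",
        tie_correction_applied=ties and not exact,
    )


def kruskal_h(groups: list[np.ndarray]) -> TestResult:
    """Kruskal-Wallis H across >= 2 groups (chi-square approximation).

    The fully degenerate case (every pooled value identical) returns H = 0,
    p = 1 rather than erroring, so constant features report "no separation".
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("need a total of >= 3 observations")
    ties = _has_ties(pooled)
    if np.unique(pooled).size == 1:
        return TestResult(0.0, 1.0, "chi2-approx", True)
    res = stats.kruskal(*groups)
    return TestResult(float(res.statistic), min(1.0, float(res.pvalue)), "chi2-approx", ties)


def feature_separability_report(features: pd.DataFrame, feature_name: str) -> dict[str, TestResult]:
    """Both rank tests for one feature column of a labelled feature table.

    Kruskal-Wallis compares the three activity classes; Mann-Whitney
    compares motor epochs (labels 2 and 3 pooled) against rest (label 1).
    All three label codes must be present.
    """
    if feature_name not in features.columns:
        raise KeyError(f"feature {feature_name!r} not in table")
    labels = features["label"].to_numpy(dtype=int)
    missing = {1, 2, 3} - set(np.unique(labels))
    if missing:
        raise ValueError(f"label class(es) {sorted(missing)} absent from the feature table")
    vals = features[feature_name].to_numpy(dtype=float)
    groups = [vals[labels == c] for c in (1, 2, 3)]
    motor = vals[(labels == 2) | (labels == 3)]
    rest = vals[labels == 1]
    return {
        "kruskal": kruskal_h(groups),
        "mannwhitney": mann_whitney_u(motor, rest),
    }


def separability_table(features: pd.DataFrame, feature_names: list[str] | None = None) -> pd.DataFrame:
    """Tabulated rank tests: test,feature,statistic,p_value,decision_at_0.05."""
    if feature_names is None:
        feature_names = [c for c in features.columns if c != "label"]
    rows = []
    for name in feature_names:
        for test, res in feature_separability_report(features, name).items():
            rows.append(
                {
                    "test": test,
                    "feature": name,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "decision_at_0.05": "reject" if res.reject_at_05 else "retain",
                }
            )
    return pd.DataFrame(rows)
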