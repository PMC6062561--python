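"""Two-group statistics: Cohen's d, Student's t-test, Bonferroni coding.

Effect sizes are absolute mean differences divided by the (n-1)-weighted
pooled standard deviation; p-values come from the pooled-variance
(Student, not Welch) two-sided unpaired t-test.  Significance codes follow
the convention o (n.s.), + (p < 0.05), ++ (p < 0.001), with the Bonferroni
variant dividing both thresholds by the family size m (default 84, the
number of volumetric features tested).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import COVARIATE_FEATURES, FeatureMatrix

#: default Bonferroni family size: 86 features minus the age/gender covariates
DEFAULT_FAMILY_SIZE = 84

SIG_NONE, SIG_05, SIG_001 = "o", "+", "++"


def cohens_d_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> float:
    """Cohen's d = |mean1 - mean2| / pooled SD, pooled with n-1 weights."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    diff = abs(mean1 - mean2)
    if pooled_var == 0:
        if diff == 0:
            return 0.0
        raise ValueError("pooled SD is zero with unequal means (infinite d)")
    return diff / np.sqrt(pooled_var)


def cohens_d(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return cohens_d_from_summary(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )


def ttest_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, int, float]:
    """Pooled-variance Student's t; returns (t, df, two-sided p)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if pooled_var == 0:
        if mean1 == mean2:
            return 0.0, n1 + n2 - 2, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(t), n1 + n2 - 2, float(p)


def ttest(x, y) -> tuple[float, int, float]:
    """Raw-data variant; delegates to the summary path so both agree exactly."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return ttest_from_summary(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )


def significance_code(p: float, m: int = 1) -> str:
    """o / + / ++ code for a p-value at family size m (m=1: uncorrected)."""
    if m <= 0:
        raise ValueError("family size m must be positive")
    if not 0 <= p <= 1:
        raise ValueError(f"p-value out of range: {p}")
    if p < 0.001 / m:
        return SIG_001
    if p < 0.05 / m:
        return SIG_05
    return SIG_NONE


def bonferroni(p_values, m: int | None = None) -> list[str]:
    """Bonferroni-corrected significance codes for a family of tests."""
    p_values = list(p_values)
    if m is None:
        m = max(len(p_values), 1)
    if m < len(p_values):
        raise ValueError(f"family size m={m} smaller than number of tests")
    return [significance_code(p, m) for p in p_values]


@dataclass
class GroupComparison:
    """One feature's two-group comparison row."""

    feature: str
    group_pos: str
    group_neg: str
    mean_pos: float
    sd_pos: float
    n_pos: int
    mean_neg: float
    sd_neg: float
    n_neg: int
    d: float
    p: float
    sig_raw: str
    sig_bonferroni: str


def compare_feature(
    x_pos, x_neg, feature: str, group_pos: str, group_neg: str, m: int = DEFAULT_FAMILY_SIZE
) -> GroupComparison:
    x_pos = np.asarray(x_pos, float)
    x_neg = np.asarray(x_neg, float)
    d = cohens_d(x_pos, x_neg)
    _, _, p = ttest(x_pos, x_neg)
    return GroupComparison(
        feature=feature,
        group_pos=group_pos,
        group_neg=group_neg,
        mean_pos=float(x_pos.mean()),
        sd_pos=float(x_pos.std(ddof=1)),
        n_pos=len(x_pos),
        mean_neg=float(x_neg.mean()),
        sd_neg=float(x_neg.std(ddof=1)),
        n_neg=len(x_neg),
        d=d,
        p=p,
        sig_raw=significance_code(p, 1),
        sig_bonferroni=significance_code(p, m),
    )


def compare_groups(
    fm: FeatureMatrix,
    labels: pd.Series,
    group_pos: str,
    group_neg: str,
    features: list[str] | None = None,
    m: int | None = None,
) -> pd.DataFrame:
    """Per-feature comparison of two diagnosis groups.

    ``labels`` maps subject id to group; the positive group is the diseased
    one.  Age and gender covariates are excluded from testing.  Returns one
    row per feature, sorted by descending effect size.
    """
    labels = pd.Series(labels)
    if features is None:
        features = [c for c in fm.data.columns if c not in COVARIATE_FEATURES]
    if m is None:
        m = len(features)
    pos_ids = labels.index[labels == group_pos].intersection(fm.data.index)
    neg_ids = labels.index[labels == group_neg].intersection(fm.data.index)
    if len(pos_ids) < 2 or len(neg_ids) < 2:
        raise ValueError(
            f"need >= 2 subjects per group, got {len(pos_ids)} {group_pos} / "
            f"{len(neg_ids)} {group_neg}"
        )
    rows = []
    for feature in features:
        comp = compare_feature(
            fm.data.loc[pos_ids, feature],
            fm.data.loc[neg_ids, feature],
            feature, group_pos, group_neg, m=m,
        )
        rows.append(vars(comp))
    out = pd.DataFrame(rows)
    return out.sort_values("d", ascending=False, kind="mergesort").reset_index(drop=True)
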