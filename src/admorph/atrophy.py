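"""Log-transform atrophy rates and clinical-trial sample sizes.

The volume change of a structure between a baseline volume ``v1`` and a
follow-up volume ``v2`` is expressed on the log scale,

    rate = ln(v2 / v1) * 100  [%],

which makes rates anti-symmetric under swapping the visits and exactly
additive over chained intervals.  A positive rate is a volume increase
(used for ventricles); "atrophy rate" and "volume change" are
interchangeable here.

The per-arm sample size needed to detect a fraction of the group's mean
rate with given power and significance is

    N = (z_{1-beta} + z_{1-alpha/2})^2 * 2 sigma_g^2 / Delta^2,

with Delta = f * mu_g uncorrected, or Delta = f * (mu_g - mu_healthy) when
the detectable effect is reduced to the excess change over normal aging
(assuming sigma_healthy ~= sigma_g), which is usually more conservative.
Defaults: f = 0.25, power 0.80, alpha 0.05.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

#: z-value conventions: the two-decimal approximations commonly printed in
#: the trial-design literature, or exact normal quantiles
Z_CONVENTIONS = ("paper", "exact")


def atrophy_rate(v1: float, v2: float) -> float:
    """Log-scale volume change in percent between two positive volumes."""
    if v1 <= 0 or v2 <= 0:
        raise ValueError(f"volumes must be positive, got v1={v1}, v2={v2}")
    return math.log(v2 / v1) * 100.0


def rates_from_volumes(baseline: pd.DataFrame, followup: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-structure rates from wide baseline/follow-up tables.

    Subjects missing from either table are dropped (never imputed); both
    tables must share structure columns and contain positive volumes.
    """
    common_subjects = baseline.index.intersection(followup.index)
    common_cols = [c for c in baseline.columns if c in followup.columns]
    b = baseline.loc[common_subjects, common_cols].to_numpy(float)
    f = followup.loc[common_subjects, common_cols].to_numpy(float)
    if (b <= 0).any() or (f <= 0).any():
        raise ValueError("non-positive volumes; rates undefined")
    rates = np.log(f / b) * 100.0
    return pd.DataFrame(rates, index=common_subjects, columns=common_cols)


def _z_values(power: float, alpha: float, convention: str) -> tuple[float, float]:
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ValueError("power and alpha must lie in (0, 1)")
    if convention == "paper":
        if (power, alpha) == (0.80, 0.05):
            return 0.84, 1.96
        # two-decimal approximation of the exact quantiles
        return (
            round(float(sps.norm.ppf(power)), 2),
            round(float(sps.norm.ppf(1 - alpha / 2)), 2),
        )
    if convention == "exact":
        return float(sps.norm.ppf(power)), float(sps.norm.ppf(1 - alpha / 2))
    raise ValueError(f"unknown z convention {convention!r}; choose from {Z_CONVENTIONS}")


def sample_size(
    mu_g: float,
    sigma_g: float,
    effect_fraction: float = 0.25,
    power: float = 0.80,
    alpha: float = 0.05,
    mu_healthy: float | None = None,
    z_convention: str = "paper",
    rounding: str = "nearest",
) -> int:
    """Per-arm subject count to detect ``effect_fraction`` of the mean rate.

    With ``mu_healthy`` given, the detectable difference is the excess over
    normal aging, Delta = f * (mu_g - mu_healthy).  ``rounding`` is
    ``"nearest"`` (table-reproduction default) or ``"ceil"`` (conventional
    trial-design practice).
    """
    if sigma_g < 0:
        raise ValueError("sigma_g must be non-negative")
    delta = effect_fraction * (mu_g if mu_healthy is None else mu_g - mu_healthy)
    if delta == 0:
        raise ValueError("zero detectable effect (Delta = 0): sample size infinite")
    z_power, z_alpha = _z_values(power, alpha, z_convention)
    n = (z_power + z_alpha) ** 2 * (2 * sigma_g**2) / delta**2
    if rounding == "nearest":
        return int(round(n))
    if rounding == "ceil":
        return int(math.ceil(n)) if n > 0 else 0
    raise ValueError(f"unknown rounding {rounding!r}")


def summarize_atrophy(
    rates: pd.DataFrame,
    labels: pd.Series,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Per structure x group mean, SD and n of rates.

    ``rates`` is subjects x structures; ``labels`` maps subject id to group.
    """
    labels = pd.Series(labels)
    if groups is None:
        groups = list(pd.unique(labels.loc[labels.index.intersection(rates.index)]))
    rows = []
    for group in groups:
        ids = labels.index[labels == group].intersection(rates.index)
        if len(ids) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 subjects with rates")
        sub = rates.loc[ids]
        for structure in rates.columns:
            rows.append(
                {
                    "structure": structure,
                    "group": group,
                    "mean": float(sub[structure].mean()),
                    "sd": float(sub[structure].std(ddof=1)),
                    "n": int(len(ids)),
                }
            )
    return pd.DataFrame(rows)


def sample_size_table(
    summary: pd.DataFrame,
    healthy_group: str = "HC",
    groups: list[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Uncorrected and normal-aging-corrected sample sizes per structure/group.

    ``summary`` is the output of :func:`summarize_atrophy`.  Structures whose
    mean rate (or excess over the healthy rate) is zero get a missing value.
    """
    healthy = summary[summary["group"] == healthy_group].set_index("structure")["mean"]
    if groups is None:
        groups = [g for g in pd.unique(summary["group"]) if g != healthy_group]
    rows = []
    for group in groups:
        sub = summary[summary["group"] == group]
        for _, r in sub.iterrows():
            row = {"structure": r["structure"], "group": group,
                   "mu_g": r["mean"], "sigma_g": r["sd"]}
            try:
                row["n_uncorrected"] = sample_size(r["mean"], r["sd"], **kwargs)
            except ValueError:
                row["n_uncorrected"] = np.nan
            mu_h = healthy.get(r["structure"], np.nan)
            row["mu_healthy"] = mu_h
            if pd.isna(mu_h):
                row["n_corrected"] = np.nan
            else:
                try:
                    row["n_corrected"] = sample_size(
                        r["mean"], r["sd"], mu_healthy=float(mu_h), **kwargs
                    )
                except ValueError:
                    row["n_corrected"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
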