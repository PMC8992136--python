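"""Stratified descriptive statistics and distributional screens.

Reproduces the study-table layout: per-sex and pooled means +/- SD with 95%
confidence intervals for the continuous variables, counts with one-decimal
percentages for categorical levels, and the Kolmogorov-Smirnov (Lilliefors)
and Levene screens for normality and variance homogeneity.

Display rounding follows the printed precision: percentages half-up to one
decimal, means/SDs half-up to two.  Confidence intervals use t-distribution
quantiles.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .errors import DegenerateDataError

__all__ = [
    "round_half_up",
    "percentage",
    "pooled_mean",
    "describe",
    "table1",
    "normality_test",
    "homogeneity_test",
]

GROUP_LABELS = {"F": "women", "M": "men"}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of the printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(n: int, group_n: int, ndigits: int = 1) -> float:
    """One-decimal percentage n/group_n as printed in the frequency cells."""
    if group_n <= 0:
        raise DegenerateDataError("percentage undefined for an empty group")
    return round_half_up(100.0 * n / group_n, ndigits)


def pooled_mean(ns, means) -> float:
    """n-weighted average of subgroup means (the pooled 'total' column)."""
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    if ns.sum() <= 0:
        raise DegenerateDataError("pooled mean undefined for empty groups")
    return float(np.sum(ns * means) / ns.sum())


def _continuous_row(label, group, values) -> dict:
    values = pd.Series(values).dropna().to_numpy(dtype=float)
    n = len(values)
    row = dict(label=label, group=group, n=n, pct=np.nan,
               mean=np.nan, sd=np.nan, ci_low=np.nan, ci_high=np.nan)
    if n == 0:
        return row
    row["mean"] = float(values.mean())
    if n >= 2:
        sd = float(values.std(ddof=1))
        row["sd"] = sd
        half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        row["ci_low"], row["ci_high"] = row["mean"] - half, row["mean"] + half
    return row


def describe(
    table: pd.DataFrame,
    continuous: list[str],
    categorical: dict[str, list] | None = None,
    by: str = "sex",
) -> pd.DataFrame:
    """Per-group and total descriptive rows.

    Continuous variables get n / mean / SD / CI95 rows per group plus a
    pooled total; categorical variables (``{column: ordered levels}``) get
    count and one-decimal percentage rows.  Empty strata yield an ``n=0``
    row with undefined (NaN) moments rather than being dropped.
    """
    if len(table) == 0:
        raise DegenerateDataError("describe requires a non-empty table")
    categorical = categorical or {}
    groups = [(GROUP_LABELS.get(g, str(g)), sub) for g, sub in table.groupby(by, sort=True)]
    groups.append(("total", table))
    rows = []
    for var in continuous:
        for gname, sub in groups:
            rows.append(_continuous_row(var, gname, sub[var]))
    for var, levels in categorical.items():
        for gname, sub in groups:
            gn = len(sub)
            counts = sub[var].value_counts()
            for level in levels:
                n = int(counts.get(level, 0))
                rows.append(dict(
                    label=f"{var}={level}", group=gname, n=n,
                    pct=percentage(n, gn) if gn else np.nan,
                    mean=np.nan, sd=np.nan, ci_low=np.nan, ci_high=np.nan,
                ))
    return pd.DataFrame(rows)


def table1(classified: pd.DataFrame) -> pd.DataFrame:
    """Study-style descriptive table from a classified cohort.

    Expects the columns added by :func:`metspath.criteria.add_mets_columns`.
    """
    continuous = ["age", "height_cm", "weight_kg", "bmi", "sbp_mmhg",
                  "dbp_mmhg", "fg_mgdl", "tg_mgdl", "hdl_mgdl", "wc_cm"]
    categorical = {
        "age_group": ["young", "middle", "older"],
        "bmi_band": ["normal", "overweight", "obesity"],
        "mets_count": sorted(classified["mets_count"].unique()),
        "flag_wc": [True], "flag_tg": [True], "flag_hdl": [True],
        "flag_bp": [True], "flag_fg": [True],
    }
    return describe(classified, continuous, categorical)


def normality_test(values) -> tuple[float, float]:
    """Kolmogorov-Smirnov test of normality with Lilliefors correction.

    The reference normal has mean/SD estimated from the sample, so the
    Lilliefors null distribution is used for the p-value.  Requires n >= 5;
    constant input is degenerate.
    """
    values = pd.Series(values).dropna().to_numpy(dtype=float)
    if len(values) < 5:
        raise DegenerateDataError("normality test requires n >= 5")
    if np.ptp(values) == 0:
        raise DegenerateDataError("normality test undefined for constant input")
    stat, p = lilliefors(values, dist="norm")
    return float(stat), float(p)


def homogeneity_test(*groups) -> tuple[float, float]:
    """Levene's test of variance homogeneity (center = mean), F reference."""
    if len(groups) == 1:
        groups = tuple(groups[0])  # accept a single iterable of groups
    arrays = [pd.Series(g).dropna().to_numpy(dtype=float) for g in groups]
    if len(arrays) < 2:
        raise DegenerateDataError("homogeneity test requires >= 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise DegenerateDataError("each group needs n >= 2")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("homogeneity test undefined: all observations identical")
    stat, p = stats.levene(*arrays, center="mean")
    return float(stat), float(p)
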