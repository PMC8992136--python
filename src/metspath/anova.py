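"""Two-way factorial ANOVA with eta-squared bands and Tukey post-hoc tests.

The study design (age group x BMI band) is unbalanced, so Type III sums of
squares with sum-to-zero contrasts are used.  Effect sizes are classical
eta-squared (SS_effect / corrected SS_total) by default, with partial
eta-squared available, and are labelled with the interpretation bands
none (<=0.04), minimum (<=0.25), moderate (<=0.64), strong (>0.64).
Pairwise contrasts use the Tukey-Kramer studentized-range procedure.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import EstimabilityError

__all__ = ["AnovaResult", "PosthocResult", "eta2_band", "two_way_anova", "tukey_posthoc"]

EFFECTS = ["factorA", "factorB", "interaction"]


@dataclass(frozen=True)
class AnovaResult:
    effect: str          # factorA | factorB | interaction
    F: float
    p: float
    ss: float
    df: float
    eta2: float
    eta2_band: str


@dataclass(frozen=True)
class PosthocResult:
    pair: tuple
    mean_diff: float
    p_adj: float
    significant: bool


def eta2_band(eta2: float) -> str:
    if eta2 <= 0.04:
        return "none"
    if eta2 <= 0.25:
        return "minimum"
    if eta2 <= 0.64:
        return "moderate"
    return "strong"


def two_way_anova(y, a, b, eta: str = "classical") -> list[AnovaResult]:
    """Type III two-way ANOVA of ``y`` on crossed factors ``a`` and ``b``.

    Every cell of the factor cross must be observed; an empty cell raises
    :class:`EstimabilityError` naming it.  A constant response returns zero
    F and eta-squared for all three effects.
    """
    if eta not in ("classical", "partial"):
        raise ValueError("eta must be 'classical' or 'partial'")
    df = pd.DataFrame({
        "y": np.asarray(y, dtype=float),
        "a": np.asarray(a, dtype=object),
        "b": np.asarray(b, dtype=object),
    })
    la, lb = df["a"].unique(), df["b"].unique()
    if len(la) < 2 or len(lb) < 2:
        raise EstimabilityError("both factors need at least two observed levels")
    observed = set(map(tuple, df[["a", "b"]].itertuples(index=False)))
    for cell in itertools.product(la, lb):
        if cell not in observed:
            raise EstimabilityError(f"empty design cell {cell}; model not estimable")
    n_cells = len(la) * len(lb)
    if len(df) <= n_cells:
        raise EstimabilityError("need more observations than design cells")

    ss_total = float(np.sum((df["y"] - df["y"].mean()) ** 2))
    if ss_total == 0.0:
        return [AnovaResult(e, 0.0, 1.0, 0.0, np.nan, 0.0, "none") for e in EFFECTS]

    model = ols("y ~ C(a, Sum) * C(b, Sum)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tab = anova_lm(model, typ=3)
    key = {"factorA": "C(a, Sum)", "factorB": "C(b, Sum)",
           "interaction": "C(a, Sum):C(b, Sum)"}
    ss_resid = float(tab.loc["Residual", "sum_sq"])
    perfect_fit = ss_resid <= 1e-12 * ss_total
    results = []
    for effect in EFFECTS:
        row = tab.loc[key[effect]]
        ss = float(row["sum_sq"])
        denom = ss_total if eta == "classical" else ss + ss_resid
        e2 = ss / denom if denom > 0 else 0.0
        F, p = float(row["F"]), float(row["PR(>F)"])
        if perfect_fit:
            # zero residual variance: F is 0 for absent effects, infinite otherwise
            F = np.inf if ss > 1e-12 * ss_total else 0.0
            p = 0.0 if np.isinf(F) else 1.0
        results.append(AnovaResult(
            effect=effect,
            F=F,
            p=p,
            ss=ss,
            df=float(row["df"]),
            eta2=e2,
            eta2_band=eta2_band(e2),
        ))
    return results


def tukey_posthoc(y, g, alpha: float = 0.05) -> list[PosthocResult]:
    """Tukey-Kramer all-pairs comparisons with studentized-range adjustment.

    Singleton levels (n = 1) cannot contribute a within-group variance and
    are excluded with a warning.  Pairs are reported once each, ordered by
    sorted level name.
    """
    df = pd.DataFrame({"y": np.asarray(y, dtype=float), "g": np.asarray(g, dtype=object)})
    sizes = df.groupby("g").size()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        warnings.warn(f"excluding singleton level(s) {singletons} from post-hoc tests")
        df = df[~df["g"].isin(singletons)]
    if df["g"].nunique() < 2:
        raise EstimabilityError("post-hoc tests need >= 2 levels with n >= 2")
    res = pairwise_tukeyhsd(df["y"].to_numpy(), df["g"].to_numpy(), alpha=alpha)
    levels = list(res.groupsunique)
    out = []
    for (i, j), diff, p, rej in zip(
        itertools.combinations(range(len(levels)), 2),
        res.meandiffs, res.pvalues, res.reject,
    ):
        out.append(PosthocResult(
            pair=(levels[i], levels[j]),
            mean_diff=float(diff),
            p_adj=float(p),
            significant=bool(rej),
        ))
    return out
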