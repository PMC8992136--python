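"""Harmonised (JIS) metabolic-syndrome classification and study stratifications.

A subject is diagnosed with MetS when at least three of five components are
elevated: waist circumference (sex-specific cutoff), triglycerides, reduced
HDL-cholesterol (sex-specific), blood pressure (systolic OR diastolic,
counted once) and fasting glucose.  Drug treatment for a component counts as
elevated for that component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ClassificationError

__all__ = [
    "JISCutoffs",
    "MetSStatus",
    "Stratum",
    "MetSClassifier",
    "classify_mets",
    "add_mets_columns",
    "assign_stratum",
    "assign_age_group",
    "assign_bmi_band",
    "filter_cohort",
]

logger = logging.getLogger(__name__)

COMPONENTS = ["wc", "tg", "hdl", "bp", "fg"]

AGE_GROUPS = ["young", "middle", "older"]      # 18-39, 40-64, >=65
BMI_BANDS = ["normal", "overweight", "obesity"]  # <25, 25-29.9, >=30


@dataclass(frozen=True)
class JISCutoffs:
    """Component cutoffs; defaults are the harmonised European values."""

    wc_female: float = 88.0   # cm, elevated if >=
    wc_male: float = 102.0
    tg: float = 150.0         # mg/dL, elevated if >=
    hdl_female: float = 50.0  # mg/dL, reduced if <
    hdl_male: float = 40.0
    sbp: float = 130.0        # mmHg, elevated if >=
    dbp: float = 85.0
    fg: float = 100.0         # mg/dL, elevated if >=

    @classmethod
    def from_yaml(cls, path) -> "JISCutoffs":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass(frozen=True)
class MetSStatus:
    flags: dict
    count: int
    diagnosed: bool


@dataclass(frozen=True)
class Stratum:
    age_group: str
    bmi_band: str


class MetSClassifier(BaseEstimator, TransformerMixin):
    """Stateless transformer adding JIS flags, count, diagnosis and strata.

    ``transform`` takes a cohort table (documented CSV schema) and returns it
    with ``bmi``, per-component boolean ``flag_*`` columns, ``mets_count``,
    ``mets_diagnosed``, ``age_group`` and ``bmi_band`` appended.
    """

    def __init__(self, cutoffs: JISCutoffs | None = None):
        self.cutoffs = cutoffs

    def fit(self, X, y=None):
        self.cutoffs_ = self.cutoffs or JISCutoffs()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "cutoffs_"):
            self.fit(X)
        return add_mets_columns(X, self.cutoffs_)


def _check_sex(sex: pd.Series) -> None:
    bad = ~sex.isin(["F", "M"])
    if bad.any():
        raise ClassificationError(
            f"unknown sex code(s) {sorted(sex[bad].unique())}; expected 'F' or 'M'"
        )


def component_flags(df: pd.DataFrame, cutoffs: JISCutoffs | None = None) -> pd.DataFrame:
    """Per-component elevation flags (cutoff OR treatment), one column each."""
    c = cutoffs or JISCutoffs()
    _check_sex(df["sex"])
    female = df["sex"] == "F"
    def _treated(name):
        col = f"treated_{name}"
        if col in df.columns:
            return df[col].fillna(0).astype(bool)
        return pd.Series(False, index=df.index)

    treated = {f: _treated(f) for f in ("bp", "tg", "hdl", "fg")}
    flags = pd.DataFrame(index=df.index)
    flags["wc"] = df["wc_cm"] >= np.where(female, c.wc_female, c.wc_male)
    flags["tg"] = (df["tg_mgdl"] >= c.tg) | treated["tg"]
    flags["hdl"] = (df["hdl_mgdl"] < np.where(female, c.hdl_female, c.hdl_male)) | treated["hdl"]
    flags["bp"] = (df["sbp_mmhg"] >= c.sbp) | (df["dbp_mmhg"] >= c.dbp) | treated["bp"]
    flags["fg"] = (df["fg_mgdl"] >= c.fg) | treated["fg"]
    return flags


def classify_mets(record, cutoffs: JISCutoffs | None = None) -> MetSStatus:
    """Classify one subject (mapping or Series with the cohort column names)."""
    df = pd.DataFrame([dict(record)])
    flags = component_flags(df, cutoffs).iloc[0]
    count = int(flags.sum())
    return MetSStatus(flags=flags.to_dict(), count=count, diagnosed=count >= 3)


def assign_age_group(age) -> pd.Series:
    """Map ages to young (18-39) / middle (40-64) / older (>=65)."""
    age = pd.Series(np.asarray(age, dtype=float))
    return pd.cut(age, bins=[18, 40, 65, np.inf], right=False,
                  labels=AGE_GROUPS, include_lowest=True).astype(object)


def assign_bmi_band(bmi) -> pd.Series:
    """Map BMI to normal (<25, absorbing underweight) / overweight / obesity."""
    bmi = pd.Series(np.asarray(bmi, dtype=float))
    return pd.cut(bmi, bins=[0, 25, 30, np.inf], right=False,
                  labels=BMI_BANDS).astype(object)


def assign_stratum(record) -> Stratum:
    """Age-group x BMI-band stratum of one subject."""
    age = float(record["age"])
    if "bmi" in record:
        bmi = float(record["bmi"])
    else:
        bmi = float(record["weight_kg"]) / (float(record["height_cm"]) / 100.0) ** 2
    return Stratum(
        age_group=assign_age_group([age]).iloc[0],
        bmi_band=assign_bmi_band([bmi]).iloc[0],
    )


def add_mets_columns(df: pd.DataFrame, cutoffs: JISCutoffs | None = None) -> pd.DataFrame:
    out = df.copy()
    out["bmi"] = out["weight_kg"] / (out["height_cm"] / 100.0) ** 2
    flags = component_flags(out, cutoffs)
    for comp in COMPONENTS:
        out[f"flag_{comp}"] = flags[comp]
    out["mets_count"] = flags.sum(axis=1).astype(int)
    out["mets_diagnosed"] = out["mets_count"] >= 3
    out["age_group"] = assign_age_group(out["age"]).to_numpy()
    out["bmi_band"] = assign_bmi_band(out["bmi"]).to_numpy()
    return out


_REQUIRED_FOR_CLASSIFICATION = [
    "sex", "age", "height_cm", "weight_kg", "wc_cm", "sbp_mmhg", "dbp_mmhg",
    "fg_mgdl", "tg_mgdl", "hdl_mgdl",
]

FILTER_RULES = ["age_under_18", "missing_required", "not_diagnosed"]


def filter_cohort(
    table: pd.DataFrame,
    rules: list[str] = FILTER_RULES,
    cutoffs: JISCutoffs | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Apply exclusion rules in order; return (retained table, per-rule tally).

    Rules: ``age_under_18`` (age < 18), ``missing_required`` (any missing
    classification field), ``not_diagnosed`` (fewer than three elevated
    components).  The tally counts rows removed by each rule in application
    order; the counts under the reversed order are logged for transparency.
    """
    unknown = [r for r in rules if r not in FILTER_RULES]
    if unknown:
        raise ValueError(f"unknown filter rule(s): {unknown}")

    def removed(df, rule):
        if rule == "age_under_18":
            return df["age"] < 18
        if rule == "missing_required":
            return df[_REQUIRED_FOR_CLASSIFICATION].isna().any(axis=1)
        complete = ~df[_REQUIRED_FOR_CLASSIFICATION].isna().any(axis=1)
        mask = pd.Series(False, index=df.index)
        if complete.any():
            sub = df[complete]
            mask.loc[sub.index] = component_flags(sub, cutoffs).sum(axis=1) < 3
        return mask

    retained = table
    tally: dict[str, int] = {}
    for rule in rules:
        mask = removed(retained, rule)
        tally[rule] = int(mask.sum())
        retained = retained[~mask]
    if len(rules) > 1:
        rev, rt = table, {}
        for rule in reversed(rules):
            mask = removed(rev, rule)
            rt[rule] = int(mask.sum())
            rev = rev[~mask]
        logger.info("exclusion tally (stated order): %s; (reversed order): %s", tally, rt)
    return retained.reset_index(drop=True), tally
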