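"""Synthetic cardiometabolic cohort generator.

Builds subject-level cohorts with (i) configurable per-sex marginal moments for
age, anthropometrics and the five metabolic-syndrome component measurements and
(ii) a configurable linear structural skeleton (a DAG of standardized path
coefficients, by default age -> BMI -> each component -> a latent risk score).

Generation proceeds variable by variable in topological order on a
standardized scale, where every variable is its parents' weighted sum plus an
independent Gaussian disturbance scaled so the population variance is one;
afterwards each observed column is affinely rescaled, per sex, to the
configured mean and SD.  Affine rescaling preserves the correlation skeleton,
so a path model fitted to a generated cohort recovers the configured
standardized coefficients up to Monte-Carlo error, while the printed marginal
moments are reproduced essentially exactly.

Out-of-range draws (e.g. a negative triglyceride value) are handled by
redrawing only the disturbance of the offending rows -- the structural linear
part is kept, so truncation does not bias the path coefficients.  Ages are
drawn from a truncated normal on the configured range.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .errors import ConfigError, EmptyCohortError, SchemaError, SpecificationError

__all__ = [
    "COHORT_COLUMNS",
    "GeneratorConfig",
    "table1_marginals",
    "default_structural_coefs",
    "simulate_structural",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: Documented CSV schema, in column order.
COHORT_COLUMNS = [
    "id", "sex", "age", "height_cm", "weight_kg", "wc_cm",
    "sbp_mmhg", "dbp_mmhg", "fg_mgdl", "tg_mgdl", "hdl_mgdl",
    "treated_bp", "treated_tg", "treated_hdl", "treated_fg",
]

MEASUREMENT_COLUMNS = [
    "age", "height_cm", "weight_kg", "wc_cm", "sbp_mmhg", "dbp_mmhg",
    "fg_mgdl", "tg_mgdl", "hdl_mgdl",
]

TREATMENT_COLUMNS = ["treated_bp", "treated_tg", "treated_hdl", "treated_fg"]

#: Short structural names of the generated variables mapped to CSV columns.
VARIABLE_TO_COLUMN = {
    "age": "age",
    "height": "height_cm",
    "wc": "wc_cm",
    "sbp": "sbp_mmhg",
    "dbp": "dbp_mmhg",
    "fg": "fg_mgdl",
    "tg": "tg_mgdl",
    "hdl": "hdl_mgdl",
}

# Published per-sex marginals (mean, SD).  Women n=1914, men n=1667.  BMI is
# the structural variable; weight is derived from BMI and height so the
# kg/m^2 identity holds row-wise (the weight entry is kept for reference).
_WOMEN_TABLE = {
    "age": (64.08, 14.23),
    "height": (157.02, 6.16),
    "weight": (71.55, 13.89),
    "bmi": (28.98, 5.18),
    "wc": (97.69, 11.79),
    "sbp": (134.99, 14.02),
    "dbp": (75.37, 9.64),
    "fg": (107.35, 28.18),
    "tg": (121.04, 58.41),
    "hdl": (59.39, 14.12),
}
_MEN_TABLE = {
    "age": (66.73, 12.89),
    "height": (169.22, 6.84),
    "weight": (83.56, 13.37),
    "bmi": (29.135, 4.00),
    "wc": (103.67, 10.16),
    "sbp": (137.33, 13.68),
    "dbp": (76.04, 10.23),
    "fg": (116.58, 35.23),
    "tg": (130.29, 13.68),
    "hdl": (51.20, 12.77),
}


def table1_marginals(age_source: str = "table") -> dict:
    """Per-sex marginal (mean, SD) parameters of the study population.

    ``age_source`` selects which of the two published (and mutually
    inconsistent) sex-to-age-marginal assignments to use: ``"table"`` gives
    women 64.08 +/- 14.23 y, ``"text"`` gives women 66.73 +/- 12.89 y (the
    assignments are swapped for men).
    """
    women = dict(_WOMEN_TABLE)
    men = dict(_MEN_TABLE)
    if age_source == "text":
        women["age"], men["age"] = men["age"], women["age"]
    elif age_source != "table":
        raise ConfigError(f"age_source must be 'table' or 'text', got {age_source!r}")
    return {"F": women, "M": men}


def default_structural_coefs() -> dict:
    """Default standardized path coefficients of the causal skeleton.

    Age and BMI drive every component (age also drives BMI, negatively, as in
    the fitted population model); the components drive a latent continuous
    risk score ``mets`` with waist circumference dominant, then fasting
    glucose and systolic pressure, with small lipid/diastolic contributions.
    """
    return {
        ("age", "bmi"): -0.18,
        ("age", "wc"): 0.10, ("bmi", "wc"): 0.75,
        ("age", "sbp"): 0.30, ("bmi", "sbp"): 0.10,
        ("age", "dbp"): 0.10, ("bmi", "dbp"): 0.15,
        ("age", "fg"): 0.15, ("bmi", "fg"): 0.15,
        ("age", "tg"): 0.05, ("bmi", "tg"): 0.15,
        ("age", "hdl"): 0.05, ("bmi", "hdl"): -0.20,
        ("wc", "mets"): 0.35, ("fg", "mets"): 0.20, ("sbp", "mets"): 0.15,
        ("dbp", "mets"): 0.05, ("tg", "mets"): 0.05, ("hdl", "mets"): -0.05,
    }


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic cohort generator.

    Parameters
    ----------
    n_women, n_men
        Subgroup sizes (defaults are the study's 1914 / 1667).
    seed
        Seed of the single ``numpy`` generator instance; a fixed seed makes
        the cohort bit-identical across runs.
    age_range
        Closed truncation interval for ages, in years.
    marginal_params
        ``{"F": {var: (mean, sd)}, "M": {...}}``; defaults to the published
        per-sex marginals (:func:`table1_marginals`).
    structural_coefs
        Map from directed edge ``(source, target)`` to standardized
        coefficient; must form a DAG.
    noise_sd
        Optional per-variable disturbance SD override.  When absent the
        disturbance is scaled so each structural variable has unit variance,
        making the configured coefficients exactly the standardized ones.
    treatment_rates
        Per-flag independent Bernoulli rates for the drug-treatment columns
        (default 0 -- the study reports no rates).
    """

    n_women: int = 1914
    n_men: int = 1667
    seed: int = 0
    age_range: tuple[float, float] = (18.0, 102.0)
    marginal_params: dict = field(default_factory=table1_marginals)
    structural_coefs: dict = field(default_factory=default_structural_coefs)
    noise_sd: dict = field(default_factory=dict)
    treatment_rates: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_women < 0 or self.n_men < 0:
            raise ConfigError("n_women and n_men must be non-negative")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigError("age_range must be an increasing interval")
        for sex, params in self.marginal_params.items():
            if sex not in ("F", "M"):
                raise ConfigError(f"unknown sex key {sex!r} in marginal_params")
            for var, (mean, sd) in params.items():
                if sd <= 0:
                    raise ConfigError(f"SD for {var!r} ({sex}) must be > 0, got {sd}")
        g = nx.DiGraph(list(self.structural_coefs))
        if not nx.is_directed_acyclic_graph(g):
            raise SpecificationError("structural_coefs edges must form a DAG")
        for rate in self.treatment_rates.values():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("treatment rates must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "structural_coefs" in raw:
            raw["structural_coefs"] = {
                _parse_edge(k): float(v) for k, v in raw["structural_coefs"].items()
            }
        if "marginal_params" in raw:
            raw["marginal_params"] = {
                sex: {v: (float(ms[0]), float(ms[1])) for v, ms in params.items()}
                for sex, params in raw["marginal_params"].items()
            }
        if "age_range" in raw:
            raw["age_range"] = tuple(float(x) for x in raw["age_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["structural_coefs"] = {
            f"{s} -> {t}": float(b) for (s, t), b in self.structural_coefs.items()
        }
        raw["marginal_params"] = {
            sex: {v: [float(m), float(s)] for v, (m, s) in params.items()}
            for sex, params in self.marginal_params.items()
        }
        raw["age_range"] = [float(x) for x in self.age_range]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _parse_edge(text: str) -> tuple[str, str]:
    parts = [p.strip() for p in text.split("->")]
    if len(parts) != 2 or not all(parts):
        raise SpecificationError(f"cannot parse edge {text!r}; expected 'source -> target'")
    return parts[0], parts[1]


def _zscore(x: np.ndarray) -> np.ndarray:
    if x.size < 2:
        return np.zeros_like(x)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_structural(
    coefs: dict,
    n: int,
    rng: np.random.Generator,
    variables: list[str] | None = None,
    noise_sd: dict | None = None,
) -> pd.DataFrame:
    """Draw ``n`` samples from the linear-Gaussian structural system ``coefs``.

    Each variable equals the coefficient-weighted sum of its parents plus an
    independent Gaussian disturbance.  Unless overridden through ``noise_sd``
    the disturbance variance is set to ``1 - var(linear part)`` (computed from
    the exactly-implied covariance), so every variable has population variance
    one and the configured coefficients are the standardized path weights.
    Exogenous variables are mutually independent standard normals.
    """
    noise_sd = noise_sd or {}
    g = nx.DiGraph(list(coefs))
    if variables:
        g.add_nodes_from(variables)
    if not nx.is_directed_acyclic_graph(g):
        raise SpecificationError("structural_coefs edges must form a DAG")
    order = list(nx.topological_sort(g))
    draws: dict[str, np.ndarray] = {}
    cov: dict[tuple[str, str], float] = {}

    def c(u, v):
        return cov.get((u, v), cov.get((v, u), 0.0))

    for v in order:
        parents = [(p, coefs[(p, v)]) for p in g.predecessors(v)]
        lin = np.zeros(n)
        var_lin = 0.0
        for p, b in parents:
            lin += b * draws[p]
            for q, b2 in parents:
                var_lin += b * b2 * c(p, q)
        if v in noise_sd:
            nv = float(noise_sd[v]) ** 2
        else:
            nv = 1.0 - var_lin
            if nv <= 1e-9:
                raise ConfigError(
                    f"implied disturbance variance for {v!r} is non-positive "
                    f"({nv:.4g}); reduce incoming coefficients or set noise_sd"
                )
        draws[v] = lin + np.sqrt(nv) * rng.standard_normal(n)
        for u in list(draws):
            if u == v:
                continue
            cov[(v, u)] = sum(b * c(p, u) for p, b in parents)
        cov[(v, v)] = var_lin + nv
    return pd.DataFrame({v: draws[v] for v in order})


def _bounded_rescale(
    x: np.ndarray,
    lin: np.ndarray,
    noise_scale: float,
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float = 0.0,
    high: float = np.inf,
    max_iter: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Affinely rescale structural draws to (mean, sd), redrawing out-of-range rows.

    The sample is exactly standardized before the affine map, so the rescaled
    column reproduces the configured moments; rows whose rescaled value falls
    outside (low, high) get a fresh disturbance (the linear part is kept) and
    the map is recomputed.  Returns (structural draws, rescaled values).
    """
    x = x.copy()
    for _ in range(max_iter):
        values = mean + sd * _zscore(x)
        bad = (values <= low) | (values >= high)
        if not bad.any():
            return x, values
        x[bad] = lin[bad] + noise_scale * rng.standard_normal(int(bad.sum()))
    # Pathological marginals only: nudge stragglers just inside the bounds.
    eps = 1e-6 * sd
    return x, np.clip(values, low + eps, high - eps if np.isfinite(high) else None)


def generate_cohort(config: GeneratorConfig, keep_score: bool = False) -> pd.DataFrame:
    """Generate a subject-level cohort table under ``config``.

    Women are generated first, then men, from one seeded generator consumed in
    a fixed variable order, so identical configs give bit-identical cohorts.
    With ``keep_score=True`` the latent continuous risk score(s) of the
    structural system (variables without a CSV column, e.g. ``mets``) are
    appended as extra columns named ``<var>_score``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    blocks = []
    offset = 0
    for sex, n in (("F", config.n_women), ("M", config.n_men)):
        if n == 0:
            continue
        blocks.append(_generate_sex_block(config, sex, n, rng, offset, keep_score))
        offset += n
    if not blocks:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    return pd.concat(blocks, ignore_index=True)


def _generate_sex_block(config, sex, n, rng, offset, keep_score):
    marg = config.marginal_params[sex]
    coefs = config.structural_coefs
    g = nx.DiGraph(list(coefs))
    g.add_nodes_from(v for v in ("age", "bmi") if v in marg)
    order = list(nx.topological_sort(g))

    draws: dict[str, np.ndarray] = {}
    values: dict[str, np.ndarray] = {}
    cov: dict[tuple[str, str], float] = {}

    def c(u, v):
        return cov.get((u, v), cov.get((v, u), 0.0))

    lo, hi = config.age_range
    for v in order:
        parents = [(p, coefs[(p, v)]) for p in g.predecessors(v)]
        if v == "age" and not parents:
            mean, sd = marg["age"]
            a, b = (lo - mean) / sd, (hi - mean) / sd
            age = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
            values["age"] = np.clip(age, lo, hi)
            draws["age"] = _zscore(values["age"])
            cov[("age", "age")] = 1.0
            continue
        lin = np.zeros(n)
        var_lin = 0.0
        for p, b in parents:
            lin += b * draws[p]
            for q, b2 in parents:
                var_lin += b * b2 * c(p, q)
        if v in config.noise_sd:
            nv = float(config.noise_sd[v]) ** 2
        else:
            nv = 1.0 - var_lin
            if nv <= 1e-9:
                raise ConfigError(
                    f"implied disturbance variance for {v!r} is non-positive; "
                    "reduce incoming coefficients or set noise_sd"
                )
        scale = float(np.sqrt(nv))
        x = lin + scale * rng.standard_normal(n)
        if v in marg:
            mean, sd = marg[v]
            x, values[v] = _bounded_rescale(x, lin, scale, rng, mean, sd)
            draws[v] = _zscore(x)
        else:
            draws[v] = _zscore(x) if n > 1 else x
        for u in list(draws):
            if u != v:
                cov[(v, u)] = sum(b * c(p, u) for p, b in parents)
        cov[(v, v)] = 1.0

    # Any measured variable left out of the skeleton: independent normal.
    for var in list(VARIABLE_TO_COLUMN) + ["bmi"]:
        if var in values or var in ("height", "weight") or var not in marg:
            continue
        mean, sd = marg[var]
        x = rng.standard_normal(n)
        x, values[var] = _bounded_rescale(x, np.zeros(n), 1.0, rng, mean, sd)
        draws[var] = _zscore(x)

    # Height: independent per-sex normal unless wired into the skeleton.
    if "height" not in values:
        mean, sd = marg["height"]
        h = rng.normal(mean, sd, size=n)
        h, values["height"] = _bounded_rescale(h, np.full(n, mean), sd, rng, mean, sd)
    # Weight derived so BMI = weight / (height/100)^2 holds exactly.
    values["weight"] = values["bmi"] * (values["height"] / 100.0) ** 2

    out = pd.DataFrame({
        "id": [f"{sex}{offset + i + 1:06d}" for i in range(n)],
        "sex": sex,
    })
    for var, col in VARIABLE_TO_COLUMN.items():
        out[col] = values[var]
    out["weight_kg"] = values["weight"]
    for flag in TREATMENT_COLUMNS:
        rate = float(config.treatment_rates.get(flag, 0.0))
        out[flag] = (rng.random(n) < rate).astype(int)
    out = out[COHORT_COLUMNS]
    if keep_score:
        for v in order:
            if v not in marg and v not in ("height", "weight"):
                out[f"{v}_score"] = draws[v]
    return out


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort to the documented CSV dialect (UTF-8, F/M sex, 0/1 flags)."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table is missing required column(s): {missing}")
    table[COHORT_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating the schema and numeric parseability."""
    try:
        table = pd.read_csv(path, dtype={"id": str, "sex": str})
    except pd.errors.EmptyDataError:
        raise EmptyCohortError(f"{path}: empty cohort file") from None
    if len(table) == 0:
        raise EmptyCohortError(f"{path}: cohort has a header but no subjects")
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    for col in MEASUREMENT_COLUMNS + TREATMENT_COLUMNS:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: non-numeric value {table[col].iloc[row]!r} in column "
                f"{col!r} at row {row}"
            )
        table[col] = coerced
    return table[COHORT_COLUMNS]
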