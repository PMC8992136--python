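"""Recursive path analysis (observed-variable SEM) with effect decomposition.

The model is a DAG over named, standardized variables.  Each endogenous
variable is regressed on its direct parents after z-scoring; for a recursive
system with uncorrelated disturbances this equation-by-equation least-squares
solution coincides with the maximum-likelihood path solution, so no iterative
fitter is needed.  Per-edge standardized coefficients (beta) come with
standard errors, Student-t statistics (df = n - #parents - 1) and two-sided
p-values; each endogenous variable gets an R-squared and a disturbance term
1 - R-squared summarising unmeasured causes.

Model-implied correlations follow Wright's path-tracing rules, computed in
closed form through the reduced-form identity

    Sigma = (I - B)^-1 Psi (I - B)^-T

where B holds the path coefficients and Psi the exogenous correlation block
plus the disturbance variances.  Observed correlations decompose, per ordered
pair, into a direct effect (the edge coefficient), an indirect effect (sum of
coefficient products over directed paths of length >= 2), and a spurious
remainder (observed minus total).  Fit is summarised by the SRMR -- the root
mean square of the unique off-diagonal residuals between observed and implied
correlations -- with the qualitative bands perfect (~0), very good (<0.05),
adequate (<0.1) and poor otherwise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.base import BaseEstimator

from .criteria import add_mets_columns
from .errors import (
    CollinearityError,
    DegenerateDataError,
    SpecificationError,
)

__all__ = [
    "PathModelSpec",
    "PathModel",
    "EffectDecomposition",
    "FitReport",
    "standardize",
    "fit_path_model",
    "srmr",
    "fit_category",
    "run_mets_sem",
    "default_mets_spec",
]

SRMR_PERFECT_TOL = 1e-8


@dataclass(frozen=True)
class PathModelSpec:
    """A recursive path model: variables, directed edges, exogenous set."""

    variables: tuple
    edges: tuple
    exogenous: tuple

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "edges", tuple((s, t) for s, t in self.edges))
        object.__setattr__(self, "exogenous", tuple(self.exogenous))
        declared = set(self.variables)
        for s, t in self.edges:
            if s not in declared or t not in declared:
                raise SpecificationError(f"edge {s}->{t} uses an undeclared variable")
        undeclared_exo = set(self.exogenous) - declared
        if undeclared_exo:
            raise SpecificationError(f"exogenous variables not declared: {sorted(undeclared_exo)}")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise SpecificationError("path model must be acyclic (recursive)")
        for v in self.exogenous:
            if g.in_degree(v) > 0:
                raise SpecificationError(f"exogenous variable {v!r} has incoming edges")
        implicit_exo = {v for v in self.variables if g.in_degree(v) == 0}
        missing = implicit_exo - set(self.exogenous)
        if missing:
            raise SpecificationError(
                f"variables without parents must be declared exogenous: {sorted(missing)}"
            )

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        return g

    @property
    def endogenous(self) -> tuple:
        return tuple(v for v in self.variables if v not in self.exogenous)

    def parents(self, v) -> list:
        return sorted(s for s, t in self.edges if t == v)

    @classmethod
    def from_yaml(cls, path) -> "PathModelSpec":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        edges = []
        for e in raw.get("edges", []):
            parts = [p.strip() for p in str(e).split("->")]
            if len(parts) != 2 or not all(parts):
                raise SpecificationError(f"cannot parse edge {e!r}; expected 'source -> target'")
            edges.append(tuple(parts))
        return cls(
            variables=tuple(raw["variables"]),
            edges=tuple(edges),
            exogenous=tuple(raw.get("exogenous", [])),
        )


@dataclass(frozen=True)
class EffectDecomposition:
    source: str
    target: str
    direct: float
    indirect: float
    spurious: float

    @property
    def total(self) -> float:
        return self.direct + self.indirect


@dataclass(frozen=True)
class FitReport:
    observed_corr: pd.DataFrame
    implied_corr: pd.DataFrame
    residuals: pd.DataFrame
    srmr: float
    category: str


def fit_category(value: float) -> str:
    """Qualitative SRMR band: perfect (~0) / very_good (<0.05) / adequate (<0.1) / poor."""
    if value < SRMR_PERFECT_TOL:
        return "perfect"
    if value < 0.05:
        return "very_good"
    if value < 0.1:
        return "adequate"
    return "poor"


def standardize(table: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Z-score the given columns (complete cases, SD with denominator n-1)."""
    variables = list(variables) if variables is not None else list(table.columns)
    sub = table[variables].dropna().astype(float)
    out = {}
    for v in variables:
        sd = sub[v].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateDataError(f"variable {v!r} has zero variance; cannot standardize")
        out[v] = (sub[v] - sub[v].mean()) / sd
    return pd.DataFrame(out, index=sub.index)


def srmr(observed: pd.DataFrame, implied: pd.DataFrame) -> FitReport:
    """Standardized root mean square residual between two correlation matrices.

    SRMR is the root of the mean squared residual over the unique
    off-diagonal (lower-triangle) pairs.
    """
    obs = np.asarray(observed, dtype=float)
    imp = np.asarray(implied, dtype=float)
    if obs.shape != imp.shape or obs.shape[0] != obs.shape[1]:
        raise ValueError("observed and implied matrices must be square and same shape")
    if isinstance(observed, pd.DataFrame) and isinstance(implied, pd.DataFrame):
        if list(observed.columns) != list(implied.columns):
            raise ValueError("observed and implied matrices must share variables")
    for name, m in (("observed", obs), ("implied", imp)):
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError(f"{name} matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValueError(f"{name} matrix must have a unit diagonal")
    p = obs.shape[0]
    idx = np.tril_indices(p, k=-1)
    resid = obs - imp
    value = float(np.sqrt(np.mean(resid[idx] ** 2))) if p > 1 else 0.0
    cols = observed.columns if isinstance(observed, pd.DataFrame) else range(p)
    residuals = pd.DataFrame(resid, index=cols, columns=cols)
    obs_df = pd.DataFrame(obs, index=cols, columns=cols)
    imp_df = pd.DataFrame(imp, index=cols, columns=cols)
    return FitReport(obs_df, imp_df, residuals, value, fit_category(value))


class PathModel(BaseEstimator):
    """Estimator for a recursive standardized path model.

    Parameters
    ----------
    spec : PathModelSpec
        The model DAG.  Defaults to the metabolic-syndrome skeleton
        (:func:`default_mets_spec`).
    cond_threshold : float
        Condition number of a parent block above which fitting aborts with
        a collinearity error instead of silently pseudo-inverting.

    Fitted attributes (all keyed by edge ``(source, target)`` or variable):
    ``beta_``, ``se_``, ``t_``, ``p_``, ``r2_``, ``disturbance_``,
    ``exo_corr_``, ``observed_corr_``, ``n_``.
    """

    def __init__(self, spec: PathModelSpec | None = None, cond_threshold: float = 1e8):
        self.spec = spec
        self.cond_threshold = cond_threshold

    # -- estimation ---------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "PathModel":
        spec = self.spec if self.spec is not None else default_mets_spec()
        missing = [v for v in spec.variables if v not in X.columns]
        if missing:
            raise SpecificationError(f"data is missing model variable(s): {missing}")
        Z = standardize(X, spec.variables)
        n = len(Z)
        max_indeg = max((len(spec.parents(v)) for v in spec.endogenous), default=0)
        if n <= max_indeg + 1:
            raise DegenerateDataError(
                f"need n > max in-degree + 1 ({max_indeg + 1}); got n={n}"
            )
        self.spec_ = spec
        self.n_ = n
        self.beta_, self.se_, self.t_, self.p_ = {}, {}, {}, {}
        self.r2_, self.disturbance_ = {}, {}
        for v in spec.endogenous:
            parents = spec.parents(v)
            if not parents:
                continue
            Xp = Z[parents].to_numpy()
            yv = Z[v].to_numpy()
            gram = Xp.T @ Xp
            if np.linalg.cond(gram) > self.cond_threshold:
                raise CollinearityError(
                    f"parent set {parents} of {v!r} is numerically collinear"
                )
            gram_inv = np.linalg.inv(gram)
            beta = gram_inv @ (Xp.T @ yv)
            resid = yv - Xp @ beta
            rss = float(resid @ resid)
            dof = n - len(parents) - 1
            sigma2 = rss / dof
            se = np.sqrt(sigma2 * np.diag(gram_inv))
            tstat = np.divide(beta, se, out=np.full_like(beta, np.inf), where=se > 0)
            pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
            r2 = 1.0 - rss / float(yv @ yv)  # TSS = n-1 on the z-scale
            for j, parent in enumerate(parents):
                edge = (parent, v)
                self.beta_[edge] = float(beta[j])
                self.se_[edge] = float(se[j])
                self.t_[edge] = float(tstat[j])
                self.p_[edge] = float(pval[j])
            self.r2_[v] = float(r2)
            self.disturbance_[v] = float(1.0 - r2)
        exo = list(spec.exogenous)
        self.exo_corr_ = Z[exo].corr() if exo else pd.DataFrame()
        self.observed_corr_ = Z.corr()
        return self

    def _check_fitted(self):
        if not hasattr(self, "beta_"):
            raise RuntimeError("PathModel is not fitted; call fit() first")

    # -- derived quantities -------------------------------------------------

    def _matrices(self):
        """Coefficient matrix B (B[t,s] = beta) and disturbance/exogenous Psi."""
        spec = self.spec_
        order = list(spec.variables)
        ix = {v: i for i, v in enumerate(order)}
        p = len(order)
        B = np.zeros((p, p))
        for (s, t), b in self.beta_.items():
            B[ix[t], ix[s]] = b
        psi = np.zeros((p, p))
        for u in spec.exogenous:
            for v in spec.exogenous:
                psi[ix[u], ix[v]] = 1.0 if u == v else float(self.exo_corr_.loc[u, v])
        for v in spec.endogenous:
            psi[ix[v], ix[v]] = self.disturbance_.get(v, 1.0)
        return order, B, psi

    def implied_correlations(self) -> pd.DataFrame:
        """Model-implied correlation matrix by Wright's tracing rules.

        Computed via the reduced form (I-B)^-1 Psi (I-B)^-T, which for a
        recursive model equals the sum over all valid traces (no loops, at
        most one exogenous-correlation link, no forward-then-backward
        reversal).  The diagonal is fixed at one, the tracing convention for
        standardized variables.
        """
        self._check_fitted()
        order, B, psi = self._matrices()
        inv = np.linalg.inv(np.eye(len(order)) - B)
        sigma = inv @ psi @ inv.T
        np.fill_diagonal(sigma, 1.0)
        return pd.DataFrame(sigma, index=order, columns=order)

    def total_effects(self) -> pd.DataFrame:
        """Directed total effect (direct + indirect) of column on row variable."""
        self._check_fitted()
        order, B, _ = self._matrices()
        total = np.linalg.inv(np.eye(len(order)) - B) - np.eye(len(order))
        return pd.DataFrame(total, index=order, columns=order)

    def decompose_effects(self, source: str, target: str) -> EffectDecomposition:
        """Direct / indirect / spurious split of the observed source-target correlation."""
        self._check_fitted()
        if source == target:
            raise ValueError("source and target must differ")
        for v in (source, target):
            if v not in self.spec_.variables:
                raise SpecificationError(f"{v!r} is not a model variable")
        direct = self.beta_.get((source, target), 0.0)
        total = float(self.total_effects().loc[target, source])
        observed = float(self.observed_corr_.loc[source, target])
        return EffectDecomposition(
            source=source,
            target=target,
            direct=direct,
            indirect=total - direct,
            spurious=observed - total,
        )

    def effects_table(self) -> pd.DataFrame:
        """Decomposition for every ordered pair with an endogenous target."""
        rows = []
        for target in self.spec_.endogenous:
            for source in self.spec_.variables:
                if source == target:
                    continue
                d = self.decompose_effects(source, target)
                rows.append(dict(
                    source=source, target=target, direct=d.direct,
                    indirect=d.indirect, total=d.total, spurious=d.spurious,
                    observed=d.total + d.spurious,
                ))
        return pd.DataFrame(rows)

    def fit_report(self) -> FitReport:
        """SRMR of the fitted model against the observed correlations."""
        self._check_fitted()
        return srmr(self.observed_corr_, self.implied_correlations())

    # -- exports ------------------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        report = self.fit_report()
        return {
            "n": self.n_,
            "edges": [
                {
                    "source": s, "target": t,
                    "beta": self.beta_[(s, t)], "se": self.se_[(s, t)],
                    "t": self.t_[(s, t)], "p": self.p_[(s, t)],
                }
                for (s, t) in self.beta_
            ],
            "r2": dict(self.r2_),
            "disturbance": dict(self.disturbance_),
            "exogenous_correlations": {
                f"{u}~{v}": float(self.exo_corr_.loc[u, v])
                for i, u in enumerate(self.exo_corr_.columns)
                for v in list(self.exo_corr_.columns)[i + 1:]
            },
            "srmr": report.srmr,
            "fit_category": report.category,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_dot(self) -> str:
        """DOT digraph annotated with the fitted coefficients."""
        self._check_fitted()
        lines = ["digraph path_model {", "  rankdir=LR;", "  node [shape=box];"]
        for v in self.spec_.variables:
            label = v
            if v in self.r2_:
                label += f"\\nR2={self.r2_[v]:.3f}"
            lines.append(f'  "{v}" [label="{label}"];')
        for (s, t), b in self.beta_.items():
            star = "*" if self.p_[(s, t)] < 0.05 else ""
            lines.append(f'  "{s}" -> "{t}" [label="{b:.3f}{star}"];')
        lines.append("}")
        return "\n".join(lines)


def fit_path_model(spec: PathModelSpec, data: pd.DataFrame) -> PathModel:
    """Fit a recursive path model; thin wrapper over :class:`PathModel`."""
    return PathModel(spec=spec).fit(data)


# -- metabolic-syndrome front door ------------------------------------------

MODEL_COLUMNS = {
    "age": "age", "bmi": "bmi", "wc": "wc_cm", "sbp": "sbp_mmhg",
    "dbp": "dbp_mmhg", "fg": "fg_mgdl", "tg": "tg_mgdl", "hdl": "hdl_mgdl",
}

COMPONENT_VARS = ["wc", "sbp", "dbp", "fg", "tg", "hdl"]


def default_mets_spec() -> PathModelSpec:
    """The two-level skeleton: age -> BMI -> components -> MetS status."""
    edges = [("age", "bmi")]
    for c in COMPONENT_VARS:
        edges += [("age", c), ("bmi", c)]
    edges += [(c, "mets") for c in COMPONENT_VARS]
    return PathModelSpec(
        variables=("age", "bmi") + tuple(COMPONENT_VARS) + ("mets",),
        edges=tuple(edges),
        exogenous=("age",),
    )


@dataclass
class SemResult:
    subgroup: str
    model: PathModel
    report: FitReport
    effects: pd.DataFrame


def run_mets_sem(
    cohort: pd.DataFrame,
    spec: PathModelSpec | None = None,
    subgroups=("women", "men", "total"),
    outcome: str = "count",
    min_n: int = 30,
) -> dict[str, SemResult]:
    """Fit the MetS path model per subgroup (women / men / total).

    The cohort is classified first; ``mets`` is operationalized as the JIS
    component count (0-5) treated as continuous, since every analyzed
    subject is diagnosed and a binary outcome would be degenerate.  Passing
    ``outcome=<column>`` substitutes another status column (e.g. a generated
    latent score).  Subgroups below ``min_n`` are skipped with a warning.
    """
    spec = spec or default_mets_spec()
    classified = add_mets_columns(cohort)
    data = pd.DataFrame({short: classified[col] for short, col in MODEL_COLUMNS.items()})
    if outcome == "count":
        data["mets"] = classified["mets_count"].astype(float)
    else:
        data["mets"] = classified[outcome].astype(float)
    masks = {
        "women": classified["sex"] == "F",
        "men": classified["sex"] == "M",
        "total": pd.Series(True, index=classified.index),
    }
    results = {}
    for name in subgroups:
        sub = data[masks[name]]
        if len(sub) < min_n:
            warnings.warn(f"subgroup {name!r} has n={len(sub)} < {min_n}; skipped")
            continue
        model = PathModel(spec=spec).fit(sub)
        results[name] = SemResult(
            subgroup=name,
            model=model,
            report=model.fit_report(),
            effects=model.effects_table(),
        )
    return results
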