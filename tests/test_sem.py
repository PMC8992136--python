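import numpy as np
import pandas as pd
import pytest

from metspath import (
    GeneratorConfig,
    PathModel,
    PathModelSpec,
    default_structural_coefs,
    fit_path_model,
    generate_cohort,
    run_mets_sem,
    simulate_structural,
    srmr,
    standardize,
)
from metspath.errors import (
    CollinearityError,
    DegenerateDataError,
    SpecificationError,
)
from metspath.sem import fit_category

import oracles
from conftest import SEED


def make_fitted(spec, betas, exo_corr=None, observed=None, disturbances=None):
    """Assemble a PathModel with prescribed parameters (no data fit)."""
    model = PathModel(spec=spec)
    model.spec_ = spec
    model.n_ = 1000
    model.beta_ = dict(betas)
    model.se_ = {e: 0.01 for e in betas}
    model.t_ = {e: b / 0.01 for e, b in betas.items()}
    model.p_ = {e: 0.0 for e in betas}
    model.r2_ = {}
    model.disturbance_ = {}
    for v in spec.endogenous:
        parents = spec.parents(v)
        if disturbances and v in disturbances:
            d = disturbances[v]
        else:
            d = 1.0 - sum(betas.get((p, v), 0.0) ** 2 for p in parents)
        model.disturbance_[v] = d
        model.r2_[v] = 1.0 - d
    exo = list(spec.exogenous)
    if exo_corr is None:
        exo_corr = pd.DataFrame(np.eye(len(exo)), index=exo, columns=exo)
    model.exo_corr_ = exo_corr
    if observed is None:
        observed = pd.DataFrame(
            np.eye(len(spec.variables)), index=spec.variables, columns=spec.variables
        )
    model.observed_corr_ = observed
    return model


# -- specification validation ------------------------------------------------

def test_cyclic_spec_rejected():
    with pytest.raises(SpecificationError, match="acyclic"):
        PathModelSpec(("x", "y"), (("x", "y"), ("y", "x")), ("x",))


def test_exogenous_with_incoming_edge_rejected():
    with pytest.raises(SpecificationError, match="incoming"):
        PathModelSpec(("x", "y"), (("x", "y"),), ("x", "y"))


def test_undeclared_edge_endpoint_rejected():
    with pytest.raises(SpecificationError, match="undeclared"):
        PathModelSpec(("x",), (("x", "y"),), ("x",))


# -- standardization ----------------------------------------------------------

def test_standardize_simple_column():
    out = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
    assert list(out["x"]) == pytest.approx([-1.0, 0.0, 1.0])


def test_standardize_idempotent(rng):
    df = pd.DataFrame({"x": rng.normal(2, 5, 100)})
    once = standardize(df)
    twice = standardize(once)
    assert np.allclose(once["x"], twice["x"], atol=1e-12)


def test_standardize_constant_column_errors():
    with pytest.raises(DegenerateDataError, match="x"):
        standardize(pd.DataFrame({"x": np.ones(10)}))


# -- estimation ---------------------------------------------------------------

def test_single_predictor_beta_equals_pearson_r(rng):
    x = rng.normal(size=400)
    y = 0.6 * x + rng.normal(size=400)
    data = pd.DataFrame({"x": x, "y": y})
    spec = PathModelSpec(("x", "y"), (("x", "y"),), ("x",))
    model = fit_path_model(spec, data)
    r = np.corrcoef(x, y)[0, 1]
    assert model.beta_[("x", "y")] == pytest.approx(r, abs=1e-12)
    assert model.r2_["y"] == pytest.approx(r**2, abs=1e-12)
    assert model.disturbance_["y"] == pytest.approx(1 - r**2, abs=1e-12)


def test_chain_coefficients_recovered(rng):
    draws = simulate_structural({("x", "m"): 0.5, ("m", "y"): 0.4}, n=10_000, rng=rng)
    spec = PathModelSpec(("x", "m", "y"), (("x", "m"), ("m", "y")), ("x",))
    model = fit_path_model(spec, draws)
    assert model.beta_[("x", "m")] == pytest.approx(0.5, abs=0.03)
    assert model.beta_[("m", "y")] == pytest.approx(0.4, abs=0.03)


def test_inference_matches_independent_ols(rng):
    x1 = rng.normal(size=200)
    x2 = 0.3 * x1 + rng.normal(size=200)
    y = 0.5 * x1 - 0.2 * x2 + rng.normal(size=200)
    data = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
    spec = PathModelSpec(
        ("x1", "x2", "y"), (("x1", "x2"), ("x1", "y"), ("x2", "y")), ("x1",)
    )
    model = fit_path_model(spec, data)
    import statsmodels.api as sm

    Z = standardize(data)
    fit = sm.OLS(Z["y"], Z[["x1", "x2"]]).fit()
    # statsmodels uses df = n - k; the path model's t-test uses n - k - 1
    n, k = 200, 2
    resid = fit.resid
    sigma2 = float(resid @ resid) / (n - k - 1)
    xtx_inv = np.linalg.inv(Z[["x1", "x2"]].T @ Z[["x1", "x2"]])
    for j, parent in enumerate(["x1", "x2"]):
        assert model.beta_[(parent, "y")] == pytest.approx(fit.params[parent], abs=1e-10)
        se = np.sqrt(sigma2 * xtx_inv[j, j])
        assert model.se_[(parent, "y")] == pytest.approx(se, abs=1e-12)
    from scipy import stats as sps

    for edge, t in model.t_.items():
        assert model.p_[edge] == pytest.approx(
            2 * sps.t.sf(abs(t), n - len(model.spec_.parents(edge[1])) - 1)
        )


def test_collinear_parents_rejected(rng):
    x = rng.normal(size=100)
    data = pd.DataFrame({"x": x, "x2": 2 * x, "y": rng.normal(size=100)})
    spec = PathModelSpec(
        ("x", "x2", "y"), (("x", "y"), ("x2", "y"), ("x", "x2")), ("x",)
    )
    with pytest.raises(CollinearityError):
        fit_path_model(spec, data)


def test_scale_invariance(rng):
    draws = simulate_structural({("x", "m"): 0.5, ("m", "y"): 0.4}, n=500, rng=rng)
    spec = PathModelSpec(("x", "m", "y"), (("x", "m"), ("m", "y")), ("x",))
    a = fit_path_model(spec, draws)
    scaled = draws.copy()
    scaled["m"] = scaled["m"] * 1000.0  # e.g. unit change
    b = fit_path_model(spec, scaled)
    assert a.beta_ == pytest.approx(b.beta_)
    assert a.r2_ == pytest.approx(b.r2_)
    assert a.fit_report().srmr == pytest.approx(b.fit_report().srmr, abs=1e-12)


# -- implied correlations and decomposition -----------------------------------

def test_implied_single_edge():
    spec = PathModelSpec(("x", "y"), (("x", "y"),), ("x",))
    model = make_fitted(spec, {("x", "y"): 0.6})
    assert model.implied_correlations().loc["x", "y"] == pytest.approx(0.6)


def test_implied_fork_is_product_of_paths():
    spec = PathModelSpec(("z", "x", "y"), (("z", "x"), ("z", "y")), ("z",))
    model = make_fitted(spec, {("z", "x"): 0.5, ("z", "y"): 0.4})
    assert model.implied_correlations().loc["x", "y"] == pytest.approx(0.20)


def test_chain_decomposition_closed_form():
    spec = PathModelSpec(
        ("x", "m", "y"), (("x", "m"), ("m", "y"), ("x", "y")), ("x",)
    )
    model = make_fitted(
        spec, {("x", "m"): 0.5, ("m", "y"): 0.4, ("x", "y"): 0.3}
    )
    d = model.decompose_effects("x", "y")
    assert d.direct == pytest.approx(0.3)
    assert d.indirect == pytest.approx(0.20)
    assert d.total == pytest.approx(0.50)


def test_no_path_and_independent_exogenous_gives_zero_total():
    spec = PathModelSpec(("x", "y", "z"), (("x", "z"),), ("x", "y"))
    model = make_fitted(spec, {("x", "z"): 0.4})
    assert model.decompose_effects("y", "z").total == pytest.approx(0.0)


def random_recursive_model(rng, n_obs=300, max_nodes=6):
    while True:
        p = int(rng.integers(3, max_nodes + 1))
        names = [f"v{i}" for i in range(p)]
        edges = {}
        for i in range(p):
            for j in range(i + 1, p):
                if rng.random() < 0.4:
                    edges[(names[i], names[j])] = float(rng.uniform(-0.35, 0.35))
        if not edges:
            continue
        targets = {t for _, t in edges}
        exo = tuple(v for v in names if v not in targets)
        spec = PathModelSpec(tuple(names), tuple(edges), exo)
        draws = simulate_structural(edges, n=n_obs, rng=rng, variables=names)
        return PathModel(spec=spec).fit(draws)


def test_implied_and_indirect_match_trace_enumeration(rng):
    for _ in range(25):
        model = random_recursive_model(rng)
        implied = model.implied_correlations()
        psi = oracles.psi_from_fitted(model)
        names = list(model.spec_.variables)
        for i, vi in enumerate(names):
            for vj in names[i + 1:]:
                expected = oracles.implied_correlation(
                    model.beta_, psi, names, vi, vj
                )
                assert implied.loc[vi, vj] == pytest.approx(expected, abs=1e-10)
                d = model.decompose_effects(vi, vj)
                assert d.indirect == pytest.approx(
                    oracles.indirect_effect(model.beta_, vi, vj), abs=1e-10
                )
                assert d.total == pytest.approx(d.direct + d.indirect, abs=1e-12)


def test_saturated_model_reproduces_observed(rng):
    names = tuple(f"v{i}" for i in range(5))
    edges = tuple(
        (names[i], names[j]) for i in range(5) for j in range(i + 1, 5)
    )
    spec = PathModelSpec(names, edges, (names[0],))
    data = pd.DataFrame(rng.normal(size=(200, 5)), columns=names)
    model = fit_path_model(spec, data)
    report = model.fit_report()
    assert report.srmr < 1e-10
    assert report.category == "perfect"


# -- SRMR ---------------------------------------------------------------------

def test_srmr_identical_matrices_zero():
    m = pd.DataFrame(np.eye(4))
    report = srmr(m, m)
    assert report.srmr == 0.0
    assert report.category == "perfect"


def test_srmr_hand_computed_value():
    obs = np.eye(3)
    obs[1, 0] = obs[0, 1] = 0.1
    obs[2, 0] = obs[0, 2] = -0.1
    obs[2, 1] = obs[1, 2] = 0.2
    report = srmr(pd.DataFrame(obs), pd.DataFrame(np.eye(3)))
    assert report.srmr == pytest.approx(np.sqrt(0.06 / 3), abs=1e-12)
    assert report.category == "poor"


@pytest.mark.parametrize(
    "value, category",
    [(0.0, "perfect"), (0.0334, "very_good"), (0.07, "adequate"), (0.15, "poor")],
)
def test_fit_categories(value, category):
    assert fit_category(value) == category


def test_srmr_dimension_mismatch_rejected():
    with pytest.raises(ValueError):
        srmr(pd.DataFrame(np.eye(3)), pd.DataFrame(np.eye(4)))


# -- cohort-level front door --------------------------------------------------

def test_run_mets_sem_deterministic(small_cohort):
    a = run_mets_sem(small_cohort)
    b = run_mets_sem(small_cohort)
    for name in a:
        assert a[name].model.to_dict() == b[name].model.to_dict()
        assert a[name].report.srmr == b[name].report.srmr


def test_run_mets_sem_skips_tiny_subgroup(small_cohort):
    women_only = small_cohort[small_cohort.sex == "F"]
    with pytest.warns(UserWarning, match="men"):
        res = run_mets_sem(women_only, subgroups=("women", "men"))
    assert set(res) == {"women"}


def test_null_component_edges_recovered_as_zero():
    coefs = {e: b for e, b in default_structural_coefs().items() if e[1] != "mets"}
    coefs.update({(c, "mets"): 0.0 for c in ("wc", "sbp", "dbp", "fg", "tg", "hdl")})
    cfg = GeneratorConfig(n_women=4000, n_men=0, seed=SEED, structural_coefs=coefs)
    cohort = generate_cohort(cfg, keep_score=True)
    res = run_mets_sem(cohort, subgroups=("women",), outcome="mets_score")
    model = res["women"].model
    for edge, beta in model.beta_.items():
        if edge[1] == "mets":
            assert abs(beta) < 3 * model.se_[edge]


def test_dominant_component_ordering_recovered():
    cfg = GeneratorConfig(n_women=4000, n_men=0, seed=SEED)
    cohort = generate_cohort(cfg, keep_score=True)
    res = run_mets_sem(cohort, subgroups=("women",), outcome="mets_score")
    betas = {e[0]: b for e, b in res["women"].model.beta_.items() if e[1] == "mets"}
    assert max(betas, key=lambda k: abs(betas[k])) == "wc"


def test_dot_and_dict_exports(small_cohort):
    res = run_mets_sem(small_cohort, subgroups=("total",))
    model = res["total"].model
    dot = model.to_dot()
    assert dot.startswith("digraph") and '"wc" -> "mets"' in dot
    payload = model.to_dict()
    assert payload["n"] == len(small_cohort)
    assert 0 <= payload["srmr"]
    assert len(payload["edges"]) == len(model.beta_)
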