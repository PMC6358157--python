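"""Random-intercept logistic regression: design construction, the AGHQ
likelihood against a dense-integration oracle, degenerate limits,
odds-ratio tables and the model sequence."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from socisol import geolink, glmm, pipeline
from socisol.glmm import (
    Design,
    ModelSpec,
    aor_table,
    build_design,
    fit_random_intercept_logit,
    marginal_loglik,
    run_model_sequence,
    sequence_table,
)
from socisol.synthetic import simulate_clustered_binary


def toy_design(n_clusters, cluster_size, beta, sigma_u, seed):
    y, X, cidx, u = simulate_clustered_binary(n_clusters, cluster_size,
                                              beta, sigma_u, seed)
    return Design(y=y, X=X, columns=["intercept", "x"], cluster_index=cidx,
                  cluster_ids=np.arange(n_clusters), n_used=len(y), n_dropped=0)


def dense_marginal_loglik(params, design, n_grid=20001, width=8.0):
    """Brute-force marginal log-likelihood by trapezoid integration."""
    beta, sigma = params[:-1], float(np.exp(params[-1]))
    grid = np.linspace(-width * sigma, width * sigma, n_grid)
    eta0 = design.X @ beta
    total = 0.0
    for j in range(design.n_clusters):
        m = design.cluster_index == j
        eta = eta0[m][:, None] + grid[None, :]
        ll = (design.y[m][:, None] * eta - np.logaddexp(0, eta)).sum(axis=0)
        dens = np.exp(ll) * np.exp(-grid**2 / (2 * sigma**2)) \
            / np.sqrt(2 * np.pi * sigma**2)
        total += np.log(np.trapezoid(dens, grid))
    return total


# ------------------------------------------------------------ likelihood --
@pytest.mark.parametrize("sigma_u,beta", [
    (0.7, (-0.5, 0.8)),
    (0.2, (0.3, -0.4)),
    (1.5, (-1.0, 0.5)),
])
def test_aghq_matches_dense_integration_on_toy_designs(sigma_u, beta):
    d = toy_design(5, 4, beta, sigma_u, seed=11)
    params = np.array([beta[0], beta[1], np.log(sigma_u)])
    ll_q = marginal_loglik(params, d, 15)
    ll_dense = dense_marginal_loglik(params, d)
    assert ll_q == pytest.approx(ll_dense, abs=1e-6)


def test_quadrature_refinement_stable_15_vs_51_nodes():
    d = toy_design(40, 25, (-1.5, 0.6), 0.8, seed=5)
    fit = fit_random_intercept_logit(d, n_nodes=15)
    params = np.append(fit.beta, np.log(max(fit.sigma_u, 1e-6)))
    ll15 = marginal_loglik(params, d, 15)
    ll51 = marginal_loglik(params, d, 51)
    assert abs(ll15 - ll51) / abs(ll51) < 1e-4


def test_loglik_invariant_to_cluster_relabeling_and_row_order():
    d = toy_design(12, 8, (-0.8, 0.5), 0.6, seed=9)
    params = np.array([-0.7, 0.4, np.log(0.5)])
    base = marginal_loglik(params, d, 15)
    rng = np.random.default_rng(1)
    perm_rows = rng.permutation(len(d.y))
    relabel = rng.permutation(12)
    d2 = Design(y=d.y[perm_rows], X=d.X[perm_rows],
                columns=d.columns, cluster_index=relabel[d.cluster_index][perm_rows],
                cluster_ids=np.arange(12), n_used=d.n_used, n_dropped=0)
    assert marginal_loglik(params, d2, 15) == pytest.approx(base, abs=1e-10)


def test_no_cluster_effect_recovers_ordinary_logistic():
    """With data generated at sigma_u = 0 the mixed fit degenerates to
    ordinary logistic regression."""
    d = toy_design(300, 60, (-1.0, 0.8), 0.0, seed=3)
    fit = fit_random_intercept_logit(d)
    ref = sm.Logit(d.y, d.X).fit(disp=0)
    assert np.max(np.abs(fit.beta - ref.params)) < 1e-4
    assert fit.sigma_u < 0.05


def test_single_replicate_parameter_recovery_within_wald_band():
    d = toy_design(300, 60, (-2.0, 0.7), 0.5, seed=17)
    fit = fit_random_intercept_logit(d)
    assert fit.converged
    for b_true, b_hat, se in zip((-2.0, 0.7), fit.beta, fit.se_beta):
        assert abs(b_hat - b_true) < 3.5 * se
    assert 0.3 < fit.sigma_u < 0.7


def test_loglik_ascends_across_optimizer_iterates():
    d = toy_design(50, 30, (-1.2, 0.6), 0.6, seed=21)
    fit = fit_random_intercept_logit(d)
    path = np.asarray(fit.loglik_path)
    assert len(path) > 1
    assert np.all(np.diff(path) > -1e-6)  # monotone up to line-search tol


def test_needs_two_clusters():
    d = toy_design(1, 30, (-1.0, 0.5), 0.5, seed=2)
    with pytest.raises(ValueError, match="2 clusters"):
        fit_random_intercept_logit(d)


# ---------------------------------------------------------------- design --
@pytest.fixture(scope="module")
def analytic_records(small_sim):
    _, participants, census, _ = small_sim
    scored = pipeline.score_participants(participants, sensitivity_cutoff=2)
    linked, rep = geolink.link_fsa(scored, census)
    records, rep = geolink.filter_small_fsas(linked, 10, report=rep)
    return records


def test_treatment_coding_uses_stated_references(analytic_records):
    design = build_design(analytic_records, ModelSpec(outcome="lonely", model="m1"))
    assert "age_group[75_85]" not in design.columns      # reference
    assert "age_group[45_54]" in design.columns
    assert "sex[man]" in design.columns                   # ref women
    assert "income_band[missing]" in design.columns       # missing is a level
    assert "urban_rural[rural]" not in design.columns     # reference
    assert design.columns[0] == "intercept"


def test_isolation_models_exclude_definitional_terms(analytic_records):
    design = build_design(analytic_records, ModelSpec(outcome="isolated", model="m2"))
    joined = " ".join(design.columns)
    assert "marital_status" not in joined
    assert "living_alone" not in joined
    assert "pct_living_alone" not in design.columns
    fsa_cols = [c for c in design.columns if c.startswith("pct_")]
    assert len(fsa_cols) == 4


def test_loneliness_model2_includes_all_five_fsa_measures(analytic_records):
    design = build_design(analytic_records, ModelSpec(outcome="lonely", model="m2"))
    fsa_cols = [c for c in design.columns if c.startswith("pct_")]
    assert len(fsa_cols) == 5
    assert "pct_living_alone" in fsa_cols
    assert "marital_status[widowed]" in design.columns
    assert "living_alone[True]" in design.columns


def test_sex_term_only_in_total_stratum(analytic_records):
    d_total = build_design(analytic_records, ModelSpec(outcome="lonely", stratum="total"))
    d_women = build_design(analytic_records, ModelSpec(outcome="lonely", stratum="women"))
    assert "sex[man]" in d_total.columns
    assert all(not c.startswith("sex") for c in d_women.columns)
    assert d_women.n_used < d_total.n_used


def test_missing_reference_level_is_hard_error(analytic_records):
    rural_free = analytic_records[analytic_records["urban_rural"] != "rural"]
    with pytest.raises(ValueError, match="rural"):
        build_design(rural_free, ModelSpec(outcome="lonely"))


def test_rows_missing_model_terms_dropped_with_count(analytic_records):
    records = analytic_records.copy()
    records.iloc[:7, records.columns.get_loc("lonely")] = pd.NA
    design = build_design(records, ModelSpec(outcome="lonely"))
    assert design.n_dropped == 7
    assert design.n_used == len(records) - 7


# ------------------------------------------------------------- aor table --
def test_aor_closed_form_and_significance():
    fit = glmm.FitResult(
        spec=ModelSpec(), columns=["intercept", "b"],
        beta=np.array([0.0, 0.693]), se_beta=np.array([0.1, 0.1]),
        sigma_u=0.3, se_log_sigma_u=0.1, loglik=-10.0, n_used=100,
        n_clusters=10, converged=True, iterations=5, n_nodes=15)
    tab = aor_table(fit).set_index("term")
    z = stats.norm.ppf(0.995)
    assert tab.at["b", "aor"] == pytest.approx(np.exp(0.693))
    assert tab.at["b", "ci_low"] == pytest.approx(np.exp(0.693 - z * 0.1))
    assert tab.at["b", "ci_high"] == pytest.approx(np.exp(0.693 + z * 0.1))
    assert tab.at["b", "significant"]          # |z| = 6.93, p << .01
    assert tab.at["intercept", "aor"] == pytest.approx(1.0)
    assert tab.at["intercept", "ci_low"] < 1.0 < tab.at["intercept", "ci_high"]
    assert not tab.at["intercept", "significant"]


def test_zero_coefficient_is_never_significant():
    fit = glmm.FitResult(
        spec=ModelSpec(), columns=["intercept", "b"],
        beta=np.array([-2.0, 0.0]), se_beta=np.array([0.1, 0.2]),
        sigma_u=0.0, se_log_sigma_u=np.nan, loglik=-10.0, n_used=100,
        n_clusters=10, converged=True, iterations=5, n_nodes=15)
    tab = aor_table(fit).set_index("term")
    assert tab.at["b", "aor"] == 1.0
    assert tab.at["b", "ci_low"] < 1.0 < tab.at["b", "ci_high"]
    assert not tab.at["b", "significant"]


# --------------------------------------------------------- model sequence --
def test_model_sequence_shapes(analytic_records):
    fits = run_model_sequence(analytic_records, "isolated", n_nodes=5,
                              strata=("total", "women"))
    assert set(fits) == {("m1", "total"), ("m1", "women"),
                        ("m2", "total"), ("m2", "women")}
    assert all(not any(c.startswith("sex") for c in f.columns)
               for (m, s), f in fits.items() if s == "women")
    tab = sequence_table(fits)
    assert "m1_total_aor" in tab.columns and "m2_women_ci_high" in tab.columns
    # model-1 rows have no FSA-measure AORs
    m2_terms = set(tab["term"])
    assert "pct_65plus_low_income" in m2_terms
    row = tab.set_index("term").loc["pct_65plus_low_income"]
    assert np.isnan(row["m1_total_aor"])
    assert np.isfinite(row["m2_total_aor"])
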