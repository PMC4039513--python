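"""Joint bivariate random-slope model: likelihood oracle, GLS profiling,
fitting, observed information."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal, norm

import jointatrophy as ja
from jointatrophy.joint import _pattern_cov, _prep, build_design

from conftest import (scenario_config, scenario_params, simulate_and_fit,
                      true_beta_series)


# ---------------------------------------------------------------------------
# helpers

def _random_tables(rng, n_subjects, max_visits=4, drop_outcomes=False):
    subs = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n_subjects)],
        "group": "G",
        "sex": rng.choice(["M", "F"], n_subjects),
        "e4": rng.integers(0, 2, n_subjects),
        "age": rng.normal(75, 6, n_subjects),
        "mmse": rng.normal(26, 2, n_subjects),
        "tiv": rng.normal(1540, 150, n_subjects),
        "brain_vol": rng.normal(1000, 90, n_subjects),
        "hippo_vol": rng.normal(4.2, 0.7, n_subjects),
    })
    rows = []
    for i in range(n_subjects):
        k = rng.integers(1, max_visits + 1)
        ts = np.sort(rng.choice([0.5, 1.0, 1.5, 2.0, 3.0], size=k,
                                replace=False))
        for t in ts:
            yh = rng.normal(0.1 * t, 0.2)
            yb = rng.normal(7 * t, 3.0)
            if drop_outcomes and rng.random() < 0.2:
                if rng.random() < 0.5:
                    yh = np.nan
                else:
                    yb = np.nan
            rows.append((f"s{i}", int(t * 12), t, yh, yb))
    visits = pd.DataFrame(rows, columns=["subject_id", "month",
                                         "interval_years", "hippo_loss",
                                         "brain_loss"])
    return subs, visits


def _dense_loglik(design, beta_h, beta_b, vc):
    """Oracle: stack each subject's observations and evaluate one
    multivariate normal density."""
    beta = np.concatenate([np.asarray(b) for b in (beta_h, beta_b)
                           if b is not None])
    total = 0.0
    for pat in design.patterns:
        V = _pattern_cov(pat, vc.G, vc.R)
        for j in range(pat.y.shape[0]):
            total += multivariate_normal.logpdf(pat.y[j], pat.X[j] @ beta, V)
    return total


# ---------------------------------------------------------------------------
# marginal likelihood

@given(st.integers(0, 10_000))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_loglik_matches_dense_oracle(seed):
    """On random small instances the grouped evaluation equals a dense
    stacked multivariate-normal density to 1e-8."""
    rng = np.random.default_rng(seed)
    subs, visits = _random_tables(rng, int(rng.integers(1, 7)),
                                  drop_outcomes=True)
    design = build_design(subs, visits)
    vc = ja.VarianceComponents(
        sigma_h=rng.uniform(0.01, 0.1), sigma_b=rng.uniform(0.5, 4.0),
        rho=rng.uniform(-0.9, 0.9), tau_h=rng.uniform(0.02, 0.2),
        tau_b=rng.uniform(0.5, 3.0), kappa=rng.uniform(-0.5, 0.5))
    beta_h = rng.normal(0, 0.1, 7)
    beta_b = rng.normal(0, 1, 7)
    if design.outcomes == ("h",):
        args = (beta_h, None)
    elif design.outcomes == ("b",):
        args = (None, beta_b)
    else:
        args = (beta_h, beta_b)
    ll = ja.marginal_loglik(design, *args, vc)
    assert ll == pytest.approx(_dense_loglik(design, *args, vc),
                               rel=1e-8, abs=1e-8)


def test_loglik_single_visit_independence_factorization():
    """One subject, one visit, rho = kappa = 0: the joint density is the
    product of two univariate normals with variances t^2 s^2 + tau^2."""
    rng = np.random.default_rng(0)
    subs, visits = _random_tables(rng, 1, max_visits=1)
    design = build_design(subs, visits)
    vc = ja.VarianceComponents(0.05, 3.0, 0.0, 0.08, 2.0)
    beta_h = np.zeros(7)
    beta_b = np.zeros(7)
    ll = ja.marginal_loglik(design, beta_h, beta_b, vc)
    t = visits["interval_years"].iloc[0]
    expect = (norm.logpdf(visits["hippo_loss"].iloc[0], 0,
                          np.sqrt(t**2 * 0.05**2 + 0.08**2))
              + norm.logpdf(visits["brain_loss"].iloc[0], 0,
                            np.sqrt(t**2 * 3.0**2 + 2.0**2)))
    assert ll == pytest.approx(expect, abs=1e-10)


def test_loglik_no_random_effects_is_least_squares():
    """sigma = 0 reduces to the independent-errors Gaussian likelihood."""
    rng = np.random.default_rng(1)
    subs, visits = _random_tables(rng, 8)
    design = build_design(subs, visits)
    vc = ja.VarianceComponents(0.0, 0.0, 0.0, 0.1, 2.5)
    beta_h = rng.normal(0, 0.05, 7)
    beta_b = rng.normal(0, 0.5, 7)
    ll = ja.marginal_loglik(design, beta_h, beta_b, vc)
    beta = np.concatenate([beta_h, beta_b])
    expect = 0.0
    for pat in design.patterns:
        sd = np.where(pat.outcome == 0, 0.1, 2.5)
        resid = pat.y - pat.X @ beta
        expect += norm.logpdf(resid, 0, sd[None, :]).sum()
    assert ll == pytest.approx(expect, abs=1e-8)


def test_all_variances_zero_raises_not_minus_inf():
    rng = np.random.default_rng(2)
    subs, visits = _random_tables(rng, 3)
    design = build_design(subs, visits)
    vc = ja.VarianceComponents(0.0, 0.0, 0.0, 0.0, 0.0)
    with pytest.raises(ValueError, match="singular"):
        ja.marginal_loglik(design, np.zeros(7), np.zeros(7), vc)


# ---------------------------------------------------------------------------
# GLS profiling

def test_profile_equals_origin_ols_under_iid_errors():
    """Zero random slopes and equal residual SDs: GLS coincides with OLS
    through the origin on the interval-scaled design."""
    rng = np.random.default_rng(3)
    subs, visits = _random_tables(rng, 40)
    design = build_design(subs, visits)
    vc = ja.VarianceComponents(0.0, 0.0, 0.0, 1.3, 1.3)
    beta, _, _ = ja.profile_fixed_effects(design, vc)
    X = np.concatenate([p.X.reshape(-1, design.k) for p in design.patterns])
    y = np.concatenate([p.y.reshape(-1) for p in design.patterns])
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    np.testing.assert_allclose(beta, ols, atol=1e-8)


def test_profile_beta_is_stationary_point():
    """The numerical gradient of the marginal log-likelihood w.r.t. beta
    vanishes at the GLS solution."""
    rng = np.random.default_rng(4)
    subs, visits = _random_tables(rng, 25)
    design = build_design(subs, visits)
    vc = ja.VarianceComponents(0.04, 2.0, 0.5, 0.1, 2.0)
    beta, _, ll = ja.profile_fixed_effects(design, vc)
    h = 1e-6
    grad = np.empty(design.k)
    for j in range(design.k):
        e = np.zeros(design.k); e[j] = h
        lp = ja.marginal_loglik(design, (beta + e)[:7], (beta + e)[7:], vc)
        lm = ja.marginal_loglik(design, (beta - e)[:7], (beta - e)[7:], vc)
        grad[j] = (lp - lm) / (2 * h)
    assert np.linalg.norm(grad) < 1e-4


def test_profile_noise_free_exact_recovery():
    params = scenario_params(sigma_h=0.0, sigma_b=0.0, rho=0.0,
                             tau_h=0.0, tau_b=0.0)
    subjects, visits = ja.generate_cohort(scenario_config(40, seed=5), params)
    kept, kv, _ = ja.apply_eligibility(subjects, visits)
    design = build_design(kept, kv)
    vc = ja.VarianceComponents(0.0, 0.0, 0.0, 0.01, 0.01)
    beta, _, _ = ja.profile_fixed_effects(design, vc)
    # noise-free responses: any weighting recovers the generating betas
    truth = true_beta_series(params).to_numpy()
    np.testing.assert_allclose(beta, truth, atol=1e-8)


# ---------------------------------------------------------------------------
# full fit

def test_fit_improves_on_start_and_converges():
    res = simulate_and_fit(150, gen_seed=6, seed=0)
    assert res.converged
    assert res.llf >= res.convergence["llf_start"] - 1e-6
    assert res.convergence["grad_norm"] < 1e-2


def test_free_rho_fit_at_least_as_good_as_constrained():
    """Likelihood-ratio sanity: constraining rho = 0 can never beat the
    free fit."""
    params = scenario_params()
    subjects, visits = ja.generate_cohort(scenario_config(150, 7), params)
    kept, kv, _ = ja.apply_eligibility(subjects, visits)
    free = ja.fit_joint_model(kept, kv, seed=0)
    constrained = ja.fit_joint_model(kept, kv, fix_rho=0.0, seed=0)
    assert free.llf >= constrained.llf - 1e-6


def test_outcome_relabelling_symmetry():
    """Swapping the two outcome columns swaps the per-outcome parameter
    blocks and leaves rho and the log-likelihood unchanged."""
    params = scenario_params()
    subjects, visits = ja.generate_cohort(scenario_config(120, 8), params)
    kept, kv, _ = ja.apply_eligibility(subjects, visits)
    res = ja.fit_joint_model(kept, kv, seed=0)
    swapped = kv.rename(columns={"hippo_loss": "brain_loss",
                                 "brain_loss": "hippo_loss"})
    res_sw = ja.fit_joint_model(kept, swapped, seed=0)
    assert res_sw.llf == pytest.approx(res.llf, abs=1e-4)
    assert res_sw.vc.rho == pytest.approx(res.vc.rho, abs=1e-4)
    assert res_sw.vc.sigma_h == pytest.approx(res.vc.sigma_b, rel=1e-3)
    assert res_sw.vc.tau_b == pytest.approx(res.vc.tau_h, rel=1e-3)
    np.testing.assert_allclose(res_sw.beta[[f"h:{t}" for t in
                                            ja.config.FIXED_EFFECT_TERMS]],
                               res.beta[[f"b:{t}" for t in
                                         ja.config.FIXED_EFFECT_TERMS]],
                               rtol=1e-3, atol=1e-5)


def test_univariate_block_matches_mixedlm_oracle():
    """Deleting the brain outcome reduces the fit to a univariate random-
    slope model; it must match an independent statsmodels MixedLM ML fit."""
    params = scenario_params()
    subjects, visits = ja.generate_cohort(scenario_config(150, 9), params)
    kept, kv, _ = ja.apply_eligibility(subjects, visits)
    kv_h = kv.copy()
    kv_h["brain_loss"] = np.nan
    res = ja.fit_joint_model(kept, kv_h, seed=0)
    assert res.design.outcomes == ("h",)

    merged = kv.merge(kept[["subject_id", "sex", "e4", "age", "mmse", "tiv",
                            "brain_vol"]], on="subject_id")
    t = merged["interval_years"].to_numpy()
    male = (merged["sex"] == "M").astype(float).to_numpy()
    btiv = (merged["brain_vol"] / merged["tiv"]).to_numpy()
    c = res.design.centering
    X = np.column_stack([
        t * male, t * (1 - male), t * merged["e4"],
        t * (merged["age"] - c["age"]), t * (merged["mmse"] - c["mmse"]),
        t * (btiv - c["btiv"]), t * (merged["tiv"] - c["tiv"])])
    mlm = sm.regression.mixed_linear_model.MixedLM(
        merged["hippo_loss"].to_numpy(), X, groups=merged["subject_id"],
        exog_re=t[:, None]).fit(reml=False)
    np.testing.assert_allclose(res.beta.to_numpy(), mlm.fe_params, atol=1e-5)
    assert res.vc.sigma_h == pytest.approx(
        float(np.sqrt(np.asarray(mlm.cov_re)[0, 0])), rel=1e-3)
    assert res.vc.tau_h == pytest.approx(float(np.sqrt(mlm.scale)), rel=1e-3)
    assert res.llf == pytest.approx(mlm.llf, abs=1e-4)


def test_small_sigma_data_fits_with_boundary_note():
    """Data generated without hippocampal slope variability still fit; the
    estimated SD collapses toward zero."""
    params = scenario_params(sigma_h=0.001, rho=0.0)
    subjects, visits = ja.generate_cohort(scenario_config(150, 10), params)
    kept, kv, _ = ja.apply_eligibility(subjects, visits)
    res = ja.fit_joint_model(kept, kv, seed=0)
    assert res.vc.sigma_h < 0.02


def test_mar_mcar_deletion_robustness():
    """MCAR visit deletion on a large cohort moves estimates by less than
    3 reported SEs (the likelihood is valid under MAR)."""
    params = scenario_params()
    subjects, visits = ja.generate_cohort(
        scenario_config(2000, 11, retention=(1.0,) * 5), params)
    kept, kv, _ = ja.apply_eligibility(subjects, visits)
    full = ja.fit_joint_model(kept, kv, seed=0)
    thinned = ja.apply_retention(kv, (0.8,) * 5, seed=12)
    kept2, kv2, _ = ja.apply_eligibility(kept, thinned)
    sub = ja.fit_joint_model(kept2, kv2, seed=0)
    se = sub.bse()
    for name in ("h:e4", "b:e4", "sigma_h", "sigma_b", "rho", "tau_h",
                 "tau_b"):
        assert abs(full.params[name] - sub.params[name]) < 3 * se[name], name


# ---------------------------------------------------------------------------
# observed information

def test_duplicating_subjects_halves_parameter_variances():
    """Doubling the data doubles the information: variances from the
    duplicated fit are half the originals."""
    params = scenario_params()
    subjects, visits = ja.generate_cohort(scenario_config(200, 13), params)
    kept, kv, _ = ja.apply_eligibility(subjects, visits)
    res = ja.fit_joint_model(kept, kv, seed=0)
    k2 = kept.copy()
    k2["subject_id"] = k2["subject_id"] + "_dup"
    v2 = kv.copy()
    v2["subject_id"] = v2["subject_id"] + "_dup"
    res2 = ja.fit_joint_model(pd.concat([kept, k2], ignore_index=True),
                              pd.concat([kv, v2], ignore_index=True), seed=0)
    v_single = np.diag(res.cov_params().to_numpy())
    v_double = np.diag(res2.cov_params().to_numpy())
    ratio = v_double / v_single
    assert np.all(ratio > 0.45) and np.all(ratio < 0.55)


def test_reported_se_matches_replicate_scatter(recovery_replicates):
    """Across 100 replicate fits the mean reported SE of the carrier
    effects agrees with the empirical SD of the estimates within 15%."""
    est, se, _ = recovery_replicates
    for name in ("h:e4", "b:e4"):
        emp = est[name].std()
        rep = se[name].mean()
        assert abs(rep - emp) / emp < 0.15, (name, emp, rep)


def test_independent_outcomes_have_vanishing_cross_covariance():
    """Data generated with rho = 0: the cross-outcome covariance entries
    of the carrier effects are negligible relative to their variances."""
    params = scenario_params(rho=0.0)
    subjects, visits = ja.generate_cohort(scenario_config(400, 14), params)
    kept, kv, _ = ja.apply_eligibility(subjects, visits)
    res = ja.fit_joint_model(kept, kv, seed=0)
    C = res.cov_params()
    cross = abs(C.loc["h:e4", "b:e4"])
    scale = np.sqrt(C.loc["h:e4", "h:e4"] * C.loc["b:e4", "b:e4"])
    assert cross < 0.2 * scale


def test_reml_option_runs_and_shrinks_less():
    """REML variance components are no smaller than ML ones on the same
    data (REML removes the fixed-effect degrees of freedom)."""
    params = scenario_params()
    subjects, visits = ja.generate_cohort(scenario_config(80, 15), params)
    kept, kv, _ = ja.apply_eligibility(subjects, visits)
    ml = ja.fit_joint_model(kept, kv, seed=0)
    reml = ja.fit_joint_model(kept, kv, reml=True, seed=0)
    assert reml.vc.sigma_b >= ml.vc.sigma_b * 0.99
    assert reml.converged


def test_kappa_option_estimated_near_truth():
    """With the residual cross-correlation enabled, a cohort generated
    with kappa = 0.5 recovers it roughly."""
    params = scenario_params(kappa=0.5)
    subjects, visits = ja.generate_cohort(scenario_config(400, 16), params)
    kept, kv, _ = ja.apply_eligibility(subjects, visits)
    res = ja.fit_joint_model(kept, kv, kappa=True, seed=0)
    assert "kappa" in res.params.index
    assert res.params["kappa"] == pytest.approx(0.5, abs=0.15)


def test_both_carrier_states_required():
    subjects, visits = ja.generate_cohort(
        scenario_config(30, 17, genotype=(1.0, 0.0, 0.0, 0.0)),
        scenario_params())
    kept, kv, _ = ja.apply_eligibility(subjects, visits)
    with pytest.raises(ValueError, match="carrier"):
        ja.JointAtrophyModel(kept, kv)
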