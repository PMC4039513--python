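"""Shared fixtures: scenario configurations with known ground truth and a
session-scoped replicate simulation reused by several recovery checks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import jointatrophy as ja
from jointatrophy.config import CohortConfig, GroupConfig, TrueParameters

#: ground-truth variance components used throughout the recovery studies
TRUE_VC = dict(sigma_h=0.05, sigma_b=3.0, rho=0.7, tau_h=0.08, tau_b=2.0)


def scenario_params(e4_h: float = 0.04, e4_b: float = 1.5,
                    **vc_overrides) -> TrueParameters:
    """AD-like ground truth: carrier effects 0.04 / 1.5 ml per year."""
    vc = {**TRUE_VC, **vc_overrides}
    return TrueParameters(
        coef_h={"male": 0.16, "female": 0.186, "e4": e4_h,
                "age": 0.001, "mmse": -0.005, "btiv": -0.3, "tiv": 0.00002},
        coef_b={"male": 13.5, "female": 14.7, "e4": e4_b,
                "age": 0.05, "mmse": -0.3, "btiv": -30.0, "tiv": 0.002},
        **vc)


def scenario_config(n: int, seed: int,
                    genotype=(0.30, 0.47, 0.23, 0.0),
                    retention=(0.9,) * 5,
                    male_fraction=0.5) -> CohortConfig:
    """Single AD-like group with the given size and genotype mix."""
    g = GroupConfig(
        n=n, genotype_freqs=genotype, male_fraction=male_fraction,
        age_mean=75.0, age_sd=7.6, mmse_mean=23.4, mmse_sd=1.9,
        tiv_mean=1537.0, tiv_sd=167.0, hippo_mean=3.9, hippo_sd=0.9,
        hippo_e4_shift=-0.33, retention=tuple(retention))
    return CohortConfig(groups={"AD": g}, seed=seed)


def simulate_and_fit(n: int, gen_seed: int,
                     params: TrueParameters | None = None, **fit_kw):
    """Generate one scenario cohort, apply eligibility, fit the joint model."""
    params = params or scenario_params()
    subjects, visits = ja.generate_cohort(scenario_config(n, gen_seed), params)
    kept, kept_visits, _ = ja.apply_eligibility(subjects, visits)
    return ja.fit_joint_model(kept, kept_visits, **fit_kw)


def true_beta_series(params: TrueParameters) -> pd.Series:
    names = ([f"h:{t}" for t in ja.config.FIXED_EFFECT_TERMS]
             + [f"b:{t}" for t in ja.config.FIXED_EFFECT_TERMS])
    vals = np.concatenate([params.beta("h"), params.beta("b")])
    return pd.Series(vals, index=names)


@pytest.fixture(scope="session")
def recovery_replicates():
    """100 replicate cohorts (n = 400) fitted by maximum likelihood.

    Returns (estimates DataFrame, standard-error DataFrame, truth Series).
    """
    params = scenario_params()
    ests, ses = [], []
    for r in range(100):
        res = simulate_and_fit(400, gen_seed=1000 + r, params=params, seed=r)
        ests.append(res.params)
        ses.append(res.bse())
    est = pd.DataFrame(ests).reset_index(drop=True)
    se = pd.DataFrame(ses).reset_index(drop=True)
    truth = pd.concat([
        true_beta_series(params),
        pd.Series({"sigma_h": params.sigma_h, "sigma_b": params.sigma_b,
                   "rho": params.rho, "tau_h": params.tau_h,
                   "tau_b": params.tau_b})])
    return est, se, truth


@pytest.fixture()
def small_selected_cohort():
    """A selected (eligibility-applied) multi-group cohort, ~150 subjects."""
    cfg = ja.default_cohort_config(seed=11, size_scale=0.25)
    subjects, visits = ja.generate_cohort(cfg, ja.default_parameters())
    traj = ja.generate_trajectories(subjects, cfg.schedule_months, seed=12)
    kept, kept_visits, tally = ja.apply_eligibility(subjects, visits, traj)
    return kept, kept_visits, tally
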