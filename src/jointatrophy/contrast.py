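"""Carrier-vs-non-carrier rate contrasts, including the hippocampal
difference adjusted for concurrent whole-brain atrophy rate.

The adjustment uses the fitted random-slope covariance: with slope SDs
:math:`\\sigma_h, \\sigma_b` and correlation :math:`\\rho`, the
attributable coefficient

.. math:: \\lambda = \\rho \\, \\sigma_h / \\sigma_b

is the regression slope of the hippocampal random slope on the brain
random slope, and the adjusted carrier effect is

.. math:: \\Delta_{adj} = \\Delta_h - \\lambda \\, \\Delta_b,

the unadjusted hippocampal rate difference minus the share attributable
to the brain-rate difference.  Uncertainty comes from the delta method
on the full ML covariance, or from a parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .joint import ConvergenceError


@dataclass
class RateContrast:
    """Carrier-vs-non-carrier rate differences (ml/year) with 95% CIs."""

    delta_h: float
    delta_b: float
    lam: float
    delta_adj: float
    ci_h: tuple
    ci_b: tuple
    ci_adj: tuple
    p_h: float
    p_b: float
    p_adj: float
    method: str = "delta"

    def __post_init__(self):
        expect = self.delta_h - self.lam * self.delta_b
        scale = max(1.0, abs(self.delta_h), abs(self.lam * self.delta_b))
        if abs(self.delta_adj - expect) > 1e-12 * scale:
            raise ValueError(
                "adjusted difference violates the identity "
                f"delta_adj = delta_h - lambda*delta_b: {self.delta_adj} "
                f"vs {expect}")


def attributable_coefficient(vc) -> float:
    """lambda = rho * sigma_h / sigma_b (ml/ml, unitless)."""
    if vc.sigma_b <= 0:
        raise ValueError("sigma_b must be positive: the brain-rate "
                         "adjustment is undefined without brain slope "
                         "variability")
    return vc.rho * vc.sigma_h / vc.sigma_b


def adjustment_identity(delta_h: float, delta_b: float, lam: float) -> float:
    """Adjusted hippocampal difference: delta_h - lambda * delta_b."""
    return delta_h - lam * delta_b


def back_solve_lambda(unadjusted: float, adjusted: float,
                      brain_difference: float) -> float:
    """Recover the attributable coefficient from a reported triple of
    unadjusted, adjusted and brain rate differences."""
    if brain_difference == 0:
        raise ValueError("brain difference of zero: lambda is unidentified")
    return (unadjusted - adjusted) / brain_difference


def _wald(est: float, var: float):
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.975)
    p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else float(est == 0.0)
    return (est - z * se, est + z * se), p


def mean_adjusted_rate(fit, outcome: str, carrier: int):
    """Covariate-adjusted mean atrophy rate at the 50/50 gender split.

    ``outcome`` is ``"h"`` (hippocampus) or ``"b"`` (whole brain);
    ``carrier`` 0/1.  Requires a fit centred at the group covariate
    means (otherwise the adjusted mean is undefined).  Returns
    ``(rate_ml_per_year, (lo, hi))``.
    """
    if not fit.design.centered_at_means:
        raise ValueError("fit is not centred at group means; adjusted mean "
                         "rates are undefined")
    if outcome not in fit.design.outcomes:
        raise ValueError(f"outcome {outcome!r} not in the fit")
    names = [f"{outcome}:male", f"{outcome}:female", f"{outcome}:e4"]
    w = np.array([0.5, 0.5, float(carrier)])
    beta = fit.beta[names].to_numpy()
    est = float(w @ beta)
    cov = fit.cov_params().loc[names, names].to_numpy()
    ci, _ = _wald(est, float(w @ cov @ w))
    return est, ci


def brain_adjusted_difference(fit) -> RateContrast:
    """The full contrast set: unadjusted hippocampal and brain carrier
    differences, and the brain-adjusted hippocampal difference with a
    delta-method CI over (delta_h, delta_b, sigma_h, sigma_b, rho)."""
    if set(fit.design.outcomes) != {"h", "b"}:
        raise ValueError("both outcomes are required for the adjusted "
                         "contrast")
    cov_all = fit.cov_params()
    # a fit with the slope correlation fixed carries no "rho" entry: the
    # constant contributes no sampling variability
    rho_fixed = getattr(fit.model, "fix_rho", None) is not None
    need = ["h:e4", "b:e4", "sigma_h", "sigma_b"]
    if not rho_fixed:
        need.append("rho")
    missing = [n for n in need if n not in cov_all.index]
    if missing:
        raise ValueError(
            f"parameter covariance lacks {missing}; refit and recompute the "
            "full covariance (see observed_information)")
    d_h = float(fit.params["h:e4"])
    d_b = float(fit.params["b:e4"])
    s_h, s_b = float(fit.params["sigma_h"]), float(fit.params["sigma_b"])
    rho = float(fit.vc.rho)
    lam = attributable_coefficient(fit.vc)
    d_adj = adjustment_identity(d_h, d_b, lam)

    C = np.zeros((5, 5))
    sub = cov_all.loc[need, need].to_numpy()
    C[:len(need), :len(need)] = sub
    grad = np.array([
        1.0,
        -lam,
        -rho * d_b / s_b,
        rho * s_h * d_b / s_b**2,
        -s_h * d_b / s_b,
    ])
    var_adj = float(grad @ C @ grad)
    ci_h, p_h = _wald(d_h, C[0, 0])
    ci_b, p_b = _wald(d_b, C[1, 1])
    ci_adj, p_adj = _wald(d_adj, var_adj)
    return RateContrast(delta_h=d_h, delta_b=d_b, lam=lam, delta_adj=d_adj,
                        ci_h=ci_h, ci_b=ci_b, ci_adj=ci_adj,
                        p_h=p_h, p_b=p_b, p_adj=p_adj, method="delta")


def parametric_bootstrap_ci(fit, B: int, seed: int,
                            max_failure_rate: float = 0.05) -> RateContrast:
    """Percentile bootstrap for the contrasts: simulate from the fitted
    model at the observed design, refit, take the 2.5/97.5 percentiles.

    Point estimates are those of the original fit; a refit failure rate
    above ``max_failure_rate`` raises.
    """
    if B < 100:
        raise ValueError(f"B must be at least 100, got {B}")
    rng = np.random.default_rng(seed)
    point = brain_adjusted_difference(fit)
    draws = {"h": [], "b": [], "adj": []}
    failures = 0
    model = fit.model
    for _ in range(B):
        ys = fit.simulate(rng)
        design = fit.design.with_responses(ys)
        try:
            sub_model = _copy_with_design(model, design)
            refit = sub_model.fit(start=fit.vc, compute_cov=False)
            d_h = float(refit.params["h:e4"])
            d_b = float(refit.params["b:e4"])
            d_adj = adjustment_identity(
                d_h, d_b, attributable_coefficient(refit.vc))
        except (ValueError, ConvergenceError):
            failures += 1
            continue
        draws["h"].append(d_h)
        draws["b"].append(d_b)
        draws["adj"].append(d_adj)
    if failures > max_failure_rate * B:
        raise RuntimeError(
            f"{failures} of {B} bootstrap refits failed "
            f"(> {max_failure_rate:.0%} allowed)")

    def pct(v):
        return tuple(np.percentile(v, [2.5, 97.5]))

    def pboot(v):
        # symmetric two-sided percentile-of-zero p-value
        v = np.asarray(v)
        frac = min((v <= 0).mean(), (v >= 0).mean())
        return min(1.0, 2.0 * max(frac, 1.0 / len(v)))

    return RateContrast(
        delta_h=point.delta_h, delta_b=point.delta_b, lam=point.lam,
        delta_adj=point.delta_adj,
        ci_h=pct(draws["h"]), ci_b=pct(draws["b"]), ci_adj=pct(draws["adj"]),
        p_h=pboot(draws["h"]), p_b=pboot(draws["b"]),
        p_adj=pboot(draws["adj"]),
        method="bootstrap")


def _copy_with_design(model, design):
    import copy
    m = copy.copy(model)
    m.design = design
    return m
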