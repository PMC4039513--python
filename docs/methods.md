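# Methods

`jointatrophy` implements a longitudinal analysis of APOE ε4 effects on
hippocampal atrophy: a joint bivariate linear mixed model of hippocampal
and whole-brain volume loss with correlated random slopes, the
brain-rate-adjusted carrier contrast derived from the random-slope
covariance, a cross-sectional baseline volume regression, the cohort
selection rules, and a synthetic cohort generator that reproduces the
statistical structure the models assume.

## The longitudinal model

For subject *i* in one clinical group, with follow-up scans at intervals
*t<sub>ij</sub>* (years after baseline), the measured losses since
baseline (ml, boundary-shift-integral change measures) are

    y_hij = t_ij (x_i' β_h + b_hi) + ε_hij      (hippocampus)
    y_bij = t_ij (x_i' β_b + b_bi) + ε_bij      (whole brain)

* `x_i` — fixed-effect covariate row: male and female indicators
  (cell-means coding, no separate intercept column), ε4 carrier status
  (1 = one or two ε4 alleles), and age, MMSE, brain-to-TIV ratio and TIV
  centred at the group means.  Every term enters as an interaction with
  interval: the model has **no constant terms, fixed or random**,
  because true tissue change over a zero interval is zero while the two
  scans of a pair still carry independent measurement error.
* `(b_hi, b_bi) ~ N(0, G)` — subject-level random slopes, the only link
  between the two outcomes, with SDs σ<sub>h</sub>, σ<sub>b</sub>
  (ml/year) and correlation ρ.
* `ε` — scan-pair measurement noise, independent across visits, with
  SDs τ<sub>h</sub>, τ<sub>b</sub> (ml).  A same-visit cross-correlation
  κ between the two residuals is implemented but **off by default**:
  the default residual structure is diagonal, and the outcomes are
  coupled through ρ alone.

The Gaussian marginal likelihood is evaluated per subject with
covariance `Cov(y_Aj, y_Bk) = t_j t_k G_AB + 1{j=k} R_AB`; a subject
contributes whatever measurements exist, so the likelihood is valid
under missing-at-random follow-up and no completeness per subject is
required.

**Estimation.** Maximum likelihood.  The fixed effects are profiled out
by generalized least squares; the variance components are maximised by
quasi-Newton (L-BFGS-B) on an unconstrained scale — log SDs, atanh
correlations — from method-of-moments starts (per-outcome OLS, then a
regression of squared residuals on *t*² to split slope from residual
variance, and the correlation of per-subject mean residual rates for ρ).
Line-search failures are retried from perturbed points and, if
necessary, polished with Nelder–Mead; the maximised log-likelihood is
never allowed below its starting value.  Optimizer tolerances:
relative objective change 1e-12, projected gradient 1e-7; a fit is
flagged converged when the optimizer reports success or the central
finite-difference gradient is below 1e-4·max(1, |log L|).  Estimated
SDs below 1e-6 or |correlations| above 0.999 are recorded as boundary
estimates in the convergence record.  ML is the default because the
slope-only, no-intercept structure leaves little small-sample REML
correction at these group sizes (≥ ~40 per group); REML is available as
an option.  Subjects sharing a visit/missingness pattern share one
covariance factorisation, which makes a fit of 400 subjects take well
under a second.

**Observed information.** The parameter covariance is the inverse
observed information over all parameters.  Given the variance
components the log-likelihood is exactly quadratic in β, so the β-block
of the Hessian is −XᵀV⁻¹X; the variance-component block and the cross
block come from central finite differences (relative step 1e-4) of the
profile quantities.  The covariance is symmetrised, its spectrum
clipped at zero (an eigenvalue below −1e-8 relative raises an
indefinite-Hessian error advising a restart), and the
variance-component block is mapped to the natural scale (SDs,
correlations) by the delta method.

## The adjusted carrier contrast

Let Δ<sub>h</sub> and Δ<sub>b</sub> be the ε4+ vs ε4− rate differences
(the `e4` interaction coefficients).  The attributable coefficient

    λ = ρ σ_h / σ_b

is the population regression slope of the hippocampal random slope on
the brain random slope, and the hippocampal difference adjusted for
concurrent whole-brain atrophy rate is

    Δ_adj = Δ_h − λ Δ_b .

λ is a plug-in estimate whose sampling variability is propagated by the
delta method with gradient (1, −λ, −ρΔ_b/σ_b, ρσ_hΔ_b/σ_b²,
−σ_hΔ_b/σ_b) over (Δ_h, Δ_b, σ_h, σ_b, ρ), using the full ML
covariance.  When the fit fixes ρ, the constant contributes no
variance.  All intervals are normal-based Wald 95% CIs with two-sided
p-values and no multiple-testing correction (per-group results are
reported unadjusted).  A parametric bootstrap (simulate from the fitted
model at the observed design, refit, percentile interval; B ≥ 100) is
available as an alternative.

Adjusted mean rates are reported for a 50/50 gender split — half the
male coefficient plus half the female coefficient (+ the ε4 coefficient
for carriers) — which is well defined because covariates are centred at
group means; an uncentred fit refuses to produce adjusted means.

On the published longitudinal summary rows the identity can be checked
in-table: λ back-solved from the stable-MCI row, (0.036−0.013)/2.57 ≈
0.0089, applied to the AD row (0.043 − λ·1.58) and the progressive-MCI
row (0.045 − λ·1.62) reproduces the printed adjusted differences 0.029
and 0.031 at 3 decimals, and the λ implied by each of the three rows
falls in [0.0080, 0.0095].  The discussion-level reduction fractions
(~25% AD, ~40% MCI-P, ~75% MCI-S) differ from fractions recomputed from
the rounded table entries (~33%, ~31%, ~64%) — presumably computed from
unrounded estimates; the package reports the table arithmetic and does
not force agreement.

## The baseline model

Within each group, OLS of bilateral baseline hippocampal volume on
{male, female, ε4, age, MMSE, TIV, brain-to-TIV ratio} with cell-means
gender coding, so the 50/50-gender adjusted mean is literally
0.5·β_male + 0.5·β_female + carrier·β_ε4 + Σ covariate·β.  CIs are
normal-based (group sizes ≥ ~40 make the t correction negligible).
Rank-deficient designs (e.g. a single-carrier-state group) are rejected
with the offending columns named.  The published baseline table's
caption says "left and right summed" while its footnote says "average
of left and right"; this package standardises on the bilateral **sum**
throughout.

## Selection rules

* APOE coding: carrier = 1 iff ≥ 1 ε4 allele; any ε2 allele (2/2, 2/3,
  2/4) excludes the subject.
* MCI dichotomisation: MCI-P iff first AD diagnosis at month ≤ 36
  (inclusive — the 36-month visit counts) and AD maintained at all later
  observed visits; MCI-S iff MCI at every observed visit; reversion
  (AD→MCI, or AD→Normal) and MCI→Normal are excluded.  Classification
  uses observed visits only.  A first AD diagnosis *after* month 36 with
  clean MCI before it is not covered by the published rules; the default
  policy labels it stable, an alternative policy excludes it.
* Eligibility: baseline scan plus ≥ 1 follow-up.  Each excluded subject
  is tallied once, under the first applicable of {no follow-up, ε2
  carrier, MCI reverter, MCI-to-normal, late progression}, so kept +
  tallied = input (a checked partition).

## The synthetic cohort generator

The generator emulates, per clinical group: covariate distributions
(age, MMSE, TIV, baseline volumes) as independent normals with the
published group means/SDs; genotype mixes from the published carrier
frequencies, re-inflated with a 12% ε2-carrier fraction (approximate
elderly population prevalence) so the exclusion stage has realistic
work; a 6/12/18/24/36-month schedule with the published per-visit
retention (visit-wise independent, i.e. MCAR, which satisfies the
model's MAR assumption; a monotone-dropout mode exists for sensitivity
checks); true slopes drawn from the bivariate normal around a
covariate-driven linear predictor; and independent scan-pair noise.
Defaults: σ_h = 0.05, σ_b = 3.0, ρ = 0.7, τ_h = 0.08, τ_b = 2.0, κ = 0;
group mean rates and carrier effects set to the published ε4− rates and
differences (e.g. AD: 0.173/14.11 ml/yr, effects 0.043/1.58).

Choices and caveats:

* Continuous covariates in the linear predictor are centred at the
  *sample* means of the generated group — the same convention the
  analysis uses — so the male/female coefficients are exactly the
  covariate-adjusted group mean rates (the nonlinear brain-to-TIV ratio
  makes config-mean centring subtly different).
* Baseline whole-brain volume is not published; the default
  (1000 ± 100 ml, giving plausible brain-to-TIV ratios ≈ 0.65) is
  synthetic-only.
* Baseline hippocampal volume gets a per-group carrier shift (defaults
  −0.02/−0.06/−0.03/−0.33 ml for controls/MCI-S/MCI-P/AD), with the
  configured mean interpreted as the ε4− stratum mean.
* MMSE is clipped to [0, 30]; for a control-like group (mean 29.2,
  SD 0.9) this truncation visibly deflates the mean relative to the
  config — as the real ceiling does — so moment-match checks use groups
  away from the ceiling.
* Covariates are drawn independently (only marginal moments are
  published); diagnosis trajectories are generated consistent with the
  group label, with no conversion-hazard model.  The generator makes no
  attempt at image-level realism (segmentation, BSI computation): it
  reproduces the *statistical* structure, so passing tests demonstrate
  correctness of the estimation machinery under the model's own
  assumptions, not robustness to real-data violations (non-normal
  noise, informative dropout, covariate-dependent variance).

## Verification and problem sizes

The test suite checks, among others: the grouped likelihood against a
dense stacked multivariate-normal oracle (random instances ≤ 6
subjects × ≤ 4 visits, equality to 1e-8); GLS stationarity and the
least-squares and noise-free limits; exact recovery symmetry under
outcome relabelling; the univariate reduction against an independent
statsmodels MixedLM ML fit; the free-vs-ρ=0 likelihood ordering;
MCAR-deletion stability; exact variance halving under data duplication;
parameter recovery over 100 replicate cohorts of n = 400 (every
parameter within 3 Monte-Carlo SEs, variance-component bias < 10%); and
95% delta-method CI coverage for Δ_adj in [0.91, 0.98] over 300
simulations at n = 200.  The recovery and coverage studies use a single
AD-like group (carrier mix 0.30/0.47/0.23, no ε2; retention 0.9 at each
of the five visits; carrier effects 0.04 and 1.5 ml/yr) — sizes chosen
as the smallest that make the Monte-Carlo checks sharp.  The
`scripts/acceptance.py` entry point recomputes the published adjusted
differences from the printed summary rows through the package's
adjustment-identity functions.

## Known limitations

* Exactly two outcomes; no random intercepts (excluded by design); no
  non-Gaussian outcomes.
* The delta-method CI for Δ_adj is first-order; at small n or ρ near
  ±1 the bootstrap option is the safer choice.
* The observed information uses finite differences in the
  variance-component block; step size 1e-4 is adequate for the
  well-conditioned parameterisation but extremely flat likelihoods
  (e.g. σ → 0 boundaries) can make the Hessian indefinite, which is
  reported rather than silently repaired.
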