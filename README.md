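# jointatrophy

Joint modelling of longitudinal hippocampal and whole-brain atrophy with
APOE ε4 carrier contrasts — including the question the package exists to
answer: **is the higher hippocampal atrophy rate in ε4 carriers more
than what their faster whole-brain atrophy would already predict?**

It is written for biostatisticians and imaging researchers analysing
serial volumetric MRI in Alzheimer's disease, mild cognitive impairment
(MCI) and controls, where per-visit change measures (boundary-shift
integral, ml lost since baseline) are available per subject together
with baseline covariates and APOE genotype.

## The model

For subject *i* of one clinical group with scans at intervals
*t<sub>ij</sub>* years, losses for outcome *A* ∈ {hippocampus, brain}:

    y_Aij = t_ij (x_i' β_A + b_Ai) + ε_Aij ,   (b_hi, b_bi) ~ N(0, G)

with covariates (sex, ε4 carrier status, age, MMSE, brain-to-TIV ratio,
TIV) entering only as interactions with interval — no constant terms,
fixed or random — and the two outcomes linked through the correlation ρ
of the random slopes, G = [[σ_h², ρσ_hσ_b], [ρσ_hσ_b, σ_b²]].
Estimation is maximum likelihood (GLS-profiled fixed effects,
quasi-Newton over log-SD/atanh-correlation coordinates), valid under
missing-at-random follow-up.

The headline statistic is the carrier difference in hippocampal rate
adjusted for the concurrent brain rate,

    Δ_adj = Δ_h − λ Δ_b ,   λ = ρ σ_h / σ_b ,

with delta-method (or parametric-bootstrap) confidence intervals.
A per-group baseline OLS of hippocampal volume, the cohort selection
rules (ε4 coding, ε2 exclusion, MCI progressor/stable dichotomisation,
minimum-scan eligibility) and a calibrated synthetic cohort generator
complete the pipeline.  See `docs/methods.md` for the full account.

## Worked example

Everything runs off two long-format tables (`subjects`, `visits`); the
generator produces calibrated ADNI-like ones so no external data are
needed:

```python
import jointatrophy as ja

cfg = ja.default_cohort_config(seed=42)
subjects, visits = ja.generate_cohort(cfg, ja.default_parameters())
traj = ja.generate_trajectories(subjects, cfg.schedule_months, seed=43)
kept, kept_visits, tally = ja.apply_eligibility(subjects, visits, traj)
print(f"kept {len(kept)} of {len(subjects)} subjects; exclusions: {tally}")

res = ja.fit_joint_model(kept, kept_visits, group="AD", seed=0)
rate0, ci0 = res.adjusted_rate("h", carrier=0)
print(f"AD e4- hippocampal rate: {rate0:.3f} "
      f"[{ci0[0]:.3f}, {ci0[1]:.3f}] ml/yr")
rc = res.rate_contrast()
print(f"delta_h  = {rc.delta_h:.3f} [{rc.ci_h[0]:.3f}, {rc.ci_h[1]:.3f}]"
      f"  p = {rc.p_h:.3f}")
print(f"delta_b  = {rc.delta_b:.2f} [{rc.ci_b[0]:.2f}, {rc.ci_b[1]:.2f}]"
      f"  p = {rc.p_b:.3f}")
print(f"lambda   = {rc.lam:.4f}")
print(f"delta_adj= {rc.delta_adj:.3f} "
      f"[{rc.ci_adj[0]:.3f}, {rc.ci_adj[1]:.3f}]  p = {rc.p_adj:.3f}")
```

prints

```
kept 536 of 622 subjects; exclusions: {'no_follow_up': 0, 'e2_carrier': 86,
 'mci_revert': 0, 'mci_to_normal': 0, 'mci_late_progression': 0}
AD e4- hippocampal rate: 0.171 [0.151, 0.190] ml/yr
delta_h  = 0.029 [0.005, 0.053]  p = 0.018
delta_b  = 1.69 [0.55, 2.84]  p = 0.004
lambda   = 0.0100
delta_adj= 0.012 [-0.011, 0.035]  p = 0.308
```

Reading this: in the simulated AD group, ε4 carriers lose hippocampal
volume 0.029 ml/yr faster than non-carriers (p = 0.018) and whole-brain
volume 1.69 ml/yr faster.  Each extra ml/yr of brain loss predicts
λ ≈ 0.010 ml/yr of hippocampal loss through the random-slope
correlation, so 0.017 ml/yr of the carrier gap is attributable to the
global difference, leaving Δ_adj = 0.012 ml/yr.  These are estimates
from *one* synthetic cohort of ADNI-like size — single-cohort
uncertainty is substantial (here Δ_adj is not significant even though
the generating adjusted effect is positive), which is exactly what the
intervals convey.  `res.summary()` shows all fixed effects and variance
components; `res.bootstrap_contrast(B=200, seed=1)` replaces the
delta-method intervals with percentile-bootstrap ones.

The same pipeline is scriptable from the shell:

```bash
jointatrophy simulate --seed 42 --out data/
jointatrophy select --subjects data/subjects.csv --visits data/visits.csv \
    --trajectories data/trajectories.csv --out selected/
jointatrophy longitudinal --subjects selected/subjects.csv \
    --visits selected/visits.csv --group AD --seed 0
jointatrophy report --seed 42 --out out/     # demographics + baseline +
                                             # longitudinal tables, run log
```

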