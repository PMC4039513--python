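"""Synthetic ADNI-like cohort generator.

Emulates the statistical structure the longitudinal analysis assumes:
per-group covariate distributions and APOE genotype mixes, a fixed
follow-up schedule with per-visit retention, subject-level true atrophy
slopes drawn from a bivariate normal around a covariate-driven linear
predictor, and independent scan-pair measurement noise on the two
boundary-shift-integral (BSI) change measures.

Data layout (long format, all volumes in ml):

``subjects`` — one row per participant:
    subject_id, group, apoe1, apoe2, sex (M/F), age, mmse, tiv,
    brain_vol, hippo_vol, true_slope_h, true_slope_b
``visits`` — one row per retained follow-up scan pair:
    subject_id, month, interval_years, hippo_loss, brain_loss

The true slopes are generator-only ground truth; the analysis never
reads them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    GENOTYPE_CATEGORIES,
    CohortConfig,
    ConfigError,
    GroupConfig,
    TrueParameters,
)

SUBJECT_COLUMNS = [
    "subject_id", "group", "apoe1", "apoe2", "sex", "age", "mmse", "tiv",
    "brain_vol", "hippo_vol", "true_slope_h", "true_slope_b",
]
VISIT_COLUMNS = ["subject_id", "month", "interval_years", "hippo_loss", "brain_loss"]

def _psd_factor(C: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix; tolerates zero variances."""
    w, U = np.linalg.eigh(C)
    if w.min() < -1e-10 * max(w.max(), 1.0):
        raise ConfigError("slope/residual covariance is not positive "
                          "semi-definite")
    return U * np.sqrt(np.clip(w, 0.0, None))


# allele pairs drawn within the "contains e2" category
_E2_PAIRS = ((2, 2), (2, 3), (2, 4))
_E2_WEIGHTS = (0.05, 0.75, 0.20)


def _draw_covariates(g: GroupConfig, n: int, rng: np.random.Generator):
    """Draw baseline covariates; redraw rows violating hippo < brain < TIV."""
    age = rng.normal(g.age_mean, g.age_sd, n)
    mmse = np.clip(rng.normal(g.mmse_mean, g.mmse_sd, n), 0.0, 30.0)
    tiv = rng.normal(g.tiv_mean, g.tiv_sd, n)
    brain = rng.normal(g.brain_mean, g.brain_sd, n)
    hippo = rng.normal(g.hippo_mean, g.hippo_sd, n)
    for _ in range(100):
        bad = ~((hippo > 0) & (hippo < brain) & (brain < tiv))
        if not bad.any():
            break
        k = int(bad.sum())
        tiv[bad] = rng.normal(g.tiv_mean, g.tiv_sd, k)
        brain[bad] = rng.normal(g.brain_mean, g.brain_sd, k)
        hippo[bad] = rng.normal(g.hippo_mean, g.hippo_sd, k)
    else:  # pragma: no cover - only reachable with absurd configs
        raise ConfigError("could not satisfy hippo < brain < TIV ordering")
    return age, mmse, tiv, brain, hippo


def _draw_genotypes(g: GroupConfig, n: int, rng: np.random.Generator):
    cat = rng.choice(len(GENOTYPE_CATEGORIES), size=n, p=np.asarray(g.genotype_freqs))
    a1 = np.full(n, 3, dtype=int)
    a2 = np.full(n, 3, dtype=int)
    a2[cat == 1] = 4                      # heterozygote 3/4
    a1[cat == 2] = 4                      # homozygote 4/4
    a2[cat == 2] = 4
    idx_e2 = np.flatnonzero(cat == 3)
    if idx_e2.size:
        pick = rng.choice(len(_E2_PAIRS), size=idx_e2.size, p=np.asarray(_E2_WEIGHTS))
        for j, p in zip(idx_e2, pick):
            a1[j], a2[j] = _E2_PAIRS[p]
    return a1, a2


def _linear_predictors(params: TrueParameters, male, e4,
                       age, mmse, tiv, brain):
    """Per-subject mean rates (ml/year).  Continuous covariates are centred
    at the group sample means — the same convention the analysis uses —
    so the male/female coefficients are exactly the covariate-adjusted
    sex-specific mean rates of the generated group."""
    btiv = brain / tiv
    cols = {
        "male": male.astype(float),
        "female": 1.0 - male,
        "e4": e4.astype(float),
        "age": age - age.mean(),
        "mmse": mmse - mmse.mean(),
        "btiv": btiv - btiv.mean(),
        "tiv": tiv - tiv.mean(),
    }
    lp_h = sum(params.coef_h[t] * v for t, v in cols.items())
    lp_b = sum(params.coef_b[t] * v for t, v in cols.items())
    return np.asarray(lp_h, dtype=float), np.asarray(lp_b, dtype=float)


def apply_retention(visits: pd.DataFrame, retention, seed: int,
                    mode: str = "independent") -> pd.DataFrame:
    """Thin a full visit table by per-visit retention probabilities.

    ``retention`` is aligned with the sorted unique months in ``visits``.
    ``independent`` keeps each visit independently (MCAR); ``monotone``
    drops a subject permanently at the first failed visit.
    """
    ret = np.asarray(retention, dtype=float)
    if np.any(ret < 0) or np.any(ret > 1):
        raise ConfigError(f"retention outside [0, 1]: {list(ret)}")
    if visits.empty:
        return visits.reset_index(drop=True)
    months = np.sort(visits["month"].unique())
    if ret.shape != months.shape:
        raise ConfigError(
            f"retention has {ret.size} entries for {months.size} visit months"
        )
    if mode not in ("independent", "monotone"):
        raise ConfigError(f"unknown dropout mode {mode!r}")
    rng = np.random.default_rng(seed)
    prob = dict(zip(months, ret))
    # draw in a fixed (subject, month) order for reproducibility
    v = visits.sort_values(["subject_id", "month"], kind="mergesort")
    u = rng.random(len(v))
    p = v["month"].map(prob).to_numpy()
    keep = u < p
    if mode == "monotone":
        keep = pd.Series(keep, index=v.index).groupby(
            v["subject_id"], sort=False).cummin().to_numpy().astype(bool)
    return v.loc[keep].reset_index(drop=True)


def generate_group(name: str, g: GroupConfig, params: TrueParameters,
                   schedule_months, rng: np.random.Generator,
                   id_offset: int = 0, dropout: str = "independent"):
    """Generate one group's subject and (pre-retention) visit tables."""
    n = g.n
    if n == 0:
        return (pd.DataFrame(columns=SUBJECT_COLUMNS),
                pd.DataFrame(columns=VISIT_COLUMNS))
    age, mmse, tiv, brain, hippo = _draw_covariates(g, n, rng)
    a1, a2 = _draw_genotypes(g, n, rng)
    male = (rng.random(n) < g.male_fraction).astype(int)
    e4 = (((a1 == 4) | (a2 == 4)) & (a1 != 2) & (a2 != 2)).astype(int)
    hippo = hippo + g.hippo_e4_shift * e4

    lp_h, lp_b = _linear_predictors(params, male, e4, age, mmse, tiv, brain)
    G = params.slope_cov
    b = rng.standard_normal((n, 2)) @ _psd_factor(G).T
    slope_h = lp_h + b[:, 0]
    slope_b = lp_b + b[:, 1]

    subjects = pd.DataFrame({
        "subject_id": [f"{name}-{id_offset + i:05d}" for i in range(n)],
        "group": name,
        "apoe1": a1, "apoe2": a2,
        "sex": np.where(male == 1, "M", "F"),
        "age": age, "mmse": mmse, "tiv": tiv,
        "brain_vol": brain, "hippo_vol": hippo,
        "true_slope_h": slope_h, "true_slope_b": slope_b,
    })

    months = np.asarray(schedule_months, dtype=int)
    t = months / 12.0
    m = months.size
    # scan-pair measurement noise, correlated across outcomes iff kappa != 0
    off = params.kappa * params.tau_h * params.tau_b
    R = np.array([[params.tau_h**2, off], [off, params.tau_b**2]])
    eps = rng.standard_normal((n, m, 2)) @ _psd_factor(R).T
    y_h = slope_h[:, None] * t[None, :] + eps[:, :, 0]
    y_b = slope_b[:, None] * t[None, :] + eps[:, :, 1]

    visits = pd.DataFrame({
        "subject_id": np.repeat(subjects["subject_id"].to_numpy(), m),
        "month": np.tile(months, n),
        "interval_years": np.tile(t, n),
        "hippo_loss": y_h.ravel(),
        "brain_loss": y_b.ravel(),
    })
    retention_seed = int(rng.integers(2**31 - 1))
    visits = apply_retention(visits, g.retention, retention_seed, mode=dropout)
    return subjects, visits


def generate_cohort(config: CohortConfig,
                    params: dict[str, TrueParameters] | TrueParameters):
    """Generate the full multi-group cohort.

    Returns ``(subjects, visits)`` DataFrames.  Identical
    ``(config, params)`` (the seed lives in the config) give identical
    output.
    """
    config.validate()
    if isinstance(params, TrueParameters):
        params = {name: params for name in config.groups}
    for name in config.groups:
        if name not in params:
            raise ConfigError(f"no TrueParameters for group {name!r}")
        params[name].validate()

    rng = np.random.default_rng(config.seed)
    subj_frames, visit_frames = [], []
    offset = 0
    for name, g in config.groups.items():
        s, v = generate_group(name, g, params[name], config.schedule_months,
                              rng, id_offset=offset, dropout=config.dropout)
        offset += g.n
        subj_frames.append(s)
        visit_frames.append(v)
    subj_nonempty = [f for f in subj_frames if not f.empty]
    visit_nonempty = [f for f in visit_frames if not f.empty]
    subjects = (pd.concat(subj_nonempty, ignore_index=True) if subj_nonempty
                else pd.DataFrame(columns=SUBJECT_COLUMNS))
    visits = (pd.concat(visit_nonempty, ignore_index=True) if visit_nonempty
              else pd.DataFrame(columns=VISIT_COLUMNS))
    return subjects, visits


def generate_trajectories(subjects: pd.DataFrame, schedule_months,
                          seed: int) -> pd.DataFrame:
    """Diagnosis trajectories consistent with each subject's group label.

    Controls stay Normal, AD stays AD, MCI-S stays MCI; MCI-P converts to
    AD at a schedule visit no later than 36 months and keeps the
    diagnosis.  No conversion hazard is modelled beyond the label.
    """
    rng = np.random.default_rng(seed)
    months = [0] + [int(m) for m in schedule_months]
    conv_choices = [m for m in months[1:] if m <= 36] or [months[1]]
    rows = []
    for sid, group in zip(subjects["subject_id"], subjects["group"]):
        base = {"Control": "Normal", "AD": "AD"}.get(group, "MCI")
        conv = rng.choice(conv_choices) if group == "MCI-P" else None
        for m in months:
            dx = base
            if conv is not None and m >= conv:
                dx = "AD"
            rows.append((sid, m, dx))
    return pd.DataFrame(rows, columns=["subject_id", "month", "diagnosis"])
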