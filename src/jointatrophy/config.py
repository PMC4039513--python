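"""Configuration containers for the synthetic cohort and the analysis pipeline.

The cohort configuration describes one clinical group per entry: how many
subjects, the APOE genotype mix, the marginal distributions of the baseline
covariates, and the follow-up schedule with per-visit retention.  The
ground-truth parameters hold the generative counterparts of everything the
longitudinal model estimates: fixed-effect rate coefficients per outcome,
the bivariate random-slope covariance, and the scan-pair residual SDs.

Default calibration mirrors the published ADNI summary statistics for the
four clinical groups (controls, stable MCI, progressive MCI, AD).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

#: genotype categories the generator draws from (probabilities sum to 1).
GENOTYPE_CATEGORIES = ("e4_non", "e4_het", "e4_hom", "e2")

#: fixed-effect terms per outcome, in design-column order.  All enter the
#: longitudinal model as interactions with scan interval.
FIXED_EFFECT_TERMS = ("male", "female", "e4", "age", "mmse", "btiv", "tiv")

#: default visit schedule in months after baseline.
DEFAULT_SCHEDULE = (6, 12, 18, 24, 36)

GROUP_ORDER = ("Control", "MCI-S", "MCI-P", "AD")


class ConfigError(ValueError):
    """Raised when a configuration field violates its invariants."""


@dataclass
class GroupConfig:
    """Generating distribution for one clinical group.

    Covariate units: age in years, MMSE in points, volumes in ml.
    ``hippo_mean`` is the mean bilateral hippocampal volume of the
    epsilon4 non-carrier stratum; carriers are shifted by
    ``hippo_e4_shift`` (negative = smaller volumes in carriers).
    """

    n: int
    genotype_freqs: tuple[float, float, float, float]
    male_fraction: float
    age_mean: float
    age_sd: float
    mmse_mean: float
    mmse_sd: float
    tiv_mean: float
    tiv_sd: float
    brain_mean: float = 1000.0  # not published; synthetic-only default
    brain_sd: float = 100.0
    hippo_mean: float = 4.5
    hippo_sd: float = 0.8
    hippo_e4_shift: float = 0.0
    retention: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)

    def validate(self, schedule: tuple[int, ...]) -> None:
        if self.n < 0:
            raise ConfigError(f"n must be >= 0, got {self.n}")
        freqs = np.asarray(self.genotype_freqs, dtype=float)
        if freqs.shape != (len(GENOTYPE_CATEGORIES),):
            raise ConfigError(
                f"genotype_freqs must have {len(GENOTYPE_CATEGORIES)} entries"
            )
        if np.any(freqs < 0) or np.any(freqs > 1):
            raise ConfigError(f"genotype_freqs outside [0, 1]: {self.genotype_freqs}")
        if abs(freqs.sum() - 1.0) > 1e-8:
            raise ConfigError(
                f"genotype_freqs must sum to 1, got {freqs.sum():.6f}"
            )
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigError(f"male_fraction outside [0, 1]: {self.male_fraction}")
        ret = np.asarray(self.retention, dtype=float)
        if ret.shape != (len(schedule),):
            raise ConfigError(
                f"retention has {ret.size} entries but the schedule has "
                f"{len(schedule)} visits"
            )
        if np.any(ret < 0) or np.any(ret > 1):
            raise ConfigError(f"retention outside [0, 1]: {self.retention}")
        for name in ("age_sd", "mmse_sd", "tiv_sd", "brain_sd", "hippo_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class CohortConfig:
    """Full multi-group cohort configuration.  ``seed`` is mandatory."""

    groups: dict[str, GroupConfig]
    seed: int
    schedule_months: tuple[int, ...] = DEFAULT_SCHEDULE
    dropout: str = "independent"  # "independent" (MCAR) or "monotone"

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        months = tuple(self.schedule_months)
        if any(m2 <= m1 for m1, m2 in zip(months, months[1:])):
            raise ConfigError("schedule_months must be strictly increasing")
        if self.dropout not in ("independent", "monotone"):
            raise ConfigError(f"unknown dropout mode {self.dropout!r}")
        for name, g in self.groups.items():
            try:
                g.validate(months)
            except ConfigError as err:
                raise ConfigError(f"group {name!r}: {err}") from None


@dataclass
class TrueParameters:
    """Ground-truth rate model for one group (or shared across groups).

    ``coef_h``/``coef_b`` map fixed-effect terms to ml/year-per-unit
    coefficients for the hippocampal and whole-brain outcome; continuous
    covariates are centred at the group config means inside the generator,
    so ``male``/``female`` are the covariate-adjusted sex-specific mean
    rates and ``e4`` is the carrier-vs-non-carrier rate difference.
    """

    coef_h: dict[str, float]
    coef_b: dict[str, float]
    sigma_h: float = 0.05
    sigma_b: float = 3.0
    rho: float = 0.7
    tau_h: float = 0.08
    tau_b: float = 2.0
    kappa: float = 0.0

    def validate(self) -> None:
        for name in ("sigma_h", "sigma_b", "tau_h", "tau_b"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not abs(self.rho) < 1:
            raise ConfigError(
                f"rho must lie in (-1, 1), got {self.rho}: slope covariance "
                "would not be positive definite"
            )
        if not abs(self.kappa) < 1:
            raise ConfigError(f"kappa must lie in (-1, 1), got {self.kappa}")
        for label, coefs in (("coef_h", self.coef_h), ("coef_b", self.coef_b)):
            missing = set(FIXED_EFFECT_TERMS) - set(coefs)
            if missing:
                raise ConfigError(f"{label} missing terms: {sorted(missing)}")

    @property
    def slope_cov(self) -> np.ndarray:
        """2x2 covariance of the (hippocampal, brain) random slopes."""
        off = self.rho * self.sigma_h * self.sigma_b
        return np.array(
            [[self.sigma_h**2, off], [off, self.sigma_b**2]], dtype=float
        )

    def beta(self, outcome: str) -> np.ndarray:
        coefs = self.coef_h if outcome == "h" else self.coef_b
        return np.array([coefs[t] for t in FIXED_EFFECT_TERMS], dtype=float)


def _scale_genotypes(non: float, het: float, hom: float,
                     e2: float = 0.12) -> tuple[float, float, float, float]:
    """Published frequencies are conditional on inclusion (no e2 carriers);
    re-inflate with an e2-carrier fraction so the eligibility filter has
    realistic work to do."""
    s = 1.0 - e2
    return (non * s, het * s, hom * s, e2)


def default_cohort_config(seed: int = 0, size_scale: float = 1.0) -> CohortConfig:
    """ADNI-like default calibration for the four clinical groups.

    ``size_scale`` multiplies every group size (useful for quick runs).
    """

    def n(x: int) -> int:
        return max(int(round(x * size_scale)), 0)

    groups = {
        "Control": GroupConfig(
            n=n(167),
            genotype_freqs=_scale_genotypes(0.71, 0.26, 0.03),
            male_fraction=0.54,
            age_mean=76.0, age_sd=5.1,
            mmse_mean=29.2, mmse_sd=0.9,
            tiv_mean=1548.0, tiv_sd=143.0,
            hippo_mean=5.2, hippo_sd=0.7,
            hippo_e4_shift=-0.02,
            retention=(165 / 167, 153 / 167, 0.0, 137 / 167, 115 / 167),
        ),
        "MCI-S": GroupConfig(
            n=n(169),
            genotype_freqs=_scale_genotypes(0.51, 0.40, 0.09),
            male_fraction=0.66,
            age_mean=75.5, age_sd=7.2,
            mmse_mean=27.2, mmse_sd=1.8,
            tiv_mean=1558.0, tiv_sd=142.0,
            hippo_mean=4.6, hippo_sd=0.8,
            hippo_e4_shift=-0.06,
            retention=(157 / 169, 147 / 169, 125 / 169, 103 / 169, 66 / 169),
        ),
        "MCI-P": GroupConfig(
            n=n(138),
            genotype_freqs=_scale_genotypes(0.30, 0.51, 0.19),
            male_fraction=0.59,
            age_mean=74.2, age_sd=6.9,
            mmse_mean=26.6, mmse_sd=1.7,
            tiv_mean=1552.0, tiv_sd=156.0,
            hippo_mean=4.2, hippo_sd=0.8,
            hippo_e4_shift=-0.03,
            retention=(133 / 138, 131 / 138, 116 / 138, 102 / 138, 69 / 138),
        ),
        "AD": GroupConfig(
            n=n(148),
            genotype_freqs=_scale_genotypes(0.30, 0.47, 0.23),
            male_fraction=0.55,
            age_mean=75.0, age_sd=7.6,
            mmse_mean=23.4, mmse_sd=1.9,
            tiv_mean=1537.0, tiv_sd=167.0,
            hippo_mean=3.9, hippo_sd=0.9,
            hippo_e4_shift=-0.33,
            retention=(143 / 148, 124 / 148, 1 / 148, 93 / 148, 1 / 148),
        ),
    }
    return CohortConfig(groups=groups, seed=seed)


# Shared covariate-interaction coefficients (per year of interval):
# small, plausible effects; continuous covariates are centred so these do
# not move the group-mean rates.
_COMMON_H = {"age": 0.001, "mmse": -0.005, "btiv": -0.3, "tiv": 0.00002}
_COMMON_B = {"age": 0.05, "mmse": -0.3, "btiv": -30.0, "tiv": 0.002}


def _group_params(rate_h: float, rate_b: float,
                  e4_h: float, e4_b: float) -> TrueParameters:
    coef_h = {"male": rate_h, "female": rate_h, "e4": e4_h, **_COMMON_H}
    coef_b = {"male": rate_b, "female": rate_b, "e4": e4_b, **_COMMON_B}
    return TrueParameters(coef_h=coef_h, coef_b=coef_b)


def default_parameters() -> dict[str, TrueParameters]:
    """Per-group ground truth calibrated to the published epsilon4- mean
    rates and carrier effects (ml/year)."""
    return {
        "Control": _group_params(0.069, 6.54, 0.001, 0.05),
        "MCI-S": _group_params(0.102, 7.91, 0.036, 2.57),
        "MCI-P": _group_params(0.151, 12.24, 0.045, 1.62),
        "AD": _group_params(0.173, 14.11, 0.043, 1.58),
    }


@dataclass
class AnalysisConfig:
    """End-to-end pipeline configuration.

    Either ``cohort`` (simulate) or ``subjects_path``/``visits_path``
    (read tables) must be provided.
    """

    seed: int
    output_dir: str = "out"
    cohort: CohortConfig | None = None
    subjects_path: str | None = None
    visits_path: str | None = None
    trajectories_path: str | None = None
    centering: str = "auto"
    kappa: bool = False
    reml: bool = False
    bootstrap: int = 0
    late_policy: str = "stable"
    verbosity: str = "summary"

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.cohort is None and (self.subjects_path is None
                                    or self.visits_path is None):
            raise ConfigError("provide either a cohort block or input paths")
        if self.cohort is not None:
            self.cohort.validate()
        if self.verbosity not in ("summary", "debug"):
            raise ConfigError(f"unknown verbosity {self.verbosity!r}")


def _group_from_mapping(m: dict) -> GroupConfig:
    m = dict(m)
    if "genotype_freqs" in m:
        m["genotype_freqs"] = tuple(float(x) for x in m["genotype_freqs"])
    if "retention" in m:
        m["retention"] = tuple(float(x) for x in m["retention"])
    return GroupConfig(**m)


def cohort_config_from_mapping(m: dict) -> CohortConfig:
    m = dict(m)
    groups = {name: _group_from_mapping(g) for name, g in m.pop("groups").items()}
    if "schedule_months" in m:
        m["schedule_months"] = tuple(int(x) for x in m["schedule_months"])
    cfg = CohortConfig(groups=groups, **m)
    cfg.validate()
    return cfg


def parameters_from_mapping(m: dict) -> dict[str, TrueParameters]:
    out = {}
    for name, p in m.items():
        params = TrueParameters(**p)
        params.validate()
        out[name] = params
    return out


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Read a YAML (key: value) analysis configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    cohort = raw.pop("cohort", None)
    if cohort is not None:
        if "seed" not in cohort:
            cohort["seed"] = raw.get("seed")
        cohort = cohort_config_from_mapping(cohort)
    cfg = AnalysisConfig(cohort=cohort, **raw)
    cfg.validate()
    return cfg
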