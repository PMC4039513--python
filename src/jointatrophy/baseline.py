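"""Cross-sectional baseline model: per-group regression of bilateral
hippocampal volume on APOE epsilon4 carrier status.

The design uses cell-means coding for sex (separate male and female
indicators, no constant), so the published convention of reporting
adjusted means for a 50/50 gender split — half the male coefficient plus
half the female coefficient — is literal.  Covariates: carrier status,
age, MMSE, TIV and brain-to-TIV ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: design columns, in order.
BASELINE_TERMS = ("male", "female", "e4", "age", "mmse", "tiv", "btiv")


def _design_matrix(subjects: pd.DataFrame) -> pd.DataFrame:
    male = (subjects["sex"] == "M").astype(float)
    X = pd.DataFrame({
        "male": male,
        "female": 1.0 - male,
        "e4": subjects["e4"].astype(float),
        "age": subjects["age"].astype(float),
        "mmse": subjects["mmse"].astype(float),
        "tiv": subjects["tiv"].astype(float),
        "btiv": (subjects["brain_vol"] / subjects["tiv"]).astype(float),
    })
    return X


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy()
    if np.linalg.matrix_rank(A) == A.shape[1]:
        return
    # name the offending columns via the QR diagonal
    _, r = np.linalg.qr(A)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps
    bad = [X.columns[j] for j in range(A.shape[1]) if diag[j] <= tol]
    # fall back: flag constant/zero columns explicitly
    degenerate = [c for c in X.columns if X[c].nunique() <= 1]
    names = sorted(set(bad) | set(degenerate)) or list(X.columns)
    raise ValueError(f"rank-deficient baseline design; collinear columns: {names}")


class BaselineVolumeModel:
    """OLS model of baseline bilateral hippocampal volume for one group.

    Parameters
    ----------
    subjects : DataFrame
        Eligible subjects (post selection rules) carrying an ``e4``
        column; if ``group`` is given, rows are filtered on
        ``analysis_group`` (falling back to ``group``).
    """

    def __init__(self, subjects: pd.DataFrame, group: str | None = None):
        if group is not None:
            col = ("analysis_group" if "analysis_group" in subjects.columns
                   else "group")
            subjects = subjects[subjects[col] == group]
        if "e4" not in subjects.columns:
            raise ValueError("subjects need an 'e4' column; run the "
                             "eligibility rules first")
        for sex in ("M", "F"):
            if (subjects["sex"] == sex).sum() < 1:
                raise ValueError(f"no subjects of sex {sex!r} in group {group!r}")
        if subjects[["age", "mmse", "tiv", "brain_vol", "hippo_vol"]].isna().any().any():
            raise ValueError("missing covariates in baseline design")
        self.group = group
        self.subjects = subjects.reset_index(drop=True)
        self.exog = _design_matrix(self.subjects)
        self.endog = self.subjects["hippo_vol"].astype(float)
        _check_rank(self.exog)

    @classmethod
    def from_tables(cls, subjects: pd.DataFrame, group: str | None = None):
        return cls(subjects, group=group)

    def fit(self) -> "BaselineVolumeResults":
        res = sm.OLS(self.endog.to_numpy(), self.exog.to_numpy()).fit()
        params = pd.Series(res.params, index=BASELINE_TERMS)
        cov = pd.DataFrame(res.cov_params(), index=BASELINE_TERMS,
                           columns=BASELINE_TERMS)
        resid_sd = float(np.sqrt(res.scale))
        ref = {
            "age": float(self.subjects["age"].mean()),
            "mmse": float(self.subjects["mmse"].mean()),
            "tiv": float(self.subjects["tiv"].mean()),
            "btiv": float((self.subjects["brain_vol"]
                           / self.subjects["tiv"]).mean()),
        }
        return BaselineVolumeResults(params, cov, resid_sd,
                                     nobs=len(self.subjects),
                                     group=self.group, reference=ref,
                                     model=self)


class BaselineVolumeResults:
    """Fitted baseline regression with Wald inference.

    Constructible directly from a coefficient vector and covariance,
    which makes closed-form checks straightforward.
    """

    def __init__(self, params: pd.Series, cov_params: pd.DataFrame,
                 resid_sd: float, nobs: int, group: str | None = None,
                 reference: dict | None = None, model=None):
        self.params = params.reindex(BASELINE_TERMS)
        self.cov = cov_params.reindex(index=BASELINE_TERMS,
                                      columns=BASELINE_TERMS)
        c = self.cov.to_numpy()
        if not np.allclose(c, c.T, atol=1e-8):
            raise ValueError("coefficient covariance must be symmetric")
        self.resid_sd = float(resid_sd)
        self.nobs = int(nobs)
        if self.nobs <= len(BASELINE_TERMS):
            raise ValueError("n must exceed the number of coefficients")
        self.group = group
        self.reference = reference or {}
        self.model = model

    def cov_params(self) -> pd.DataFrame:
        return self.cov

    def e4_difference(self):
        """Carrier-vs-non-carrier adjusted volume difference.

        Returns ``(difference_ml, (lo, hi), p)`` with a normal-based
        95% Wald interval and two-sided p-value.
        """
        est = float(self.params["e4"])
        se = float(np.sqrt(self.cov.loc["e4", "e4"]))
        z = stats.norm.ppf(0.975)
        p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else float(est == 0)
        return est, (est - z * se, est + z * se), p

    def adjusted_mean(self, carrier: int, reference: dict | None = None):
        """Adjusted mean volume at the 50/50 gender convention.

        ``reference`` maps covariate names (age, mmse, tiv, btiv) to the
        values at which to predict; defaults to the group means recorded
        at fit time.  Returns ``(volume_ml, (lo, hi))``.
        """
        ref = self.reference if reference is None else reference
        missing = [k for k in ("age", "mmse", "tiv", "btiv") if k not in ref]
        if missing:
            raise ValueError(f"missing reference covariate values: {missing}")
        c = np.array([0.5, 0.5, float(carrier), ref["age"], ref["mmse"],
                      ref["tiv"], ref["btiv"]])
        est = float(c @ self.params.to_numpy())
        var = float(c @ self.cov.to_numpy() @ c)
        z = stats.norm.ppf(0.975)
        half = z * np.sqrt(max(var, 0.0))
        return est, (est - half, est + half)

    def predict(self, row: pd.Series | dict) -> float:
        """Fitted value for a single subject-like record."""
        male = 1.0 if row["sex"] == "M" else 0.0
        c = np.array([male, 1.0 - male, float(row["e4"]), row["age"],
                      row["mmse"], row["tiv"],
                      row.get("btiv", row["brain_vol"] / row["tiv"])])
        return float(c @ self.params.to_numpy())

    def summary(self) -> str:
        se = np.sqrt(np.diag(self.cov.to_numpy()))
        tab = pd.DataFrame({"coef": self.params, "se": se})
        diff, ci, p = self.e4_difference()
        lines = [
            f"Baseline hippocampal volume model"
            f"{'' if self.group is None else f' — group {self.group}'}",
            f"n = {self.nobs}, residual SD = {self.resid_sd:.3f} ml",
            tab.to_string(float_format=lambda v: f"{v: .4f}"),
            f"e4+ vs e4- difference: {diff:.2f} ml "
            f"[{ci[0]:.2f}, {ci[1]:.2f}], p = {p:.3f}",
        ]
        return "\n".join(lines)
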