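"""Joint bivariate linear mixed model for hippocampal and whole-brain
volume loss with correlated random slopes.

Model.  For subject :math:`i` with follow-up scans at intervals
:math:`t_{ij}` (years), the measured losses (ml, by the boundary shift
integral) are

.. math::

    y^{A}_{ij} = t_{ij}\\,(x_i' \\beta_A + b_{Ai}) + \\varepsilon^{A}_{ij},
    \\qquad A \\in \\{h, b\\},

with fixed-effect covariate row :math:`x_i` (male, female, carrier
status, age, MMSE, brain-to-TIV ratio, TIV — every term an interaction
with interval), subject random slopes
:math:`(b_{hi}, b_{bi}) \\sim N(0, G)`,
:math:`G = \\begin{pmatrix} \\sigma_h^2 & \\rho\\sigma_h\\sigma_b \\\\
\\rho\\sigma_h\\sigma_b & \\sigma_b^2 \\end{pmatrix}`, and independent
scan-pair noise with SDs :math:`\\tau_h, \\tau_b` (optional same-visit
cross-correlation :math:`\\kappa`, off by default).  No constant terms,
fixed or random: true atrophy over a zero interval is zero.  The two
outcomes are linked only through the random-slope correlation
:math:`\\rho`.  The Gaussian likelihood is valid under missing-at-random
follow-up.

Fitting is maximum likelihood: the fixed effects are profiled out by
generalized least squares, and the variance components are maximised by
quasi-Newton on an unconstrained scale (log SDs, atanh correlations).
Subjects sharing a visit pattern share one covariance factorisation, so
the likelihood is cheap even for thousands of subjects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .config import FIXED_EFFECT_TERMS

__all__ = [
    "VarianceComponents", "ModelDesign", "build_design", "marginal_loglik",
    "profile_fixed_effects", "observed_information", "JointAtrophyModel",
    "JointAtrophyResults", "fit_joint_model", "ConvergenceError",
]

_LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """Optimizer failed; carries the best state seen so far."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class VarianceComponents:
    """Random-slope SDs (ml/year), their correlation, residual SDs (ml)."""

    sigma_h: float
    sigma_b: float
    rho: float
    tau_h: float
    tau_b: float
    kappa: float = 0.0

    def validate(self) -> None:
        for name in ("sigma_h", "sigma_b", "tau_h", "tau_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        if not abs(self.kappa) < 1:
            raise ValueError(f"|kappa| must be < 1, got {self.kappa}")

    @property
    def G(self) -> np.ndarray:
        off = self.rho * self.sigma_h * self.sigma_b
        return np.array([[self.sigma_h**2, off], [off, self.sigma_b**2]])

    @property
    def R(self) -> np.ndarray:
        off = self.kappa * self.tau_h * self.tau_b
        return np.array([[self.tau_h**2, off], [off, self.tau_b**2]])

    def as_series(self, names=None) -> pd.Series:
        s = pd.Series({"sigma_h": self.sigma_h, "sigma_b": self.sigma_b,
                       "rho": self.rho, "tau_h": self.tau_h,
                       "tau_b": self.tau_b, "kappa": self.kappa})
        return s if names is None else s.reindex(names)


# ---------------------------------------------------------------------------
# design construction

@dataclass
class _Pattern:
    """Subjects sharing one visit/missingness pattern."""

    t: np.ndarray        # (p,) interval of each stacked observation
    outcome: np.ndarray  # (p,) 0 = hippocampal, 1 = brain
    visit: np.ndarray    # (p,) visit index within subject
    idx: np.ndarray      # (m,) subject indices
    X: np.ndarray        # (m, p, k) fixed-effect design
    y: np.ndarray        # (m, p) responses


@dataclass
class ModelDesign:
    """Grouped design for the joint model.

    ``x`` holds the per-subject covariate rows (centred); ``patterns``
    group subjects by identical visit/missingness structure so each
    group shares one covariance factorisation.
    """

    subject_ids: list
    x: np.ndarray                  # (n, 7)
    patterns: list
    outcomes: tuple                # subset of ("h", "b") with observations
    centering: dict
    centered_at_means: bool
    group: str | None = None

    @property
    def k(self) -> int:
        return 7 * len(self.outcomes)

    @property
    def n_subjects(self) -> int:
        return self.x.shape[0]

    @property
    def nobs(self) -> int:
        return sum(p.y.size for p in self.patterns)

    @property
    def beta_names(self) -> list:
        return [f"{o}:{t}" for o in self.outcomes for t in FIXED_EFFECT_TERMS]

    def with_responses(self, new_y: list) -> "ModelDesign":
        """Same design, new responses (one (m, p) array per pattern)."""
        pats = [dataclasses.replace(p, y=y) for p, y in zip(self.patterns, new_y)]
        return dataclasses.replace(self, patterns=pats)

    def stacked(self, outcome: str):
        """All observations of one outcome: (X7, y, t, subject index)."""
        o = self.outcomes.index(outcome)
        cols = slice(7 * o, 7 * o + 7)
        Xs, ys, ts, ss = [], [], [], []
        for p in self.patterns:
            sel = p.outcome == (0 if outcome == "h" else 1)
            if not sel.any():
                continue
            m = p.X.shape[0]
            Xs.append(p.X[:, sel, cols].reshape(-1, 7))
            ys.append(p.y[:, sel].reshape(-1))
            ts.append(np.tile(p.t[sel], m))
            ss.append(np.repeat(p.idx, sel.sum()))
        return (np.concatenate(Xs), np.concatenate(ys),
                np.concatenate(ts), np.concatenate(ss))


def build_design(subjects: pd.DataFrame, visits: pd.DataFrame,
                 centering="auto", group: str | None = None) -> ModelDesign:
    """Build the grouped joint-model design.

    Continuous covariates (age, MMSE, brain-to-TIV ratio, TIV) are
    centred — at their sample means when ``centering="auto"``, at
    supplied group means when a dict — so the sex-specific slopes are
    interpretable as covariate-adjusted mean rates.  ``centering=None``
    leaves covariates raw (adjusted means are then undefined).
    """
    if group is not None:
        col = ("analysis_group" if "analysis_group" in subjects.columns
               else "group")
        subjects = subjects[subjects[col] == group]
        visits = visits[visits["subject_id"].isin(subjects["subject_id"])]
    if "e4" not in subjects.columns:
        raise ValueError("subjects need an 'e4' column; run the eligibility "
                         "rules first")
    subjects = subjects.reset_index(drop=True)
    covs = subjects[["age", "mmse", "tiv", "brain_vol"]]
    if not np.isfinite(covs.to_numpy(dtype=float)).all():
        raise ValueError("non-finite covariate in joint-model design")

    btiv = (subjects["brain_vol"] / subjects["tiv"]).to_numpy(dtype=float)
    if centering == "auto":
        means = {"age": float(subjects["age"].mean()),
                 "mmse": float(subjects["mmse"].mean()),
                 "btiv": float(btiv.mean()),
                 "tiv": float(subjects["tiv"].mean())}
        centered = True
    elif centering is None:
        means = {"age": 0.0, "mmse": 0.0, "btiv": 0.0, "tiv": 0.0}
        centered = False
    else:
        means = dict(centering)
        centered = True

    male = (subjects["sex"] == "M").astype(float).to_numpy()
    x = np.column_stack([
        male,
        1.0 - male,
        subjects["e4"].to_numpy(dtype=float),
        subjects["age"].to_numpy(dtype=float) - means["age"],
        subjects["mmse"].to_numpy(dtype=float) - means["mmse"],
        btiv - means["btiv"],
        subjects["tiv"].to_numpy(dtype=float) - means["tiv"],
    ])

    ids = subjects["subject_id"].tolist()
    pos = {sid: i for i, sid in enumerate(ids)}
    per_subject: dict[int, tuple] = {}
    for sid, vdf in visits.groupby("subject_id", sort=False):
        if sid not in pos:
            raise ValueError(f"visit rows reference unknown subject id {sid!r}")
        vdf = vdf.sort_values("interval_years")
        t = vdf["interval_years"].to_numpy(dtype=float)
        if np.any(t <= 0):
            raise ValueError(f"subject {sid!r} has a non-positive interval")
        yh = vdf["hippo_loss"].to_numpy(dtype=float)
        yb = vdf["brain_loss"].to_numpy(dtype=float)
        per_subject[pos[sid]] = (t, np.isfinite(yh), np.isfinite(yb), yh, yb)

    missing = [ids[i] for i in range(len(ids)) if i not in per_subject]
    if missing:
        raise ValueError(f"subjects with no visits: {missing[:5]}")

    has_h = any(v[1].any() for v in per_subject.values())
    has_b = any(v[2].any() for v in per_subject.values())
    outcomes = tuple(o for o, present in (("h", has_h), ("b", has_b)) if present)
    if not outcomes:
        raise ValueError("no observed responses")
    k = 7 * len(outcomes)

    groups: dict[tuple, list] = {}
    for i, (t, mh, mb, yh, yb) in per_subject.items():
        key = (tuple(np.round(t, 9)), tuple(mh), tuple(mb))
        groups.setdefault(key, []).append(i)

    patterns = []
    for (tkey, mh, mb, *_), members in sorted(groups.items()):
        t = np.asarray(tkey)
        mh = np.asarray(mh, dtype=bool)
        mb = np.asarray(mb, dtype=bool)
        parts = []
        if "h" in outcomes and mh.any():
            parts.append((0, np.flatnonzero(mh)))
        if "b" in outcomes and mb.any():
            parts.append((1, np.flatnonzero(mb)))
        if not parts:
            continue
        t_all = np.concatenate([t[v] for _, v in parts])
        outcome = np.concatenate([np.full(v.size, o) for o, v in parts])
        visit = np.concatenate([v for _, v in parts])
        idx = np.asarray(members, dtype=int)
        m, p = idx.size, t_all.size
        X = np.zeros((m, p, k))
        for r in range(p):
            block = outcomes.index("h" if outcome[r] == 0 else "b")
            X[:, r, 7 * block:7 * block + 7] = t_all[r] * x[idx]
        y = np.empty((m, p))
        for j, i in enumerate(idx):
            _, _, _, yh, yb = per_subject[i]
            vals = []
            for o, v in parts:
                vals.append((yh if o == 0 else yb)[v])
            y[j] = np.concatenate(vals)
        patterns.append(_Pattern(t=t_all, outcome=outcome.astype(int),
                                 visit=visit.astype(int), idx=idx, X=X, y=y))

    return ModelDesign(subject_ids=ids, x=x, patterns=patterns,
                       outcomes=outcomes, centering=means,
                       centered_at_means=centered, group=group)


# ---------------------------------------------------------------------------
# likelihood machinery

def _pattern_cov(pat: _Pattern, G: np.ndarray, R: np.ndarray) -> np.ndarray:
    o = pat.outcome
    V = np.outer(pat.t, pat.t) * G[np.ix_(o, o)]
    V = V + (pat.visit[:, None] == pat.visit[None, :]) * R[np.ix_(o, o)]
    return V


@dataclass
class _Prep:
    """Sufficient statistics of the likelihood at fixed variance components:
    the log-likelihood is an explicit quadratic in beta."""

    XtVX: np.ndarray
    XtVy: np.ndarray
    ytVy: float
    logdet: float
    N: int

    def loglik(self, beta: np.ndarray) -> float:
        quad = self.ytVy - 2.0 * beta @ self.XtVy + beta @ self.XtVX @ beta
        return -0.5 * (self.N * _LOG2PI + self.logdet + quad)

    def grad_beta(self, beta: np.ndarray) -> np.ndarray:
        return self.XtVy - self.XtVX @ beta


def _prep(design: ModelDesign, vc: VarianceComponents) -> _Prep:
    G, R = vc.G, vc.R
    k = design.k
    XtVX = np.zeros((k, k))
    XtVy = np.zeros(k)
    ytVy = 0.0
    logdet = 0.0
    N = 0
    for pat in design.patterns:
        V = _pattern_cov(pat, G, R)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            raise ValueError(
                "singular subject covariance (check that residual and "
                "random-slope variances are not all zero)") from None
        m, p = pat.y.shape
        Xw = solve_triangular(L, pat.X.transpose(1, 0, 2).reshape(p, -1),
                              lower=True).reshape(p, m, k)
        yw = solve_triangular(L, pat.y.T, lower=True)
        XtVX += np.einsum("pmk,pml->kl", Xw, Xw, optimize=True)
        XtVy += np.einsum("pmk,pm->k", Xw, yw, optimize=True)
        ytVy += float((yw**2).sum())
        logdet += 2.0 * m * float(np.log(np.diag(L)).sum())
        N += m * p
    return _Prep(XtVX, XtVy, ytVy, logdet, N)


def marginal_loglik(design: ModelDesign, beta_h, beta_b,
                    vc: VarianceComponents) -> float:
    """Exact marginal log-likelihood of the stacked responses.

    ``beta_h``/``beta_b`` are the 7-vectors of fixed effects for the
    outcomes present in the design (pass ``None`` for an absent one).
    """
    vc.validate()
    blocks = {"h": beta_h, "b": beta_b}
    beta = np.concatenate([np.asarray(blocks[o], dtype=float)
                           for o in design.outcomes])
    if beta.size != design.k:
        raise ValueError(f"expected {design.k} fixed effects, got {beta.size}")
    return _prep(design, vc).loglik(beta)


def profile_fixed_effects(design: ModelDesign, vc: VarianceComponents):
    """GLS fixed effects at given variance components.

    Returns ``(beta, cov_beta, loglik)``; the gradient of the marginal
    log-likelihood with respect to beta vanishes at the solution.
    """
    prep = _prep(design, vc)
    try:
        cf = cho_factor(prep.XtVX)
    except np.linalg.LinAlgError:
        raise ValueError("rank-deficient fixed-effect design") from None
    beta = cho_solve(cf, prep.XtVy)
    cov_beta = cho_solve(cf, np.eye(design.k))
    return beta, cov_beta, prep.loglik(beta)


# unconstrained parameterisation of the variance components --------------------

_CANONICAL_THETA = ("log_sigma_h", "log_sigma_b", "atanh_rho",
                    "log_tau_h", "log_tau_b", "atanh_kappa")
_NATURAL = {"log_sigma_h": "sigma_h", "log_sigma_b": "sigma_b",
            "atanh_rho": "rho", "log_tau_h": "tau_h",
            "log_tau_b": "tau_b", "atanh_kappa": "kappa"}


class _ThetaMap:
    """Active transformed variance-component coordinates for a given
    outcome set and model options."""

    def __init__(self, outcomes, kappa=False, fix_rho=False):
        both = set(outcomes) == {"h", "b"}
        active = []
        if "h" in outcomes:
            active.append("log_sigma_h")
        if "b" in outcomes:
            active.append("log_sigma_b")
        if both and not fix_rho:
            active.append("atanh_rho")
        if "h" in outcomes:
            active.append("log_tau_h")
        if "b" in outcomes:
            active.append("log_tau_b")
        if both and kappa:
            active.append("atanh_kappa")
        self.names = tuple(active)

    def __len__(self):
        return len(self.names)

    @property
    def natural_names(self):
        return tuple(_NATURAL[n] for n in self.names)

    def to_vc(self, theta: np.ndarray) -> VarianceComponents:
        vals = {"sigma_h": 0.0, "sigma_b": 0.0, "rho": 0.0,
                "tau_h": 0.0, "tau_b": 0.0, "kappa": 0.0}
        for name, v in zip(self.names, theta):
            nat = _NATURAL[name]
            vals[nat] = float(np.tanh(v)) if name.startswith("atanh") \
                else float(np.exp(v))
        return VarianceComponents(**vals)

    def from_vc(self, vc: VarianceComponents) -> np.ndarray:
        out = []
        for name in self.names:
            v = getattr(vc, _NATURAL[name])
            if name.startswith("atanh"):
                out.append(np.arctanh(np.clip(v, -0.999, 0.999)))
            else:
                out.append(np.log(max(v, 1e-8)))
        return np.array(out)

    def jacobian_diag(self, vc: VarianceComponents) -> np.ndarray:
        """d(natural)/d(transformed), elementwise."""
        out = []
        for name in self.names:
            v = getattr(vc, _NATURAL[name])
            out.append(1.0 - v**2 if name.startswith("atanh") else v)
        return np.array(out)


def _start_values(design: ModelDesign, tmap: _ThetaMap) -> np.ndarray:
    """Method-of-moments starts: per-outcome OLS, then a regression of the
    squared residuals on interval^2 to split slope vs residual variance."""
    est = {}
    subj_rates = {}
    for o in design.outcomes:
        X, y, t, s = design.stacked(o)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        e = y - X @ beta
        ve = float(np.var(e)) or 1.0
        A = np.column_stack([np.ones_like(t), t**2])
        c = np.linalg.lstsq(A, e**2, rcond=None)[0]
        tau2 = max(c[0], 0.05 * ve)
        sig2 = max(c[1], 0.05 * ve / float(np.mean(t**2)))
        est[f"sigma_{o}"] = np.sqrt(sig2)
        est[f"tau_{o}"] = np.sqrt(tau2)
        subj_rates[o] = pd.Series(e / t).groupby(pd.Series(s)).mean()
    rho0 = 0.0
    if set(design.outcomes) == {"h", "b"}:
        joined = pd.concat([subj_rates["h"], subj_rates["b"]], axis=1).dropna()
        if len(joined) >= 3:
            r = float(np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1])
            if np.isfinite(r):
                rho0 = float(np.clip(r, -0.9, 0.9))
    vc0 = VarianceComponents(
        sigma_h=est.get("sigma_h", 0.0), sigma_b=est.get("sigma_b", 0.0),
        rho=rho0, tau_h=est.get("tau_h", 0.0), tau_b=est.get("tau_b", 0.0),
        kappa=0.0)
    return tmap.from_vc(vc0)


def observed_information(design: ModelDesign, beta: np.ndarray,
                         theta: np.ndarray, tmap: _ThetaMap,
                         step: float = 1e-4):
    """Covariance of all parameters from the observed information.

    The log-likelihood is exactly quadratic in beta given theta, so the
    beta block of the Hessian is -X'V^{-1}X; the cross and
    variance-component blocks come from central finite differences.  The
    variance-component block is mapped back to the natural scale (SDs,
    correlations) by the delta method.  Returns the covariance matrix
    over ``beta_names + natural vc names`` and raises if the Hessian is
    indefinite.
    """
    q = len(tmap)
    kb = beta.size
    prep0 = _prep(design, tmap.to_vc(theta))
    H = np.zeros((kb + q, kb + q))
    H[:kb, :kb] = -prep0.XtVX
    steps = step * np.maximum(1.0, np.abs(theta))
    f0 = prep0.loglik(beta)
    fp = np.empty(q)
    fm = np.empty(q)
    for j in range(q):
        e = np.zeros(q); e[j] = steps[j]
        pp = _prep(design, tmap.to_vc(theta + e))
        pm = _prep(design, tmap.to_vc(theta - e))
        fp[j] = pp.loglik(beta)
        fm[j] = pm.loglik(beta)
        H[:kb, kb + j] = (pp.grad_beta(beta) - pm.grad_beta(beta)) / (2 * steps[j])
        H[kb + j, :kb] = H[:kb, kb + j]
        H[kb + j, kb + j] = (fp[j] - 2 * f0 + fm[j]) / steps[j]**2
    for j in range(q):
        for l in range(j + 1, q):
            e = np.zeros(q); e[j] = steps[j]; e[l] = steps[l]
            fpp = _prep(design, tmap.to_vc(theta + e)).loglik(beta)
            fmm = _prep(design, tmap.to_vc(theta - e)).loglik(beta)
            h = (fpp - fp[j] - fp[l] + 2 * f0 - fm[j] - fm[l] + fmm) \
                / (2 * steps[j] * steps[l])
            H[kb + j, kb + l] = H[kb + l, kb + j] = h
    info = -H
    try:
        cov_t = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise ValueError("indefinite observed information; restart the fit "
                         "from different starting values") from None
    cov_t = 0.5 * (cov_t + cov_t.T)
    w, U = np.linalg.eigh(cov_t)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError("indefinite observed information; restart the fit "
                         "from different starting values")
    cov_t = (U * np.clip(w, 0.0, None)) @ U.T
    # delta method: transformed vc block -> natural scale
    scale = np.concatenate([np.ones(kb),
                            tmap.jacobian_diag(tmap.to_vc(theta))])
    return cov_t * np.outer(scale, scale)


# ---------------------------------------------------------------------------
# model / results

class JointAtrophyModel:
    """Joint bivariate random-slope model of hippocampal and whole-brain
    BSI losses for one clinical group.

    Parameters
    ----------
    subjects, visits : DataFrame
        Eligible subjects (with ``e4``) and their follow-up measurements.
    group : str, optional
        Restrict to one analysis group.
    centering : "auto" | dict | None
        Covariate centering policy (see :func:`build_design`).
    kappa : bool
        Estimate a same-visit residual cross-correlation (default off:
        the outcomes are linked through the slope correlation only).
    reml : bool
        Use REML instead of ML for the variance components.
    fix_rho : float or None
        Fix the slope correlation (e.g. 0 for an independence fit).
    """

    def __init__(self, subjects, visits, group=None, centering="auto",
                 kappa=False, reml=False, fix_rho=None):
        self.design = build_design(subjects, visits, centering=centering,
                                   group=group)
        n_carrier = int(round(self.design.x[:, 2].sum()))
        if 0 < self.design.n_subjects and n_carrier in (0, self.design.n_subjects):
            raise ValueError("both carrier states must be present")
        if self.design.n_subjects < 2:
            raise ValueError("need at least 2 subjects with visits")
        self.kappa = bool(kappa)
        self.reml = bool(reml)
        self.fix_rho = fix_rho
        self.tmap = _ThetaMap(self.design.outcomes, kappa=self.kappa,
                              fix_rho=fix_rho is not None)
        self._fixed = {}
        if fix_rho is not None:
            self._fixed["rho"] = float(fix_rho)

    @classmethod
    def from_tables(cls, subjects, visits, **kw):
        return cls(subjects, visits, **kw)

    # -- criterion evaluated by the optimizer ------------------------------
    def _objective(self, theta: np.ndarray) -> float:
        vc = self._vc_at(theta)
        try:
            prep = _prep(self.design, vc)
            cf = cho_factor(prep.XtVX)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12
        beta = cho_solve(cf, prep.XtVy)
        ll = prep.loglik(beta)
        if self.reml:
            ll -= 0.5 * (2.0 * np.log(np.diag(cf[0])).sum()
                         - self.design.k * _LOG2PI)
        return -ll if np.isfinite(ll) else 1e12

    def _vc_at(self, theta: np.ndarray) -> VarianceComponents:
        vc = self.tmap.to_vc(theta)
        if "rho" in self._fixed:
            vc = dataclasses.replace(vc, rho=self._fixed["rho"])
        return vc

    def fit(self, start: VarianceComponents | None = None, maxiter: int = 300,
            restarts: int = 0, seed: int | None = None,
            compute_cov: bool = True) -> "JointAtrophyResults":
        theta0 = (self.tmap.from_vc(start) if start is not None
                  else _start_values(self.design, self.tmap))
        f0 = self._objective(theta0)
        rng = np.random.default_rng(seed)
        q = len(self.tmap)

        def _gradnorm(th):
            # central differences; step large enough to beat float noise in
            # log-likelihoods of magnitude ~1e3-1e4
            h = 1e-5
            g = np.empty(q)
            for j in range(q):
                e = np.zeros(q); e[j] = h
                g[j] = (self._objective(th + e)
                        - self._objective(th - e)) / (2 * h)
            return float(np.max(np.abs(g)))

        def _lbfgs(th):
            return optimize.minimize(
                self._objective, th, method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7})

        best = None
        starts = [theta0] + [theta0 + rng.normal(0, 0.3, q)
                             for _ in range(restarts)]
        for th0 in starts:
            res = _lbfgs(th0)
            if best is None or res.fun < best.fun:
                best = res
        # recovery: line-search failures are retried from perturbed points,
        # then polished derivative-free
        n_extra = 0
        if not best.success:
            for scale in (0.02, 0.1, 0.3):
                res = _lbfgs(best.x + rng.normal(0, scale, q))
                n_extra += res.nit
                if res.fun < best.fun:
                    best = res
                if best.success:
                    break
            if not best.success:
                nm = optimize.minimize(
                    self._objective, best.x, method="Nelder-Mead",
                    options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 4000})
                n_extra += nm.nit
                if nm.fun <= best.fun:
                    best = nm
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError("joint model failed to converge", best=best)
        if best.fun > f0 + 1e-6:
            # quasi-Newton must not end below the starting likelihood
            raise ConvergenceError(
                f"optimizer worsened the likelihood (start {-f0:.4f}, "
                f"end {-best.fun:.4f})", best=best)
        theta_hat = best.x
        vc_hat = self._vc_at(theta_hat)
        beta, cov_beta, llf = profile_fixed_effects(self.design, vc_hat)
        grad_norm = _gradnorm(theta_hat)

        boundary = []
        for name, th in zip(self.tmap.names, theta_hat):
            if name.startswith("log") and th < np.log(1e-6):
                boundary.append(_NATURAL[name])
            if name.startswith("atanh") and abs(np.tanh(th)) > 0.999:
                boundary.append(_NATURAL[name])

        names = self.design.beta_names + list(self.tmap.natural_names)
        if compute_cov:
            cov = observed_information(self.design, beta, theta_hat, self.tmap)
            cov = pd.DataFrame(cov, index=names, columns=names)
        else:
            cov = None
        params = pd.Series(
            np.concatenate([beta,
                            [getattr(vc_hat, n) for n in self.tmap.natural_names]]),
            index=names)
        gtol = 1e-4 * max(1.0, abs(float(best.fun)))
        convergence = {
            "iterations": int(best.nit) + n_extra, "grad_norm": grad_norm,
            "success": bool(best.success) or grad_norm <= gtol,
            "message": str(best.message),
            "llf_start": float(-f0), "boundary": boundary,
        }
        if not convergence["success"] and grad_norm > 10 * gtol:
            raise ConvergenceError(
                f"no convergence after {convergence['iterations']} "
                f"iterations: {best.message}", best=best)
        return JointAtrophyResults(
            model=self, params=params, beta=pd.Series(beta, index=self.design.beta_names),
            vc=vc_hat, llf=float(llf), cov=cov, cov_beta=cov_beta,
            convergence=convergence)


class JointAtrophyResults:
    """ML estimates, uncertainty and diagnostics for the joint model."""

    def __init__(self, model, params, beta, vc, llf, cov, cov_beta,
                 convergence):
        self.model = model
        self.params = params
        self.beta = beta
        self.vc = vc
        self.llf = llf
        self._cov = cov
        self.cov_beta = cov_beta
        self.convergence = convergence

    # -- basic accessors ----------------------------------------------------
    @property
    def design(self) -> ModelDesign:
        return self.model.design

    @property
    def n_subjects(self) -> int:
        return self.design.n_subjects

    @property
    def nobs(self) -> int:
        return self.design.nobs

    @property
    def converged(self) -> bool:
        return self.convergence.get("success", False) or \
            self.convergence.get("grad_norm", np.inf) < 1e-3

    def cov_params(self) -> pd.DataFrame:
        """Full parameter covariance (fixed effects and natural-scale
        variance components) from the observed information."""
        if self._cov is None:
            raise ValueError("fit was run with compute_cov=False; refit "
                             "with compute_cov=True (observed_information)")
        return self._cov

    def bse(self) -> pd.Series:
        cov = self.cov_params()
        return pd.Series(np.sqrt(np.diag(cov.to_numpy())), index=cov.index)

    # -- contrasts (delegated to the contrast module) -----------------------
    def adjusted_rate(self, outcome: str, carrier: int):
        from .contrast import mean_adjusted_rate
        return mean_adjusted_rate(self, outcome, carrier)

    def rate_contrast(self):
        from .contrast import brain_adjusted_difference
        return brain_adjusted_difference(self)

    def bootstrap_contrast(self, B: int, seed: int):
        from .contrast import parametric_bootstrap_ci
        return parametric_bootstrap_ci(self, B=B, seed=seed)

    # -- simulation ---------------------------------------------------------
    def simulate(self, rng: np.random.Generator) -> list:
        """Simulate responses from the fitted model at the observed design
        (one (m, p) array per pattern)."""
        return simulate_responses(self.design, self.beta.to_numpy(),
                                  self.vc, rng)

    def summary(self) -> str:
        se = self.bse()
        tab = pd.DataFrame({"estimate": self.params, "se": se})
        lines = [
            "Joint bivariate random-slope model"
            + ("" if self.design.group is None
               else f" — group {self.design.group}"),
            f"subjects = {self.n_subjects}, observations = {self.nobs}, "
            f"log-likelihood = {self.llf:.3f} "
            f"({'REML' if self.model.reml else 'ML'})",
            tab.to_string(float_format=lambda v: f"{v: .5f}"),
            f"convergence: {self.convergence['iterations']} iterations, "
            f"max|grad| = {self.convergence['grad_norm']:.2e}"
            + (f", boundary: {self.convergence['boundary']}"
               if self.convergence["boundary"] else ""),
        ]
        return "\n".join(lines)


def simulate_responses(design: ModelDesign, beta: np.ndarray,
                       vc: VarianceComponents,
                       rng: np.random.Generator) -> list:
    """Draw new responses from the model at the observed design."""
    G, R = vc.G, vc.R
    out = []
    for pat in design.patterns:
        V = _pattern_cov(pat, G, R)
        L = np.linalg.cholesky(V + 1e-12 * np.eye(V.shape[0]))
        mean = pat.X @ beta
        z = rng.standard_normal(pat.y.shape)
        out.append(mean + z @ L.T)
    return out


def fit_joint_model(subjects, visits, group=None, **options) -> JointAtrophyResults:
    """Convenience wrapper: build the model and fit it."""
    fit_kw = {k: options.pop(k) for k in ("start", "maxiter", "restarts", "seed")
              if k in options}
    return JointAtrophyModel(subjects, visits, group=group, **options).fit(**fit_kw)
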