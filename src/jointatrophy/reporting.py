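"""Pipeline driver and delimited-table reporting.

Reads/writes the long-format subject and visit tables (CSV, UTF-8,
"." decimal), applies the selection rules, fits the baseline and joint
models per clinical group and emits three report tables shaped like the
published ones: demographics, baseline cross-sectional results and
longitudinal rate results.  Hippocampal rates are printed to 3 decimals
(ml/year), brain rates and volumes to 2.
"""

from __future__ import annotations

import os
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .baseline import BaselineVolumeModel
from .cohort import (SUBJECT_COLUMNS, VISIT_COLUMNS, generate_cohort,
                     generate_trajectories)
from .config import GROUP_ORDER, AnalysisConfig, default_parameters
from .contrast import parametric_bootstrap_ci
from .joint import ConvergenceError, JointAtrophyModel
from .rules import apply_eligibility, exclusion_table

REQUIRED_SUBJECT_COLUMNS = ["subject_id", "group", "apoe1", "apoe2", "sex",
                            "age", "mmse", "tiv", "brain_vol", "hippo_vol"]
REQUIRED_VISIT_COLUMNS = ["subject_id", "interval_years", "hippo_loss",
                          "brain_loss"]


# ---------------------------------------------------------------------------
# formatting helpers

def fmt(x: float, dp: int) -> str:
    return f"{x:.{dp}f}"


def fmt_ci(lo: float, hi: float, dp: int) -> str:
    return f"[{fmt(lo, dp)}, {fmt(hi, dp)}]"


def fmt_p(p: float) -> str:
    return "p<0.001" if p < 0.001 else f"p = {p:.3f}"


def format_genotype_counts(counts) -> str:
    """Render genotype counts as 'n (pct%)' triplets, e.g. 44/70/34 of
    148 -> '44 (30%), 70 (47%), 34 (23%)'."""
    total = sum(counts)
    if total == 0:
        return ""
    return ", ".join(f"{c} ({round(100 * c / total):.0f}%)" for c in counts)


def _atomic_write(df: pd.DataFrame, path: Path, **to_csv_kw) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            df.to_csv(fh, index=False, **to_csv_kw)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# table I/O

def read_tables(subjects_path, visits_path, trajectories_path=None):
    """Read and validate the subject/visit (and optional trajectory)
    tables.  Raises on missing columns, duplicate (subject, interval)
    visit rows and non-numeric measurements; warns when the interval
    column looks like months rather than years."""
    subjects = pd.read_csv(subjects_path)
    visits = pd.read_csv(visits_path)
    missing = [c for c in REQUIRED_SUBJECT_COLUMNS if c not in subjects.columns]
    if missing:
        raise ValueError(f"{subjects_path}: missing column(s) {missing}")
    missing = [c for c in REQUIRED_VISIT_COLUMNS if c not in visits.columns]
    if missing:
        raise ValueError(f"{visits_path}: missing column(s) {missing}")

    for col in ("age", "mmse", "tiv", "brain_vol", "hippo_vol"):
        try:
            subjects[col] = pd.to_numeric(subjects[col])
        except (ValueError, TypeError):
            raise ValueError(f"{subjects_path}: non-numeric values in "
                             f"column {col!r}") from None
    for col in ("interval_years", "hippo_loss", "brain_loss"):
        try:
            visits[col] = pd.to_numeric(visits[col])
        except (ValueError, TypeError):
            raise ValueError(f"{visits_path}: non-numeric values in "
                             f"column {col!r}") from None

    dup = visits.duplicated(subset=["subject_id", "interval_years"], keep=False)
    if dup.any():
        row = visits.loc[dup].iloc[0]
        raise ValueError(
            f"duplicated visit row: subject {row['subject_id']!r} at "
            f"interval {row['interval_years']}")
    if (visits["interval_years"] > 5).any():
        warnings.warn(
            "interval_years values exceed 5; the column may be in months "
            "— divide by 12 to convert to years", UserWarning)
    trajectories = None
    if trajectories_path is not None:
        trajectories = pd.read_csv(trajectories_path)
        need = ["subject_id", "month", "diagnosis"]
        missing = [c for c in need if c not in trajectories.columns]
        if missing:
            raise ValueError(f"{trajectories_path}: missing column(s) {missing}")
    return subjects, visits, trajectories


def write_tables(subjects, visits, outdir, trajectories=None):
    outdir = Path(outdir)
    _atomic_write(subjects, outdir / "subjects.csv")
    _atomic_write(visits, outdir / "visits.csv")
    if trajectories is not None:
        _atomic_write(trajectories, outdir / "trajectories.csv")
    return outdir


# ---------------------------------------------------------------------------
# report tables

def demographics_table(subjects: pd.DataFrame,
                       visits: pd.DataFrame) -> pd.DataFrame:
    """Per-group demographics in the published summary shape."""
    rows = []
    months = sorted(visits["month"].unique()) if "month" in visits else []
    gcol = "analysis_group" if "analysis_group" in subjects.columns else "group"
    for group in [g for g in GROUP_ORDER if g in set(subjects[gcol])]:
        s = subjects[subjects[gcol] == group]
        v = visits[visits["subject_id"].isin(s["subject_id"])]
        het = (((s["apoe1"] == 4) ^ (s["apoe2"] == 4))).sum()
        hom = ((s["apoe1"] == 4) & (s["apoe2"] == 4)).sum()
        non = len(s) - het - hom
        row = {
            "group": group,
            "n": len(s),
            "n_per_visit": ", ".join(
                str((v["month"] == m).sum()) for m in months),
            "genotype_non_het_hom": format_genotype_counts([non, het, hom]),
            "pct_male": f"{round(100 * (s['sex'] == 'M').mean()):.0f}%",
            "age": f"{s['age'].mean():.1f} ({s['age'].std():.1f})",
            "mmse": f"{s['mmse'].mean():.1f} ({s['mmse'].std():.1f})",
            "tiv": f"{s['tiv'].mean():.0f} ({s['tiv'].std():.0f})",
            "hippo_vol": f"{s['hippo_vol'].mean():.1f} "
                         f"({s['hippo_vol'].std():.1f})",
        }
        rows.append(row)
    return pd.DataFrame(rows)


def baseline_table(fits: dict) -> pd.DataFrame:
    """Cross-sectional results, one row per group."""
    rows = []
    for group, res in fits.items():
        mean0, ci0 = res.adjusted_mean(carrier=0)
        diff, ci, p = res.e4_difference()
        rows.append({
            "group": group,
            "adj_mean_e4neg_cm3": f"{fmt(mean0, 2)} {fmt_ci(*ci0, 2)}",
            "difference_cm3": f"{fmt(diff, 2)} {fmt_ci(*ci, 2)}",
            "p": fmt_p(p),
        })
    return pd.DataFrame(rows)


def longitudinal_table(results: dict) -> pd.DataFrame:
    """Rate results shaped like the published longitudinal table:
    one column per group, rows for each outcome/quantity."""
    cols = {}
    for group, (res, rc) in results.items():
        rate_b0, ci_b0 = res.adjusted_rate("b", carrier=0)
        rate_h0, ci_h0 = res.adjusted_rate("h", carrier=0)
        cols[group] = {
            "brain rate e4- (ml/yr)": f"{fmt(rate_b0, 2)} {fmt_ci(*ci_b0, 2)}",
            "brain difference e4+ vs e4-":
                f"{fmt(rc.delta_b, 2)} {fmt_ci(*rc.ci_b, 2)} {fmt_p(rc.p_b)}",
            "hippocampal rate e4- (ml/yr)":
                f"{fmt(rate_h0, 3)} {fmt_ci(*ci_h0, 3)}",
            "hippocampal difference e4+ vs e4-":
                f"{fmt(rc.delta_h, 3)} {fmt_ci(*rc.ci_h, 3)} {fmt_p(rc.p_h)}",
            "hippocampal difference adjusted for brain rate":
                f"{fmt(rc.delta_adj, 3)} {fmt_ci(*rc.ci_adj, 3)} "
                f"{fmt_p(rc.p_adj)}",
        }
    tab = pd.DataFrame(cols)
    tab.insert(0, "quantity", tab.index)
    return tab.reset_index(drop=True)


# ---------------------------------------------------------------------------
# full pipeline

@dataclass
class ReportBundle:
    demographics: pd.DataFrame
    baseline: pd.DataFrame
    longitudinal: pd.DataFrame
    exclusions: pd.DataFrame
    contrasts: dict
    log: list = field(default_factory=list)
    failures: dict = field(default_factory=dict)


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run the whole pipeline: data in (simulated or read), selection,
    per-group baseline and longitudinal fits, report tables out."""
    config.validate()
    log = [f"seed = {config.seed}"]
    if config.cohort is not None:
        params = default_parameters()
        missing = set(config.cohort.groups) - set(params)
        if missing:
            raise ValueError(f"no default generating parameters for groups "
                             f"{sorted(missing)}; supply tables instead")
        subjects, visits = generate_cohort(config.cohort, params)
        trajectories = generate_trajectories(
            subjects, config.cohort.schedule_months, seed=config.seed + 1)
        log.append(f"simulated {len(subjects)} subjects, "
                   f"{len(visits)} visits")
    else:
        subjects, visits, trajectories = read_tables(
            config.subjects_path, config.visits_path,
            config.trajectories_path)
        log.append(f"read {len(subjects)} subjects, {len(visits)} visits")

    kept, kept_visits, tally = apply_eligibility(
        subjects, visits, trajectories, late_policy=config.late_policy)
    log.append(f"exclusions: {tally}")
    exclusions = exclusion_table(tally, len(subjects))

    groups = [g for g in GROUP_ORDER if g in set(kept["analysis_group"])]
    extra = sorted(set(kept["analysis_group"]) - set(groups))
    groups += extra
    baseline_fits, longitudinal, failures = {}, {}, {}
    for group in groups:
        n_g = int((kept["analysis_group"] == group).sum())
        if n_g == 0:
            log.append(f"group {group}: empty, skipped")
            continue
        try:
            baseline_fits[group] = BaselineVolumeModel(
                kept, group=group).fit()
        except ValueError as err:
            failures[f"baseline/{group}"] = str(err)
            log.append(f"group {group}: baseline failed ({err})")
        try:
            model = JointAtrophyModel(
                kept, kept_visits, group=group,
                centering=config.centering, kappa=config.kappa,
                reml=config.reml)
            res = model.fit(seed=config.seed)
            if config.bootstrap >= 100:
                rc = parametric_bootstrap_ci(res, B=config.bootstrap,
                                             seed=config.seed + 2)
            else:
                rc = res.rate_contrast()
            longitudinal[group] = (res, rc)
            log.append(
                f"group {group}: joint fit llf={res.llf:.2f}, "
                f"{res.convergence['iterations']} iterations")
        except (ValueError, ConvergenceError) as err:
            failures[f"joint/{group}"] = str(err)
            log.append(f"group {group}: joint fit failed ({err})")

    bundle = ReportBundle(
        demographics=demographics_table(kept, kept_visits),
        baseline=baseline_table(baseline_fits),
        longitudinal=longitudinal_table(longitudinal),
        exclusions=exclusions,
        contrasts={g: rc for g, (_, rc) in longitudinal.items()},
        log=log, failures=failures)
    return bundle


def write_report_tables(bundle: ReportBundle, outdir) -> list:
    """Write the report tables as CSV (atomic replace).  Returns paths."""
    outdir = Path(outdir)
    paths = []
    for name, df in (("table1_demographics", bundle.demographics),
                     ("table2_baseline", bundle.baseline),
                     ("table3_longitudinal", bundle.longitudinal),
                     ("exclusions", bundle.exclusions)):
        path = outdir / f"{name}.csv"
        _atomic_write(df, path)
        paths.append(path)
    log_path = outdir / "run_log.txt"
    outdir.mkdir(parents=True, exist_ok=True)
    with open(log_path, "w") as fh:
        fh.write("\n".join(bundle.log))
        if bundle.failures:
            fh.write("\nFAILURES:\n")
            for k, v in bundle.failures.items():
                fh.write(f"  {k}: {v}\n")
    paths.append(log_path)
    return paths


def plot_contrasts(bundle: ReportBundle, path=None):
    """Forest-style summary of the three carrier contrasts per group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    quantities = [("delta_b", "ci_b", "brain"),
                  ("delta_h", "ci_h", "hippocampus"),
                  ("delta_adj", "ci_adj", "hippocampus | brain rate")]
    fig, axes = plt.subplots(1, 3, figsize=(10, 3), sharey=True)
    groups = list(bundle.contrasts)
    ypos = np.arange(len(groups))
    for ax, (est, ci, title) in zip(axes, quantities):
        for i, g in enumerate(groups):
            rc = bundle.contrasts[g]
            lo, hi = getattr(rc, ci)
            ax.plot([lo, hi], [i, i], "-", color="C0")
            ax.plot([getattr(rc, est)], [i], "o", color="C0")
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_title(title, fontsize=9)
    axes[0].set_yticks(ypos, groups)
    fig.suptitle("e4+ vs e4- atrophy-rate differences (ml/year)", fontsize=10)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
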