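"""Subject selection rules: APOE coding, MCI course classification,
eligibility filtering.

The study design codes APOE epsilon4 carrier status as 1 for carriers of
one or two epsilon4 alleles and 0 otherwise, excludes every epsilon2
carrier (2/2, 2/3 and 2/4 genotypes), splits MCI subjects into
progressors (AD diagnosis within 36 months of baseline, maintained
thereafter) and stable subjects, excludes MCI subjects who revert from
AD back to MCI or who revert to normal cognition, and requires a
baseline scan plus at least one follow-up scan.
"""

from __future__ import annotations

import enum

import pandas as pd

#: months within which an MCI -> AD conversion counts as progression
#: (inclusive boundary: the 36-month visit itself counts).
PROGRESSION_WINDOW_MONTHS = 36

VALID_ALLELES = frozenset({2, 3, 4})
VALID_DIAGNOSES = frozenset({"Normal", "MCI", "AD"})


class CarrierStatus(enum.Enum):
    NON_CARRIER = 0
    CARRIER = 1
    EXCLUDED_E2 = "e2"


class MCICourse(enum.Enum):
    MCI_S = "MCI-S"
    MCI_P = "MCI-P"
    EXCLUDE_REVERT = "exclude_revert"
    EXCLUDE_TO_NORMAL = "exclude_to_normal"
    EXCLUDE_LATE_PROGRESSION = "exclude_late_progression"
    NOT_MCI = "not_mci"


def code_apoe_status(alleles) -> CarrierStatus:
    """Map an allele pair to carrier status.

    Any epsilon2 allele excludes the subject outright; otherwise the
    subject is a carrier iff at least one allele is epsilon4.
    """
    a, b = alleles
    for x in (a, b):
        if x not in VALID_ALLELES:
            raise ValueError(f"invalid APOE allele {x!r}; expected one of 2, 3, 4")
    if 2 in (a, b):
        return CarrierStatus.EXCLUDED_E2
    if 4 in (a, b):
        return CarrierStatus.CARRIER
    return CarrierStatus.NON_CARRIER


def classify_mci_course(trajectory, late_policy: str = "stable") -> MCICourse:
    """Classify an MCI subject's observed diagnosis trajectory.

    ``trajectory`` is an ordered sequence of ``(month, diagnosis)`` pairs,
    the first entry being baseline.  Classification uses observed visits
    only (no look-ahead beyond the data).

    ``late_policy`` governs a case the design leaves open — a first AD
    diagnosis after the 36-month window with clean MCI before it:
    ``"stable"`` labels the subject MCI_S (stable through the window),
    ``"exclude"`` returns EXCLUDE_LATE_PROGRESSION.
    """
    traj = list(trajectory)
    if not traj:
        raise ValueError("empty diagnosis trajectory")
    months = [m for m, _ in traj]
    if any(m2 <= m1 for m1, m2 in zip(months, months[1:])):
        raise ValueError(f"visit months not strictly increasing: {months}")
    for _, dx in traj:
        if dx not in VALID_DIAGNOSES:
            raise ValueError(f"invalid diagnosis {dx!r}")
    if late_policy not in ("stable", "exclude"):
        raise ValueError(f"unknown late_policy {late_policy!r}")

    if traj[0][1] != "MCI":
        return MCICourse.NOT_MCI

    first_ad_month = None
    for month, dx in traj:
        if dx == "Normal":
            # reversion after an AD diagnosis counts as a reversion from AD
            if first_ad_month is not None:
                return MCICourse.EXCLUDE_REVERT
            return MCICourse.EXCLUDE_TO_NORMAL
        if dx == "AD" and first_ad_month is None:
            first_ad_month = month
        elif dx == "MCI" and first_ad_month is not None:
            return MCICourse.EXCLUDE_REVERT

    if first_ad_month is None:
        return MCICourse.MCI_S
    if first_ad_month <= PROGRESSION_WINDOW_MONTHS:
        return MCICourse.MCI_P
    return (MCICourse.MCI_S if late_policy == "stable"
            else MCICourse.EXCLUDE_LATE_PROGRESSION)


#: exclusion tally keys, in filtering order (each subject is tallied at
#: most once, under the first applicable reason).
EXCLUSION_REASONS = (
    "no_follow_up", "e2_carrier", "mci_revert", "mci_to_normal",
    "mci_late_progression",
)

_COURSE_TO_REASON = {
    MCICourse.EXCLUDE_REVERT: "mci_revert",
    MCICourse.EXCLUDE_TO_NORMAL: "mci_to_normal",
    MCICourse.EXCLUDE_LATE_PROGRESSION: "mci_late_progression",
}


def apply_eligibility(subjects: pd.DataFrame, visits: pd.DataFrame,
                      trajectories: pd.DataFrame | None = None,
                      late_policy: str = "stable"):
    """Apply the selection rules to subject/visit tables.

    Returns ``(kept_subjects, kept_visits, tally)``.  ``kept_subjects``
    gains two columns: ``e4`` (0/1 carrier status) and
    ``analysis_group`` (the group label with MCI split into MCI-S /
    MCI-P when trajectories are supplied).  ``tally`` counts excluded
    subjects per reason; every input subject lands either in the kept
    set or in exactly one tally bucket.
    """
    known = set(subjects["subject_id"])
    orphans = set(visits["subject_id"]) - known
    if orphans:
        raise ValueError(
            f"visit rows reference unknown subject ids: {sorted(orphans)[:5]}"
        )

    follow_ups = visits.groupby("subject_id").size()
    courses = {}
    if trajectories is not None:
        for sid, tdf in trajectories.groupby("subject_id"):
            tdf = tdf.sort_values("month")
            courses[sid] = classify_mci_course(
                list(zip(tdf["month"], tdf["diagnosis"])), late_policy)

    tally = {r: 0 for r in EXCLUSION_REASONS}
    keep_rows, e4_col, agroup_col = [], [], []
    for row in subjects.itertuples(index=False):
        sid = row.subject_id
        if follow_ups.get(sid, 0) == 0:
            tally["no_follow_up"] += 1
            continue
        status = code_apoe_status((row.apoe1, row.apoe2))
        if status is CarrierStatus.EXCLUDED_E2:
            tally["e2_carrier"] += 1
            continue
        agroup = row.group
        course = courses.get(sid)
        if course in _COURSE_TO_REASON:
            tally[_COURSE_TO_REASON[course]] += 1
            continue
        if course in (MCICourse.MCI_S, MCICourse.MCI_P):
            agroup = course.value
        keep_rows.append(sid)
        e4_col.append(status.value)
        agroup_col.append(agroup)

    kept = subjects[subjects["subject_id"].isin(keep_rows)].copy()
    kept["e4"] = pd.Series(e4_col, index=kept.index, dtype=int)
    kept["analysis_group"] = pd.Series(agroup_col, index=kept.index)
    kept_visits = visits[visits["subject_id"].isin(keep_rows)].reset_index(drop=True)
    return kept.reset_index(drop=True), kept_visits, tally


def exclusion_table(tally: dict, n_input: int) -> pd.DataFrame:
    """Selection-flowchart-style stage table for the exclusion tally."""
    rows = [("available", n_input)]
    remaining = n_input
    for reason in EXCLUSION_REASONS:
        remaining -= tally.get(reason, 0)
        rows.append((f"excluded: {reason}", tally.get(reason, 0)))
    rows.append(("included", remaining))
    return pd.DataFrame(rows, columns=["stage", "n"])
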