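"""Shock cohort definition: onset detection, study window, eligibility.

Day 0 is the earliest calendar day with both a systolic blood pressure
reading below 90 mmHg and a SOFA total strictly above the last
previously recorded total (baseline 0 when no prior measurement
exists, so admission-day shock remains detectable). The study window
is days 0 through 4.

Eligibility then requires: a shock-documenting note on day 0, not all
etiology mentions negated over the window, two or more *distinct*
clinicians with shock notes on at least one single study day (pairwise
comparison is impossible otherwise), and age >= 18. Excluded patients
carry exactly one terminal reason — the first failing rule in the
order: no-structured-shock, no-shock-note-day0, negation-only-notes,
fewer-than-two-clinician-notes, under-18.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "STUDY_DAYS",
    "EXCLUSION_REASONS",
    "ShockEpisode",
    "ExclusionRecord",
    "detect_shock_onset",
    "apply_eligibility",
    "build_cohort",
]

STUDY_DAYS = 5  # day 0 through day 4 inclusive

EXCLUSION_REASONS = (
    "no-structured-shock",
    "no-shock-note-day0",
    "negation-only-notes",
    "fewer-than-two-clinician-notes",
    "under-18",
)

SBP_THRESHOLD = 90.0  # mmHg, qualifying reading is strictly below


@dataclass(frozen=True)
class ShockEpisode:
    """Day-0 anchor with its structured-data evidence."""

    patient_id: str
    day0: dt.date
    qualifying_sbp: float
    qualifying_time: pd.Timestamp
    baseline_sofa: int
    elevated_sofa: int
    no_prior_sofa: bool = False  # baseline-0 convention applied (QC flag)

    def __post_init__(self) -> None:
        assert self.qualifying_sbp < SBP_THRESHOLD
        assert self.elevated_sofa > self.baseline_sofa

    @property
    def study_days(self) -> tuple[dt.date, ...]:
        return tuple(self.day0 + dt.timedelta(days=i) for i in range(STUDY_DAYS))


@dataclass(frozen=True)
class ExclusionRecord:
    patient_id: str
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.reason!r}")


def detect_shock_onset(
    vitals: pd.DataFrame, sofa_daily: pd.DataFrame
) -> ShockEpisode | None:
    """Find day 0 for one patient from vitals and daily SOFA totals.

    ``vitals``: columns timestamp, measure, value (time-ordered); SBP
    rows have measure == 'sbp'. ``sofa_daily``: columns date,
    sofa_total (plus optionally patient_id). Returns None when no
    calendar day satisfies both criteria.
    """
    if vitals.empty:
        return None
    pid = str(vitals["patient_id"].iloc[0]) if "patient_id" in vitals else ""
    sbp = vitals[vitals["measure"] == "sbp"].copy()
    if sbp.empty:
        return None
    sbp["timestamp"] = pd.to_datetime(sbp["timestamp"])
    sbp["date"] = sbp["timestamp"].dt.date
    sofa = sofa_daily.sort_values("date")
    totals = list(zip(sofa["date"], sofa["sofa_total"]))

    low_days = sorted(sbp.loc[sbp["value"] < SBP_THRESHOLD, "date"].unique())
    for day in low_days:
        today = [t for d, t in totals if d == day]
        if not today:
            continue
        prior = [t for d, t in totals if d < day]
        baseline = int(prior[-1]) if prior else 0
        current = int(today[-1])
        if current > baseline:
            qual = sbp[(sbp["date"] == day) & (sbp["value"] < SBP_THRESHOLD)].iloc[0]
            return ShockEpisode(
                patient_id=pid,
                day0=day,
                qualifying_sbp=float(qual["value"]),
                qualifying_time=qual["timestamp"],
                baseline_sofa=baseline,
                elevated_sofa=current,
                no_prior_sofa=not prior,
            )
    return None


def apply_eligibility(
    episode: ShockEpisode | None,
    notes: pd.DataFrame,
    age: float,
    patient_id: str = "",
) -> ExclusionRecord | None:
    """Inclusion decision for one patient; None means included.

    ``notes``: one row per study-window note with columns date,
    clinician_id, shock_word, negated_only, has_matches. Rules are
    evaluated in the fixed exclusion order and the first failure wins.
    """
    if episode is None:
        return ExclusionRecord(patient_id, "no-structured-shock")
    pid = episode.patient_id or patient_id
    window = set(episode.study_days)
    notes = notes[notes["date"].isin(window)]
    shock_notes = notes[notes["shock_word"]]

    day0_notes = shock_notes[shock_notes["date"] == episode.day0]
    if day0_notes.empty:
        return ExclusionRecord(pid, "no-shock-note-day0")

    with_matches = notes[notes["has_matches"]]
    if not with_matches.empty and bool(with_matches["negated_only"].all()):
        return ExclusionRecord(pid, "negation-only-notes")

    multi = (
        shock_notes.groupby("date")["clinician_id"].nunique() >= 2
    )
    if not bool(multi.any()):
        return ExclusionRecord(pid, "fewer-than-two-clinician-notes")

    if age < 18:
        return ExclusionRecord(pid, "under-18")
    return None


def build_cohort(
    vitals: pd.DataFrame,
    sofa_daily: pd.DataFrame,
    note_meta: pd.DataFrame,
    demographics: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, ShockEpisode]]:
    """Apply onset detection and eligibility to every patient.

    ``note_meta`` needs columns patient_id, date, clinician_id,
    shock_word, negated_only, has_matches. Returns (cohort table,
    exclusion table, episode map for included patients).
    """
    ages = demographics.set_index("patient_id")["age"]
    cohort_rows, exclusion_rows, episodes = [], [], {}
    note_groups = {pid: grp for pid, grp in note_meta.groupby("patient_id")}
    sofa_groups = {pid: grp for pid, grp in sofa_daily.groupby("patient_id")}
    empty_notes = note_meta.iloc[0:0]
    for pid, pat_vitals in vitals.groupby("patient_id", sort=True):
        pid = str(pid)
        episode = detect_shock_onset(
            pat_vitals, sofa_groups.get(pid, sofa_daily.iloc[0:0])
        )
        excl = apply_eligibility(
            episode, note_groups.get(pid, empty_notes), float(ages.get(pid, 0)),
            patient_id=pid,
        )
        if excl is not None:
            exclusion_rows.append({"patient_id": pid, "reason": excl.reason})
            continue
        assert episode is not None
        episodes[pid] = episode
        cohort_rows.append({
            "patient_id": pid,
            "day0": episode.day0,
            "qualifying_sbp": episode.qualifying_sbp,
            "baseline_sofa": episode.baseline_sofa,
            "elevated_sofa": episode.elevated_sofa,
            "no_prior_sofa": episode.no_prior_sofa,
        })
    cohort = pd.DataFrame.from_records(
        cohort_rows, columns=["patient_id", "day0", "qualifying_sbp",
                              "baseline_sofa", "elevated_sofa", "no_prior_sofa"])
    exclusions = pd.DataFrame.from_records(
        exclusion_rows, columns=["patient_id", "reason"])
    return cohort, exclusions, episodes
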